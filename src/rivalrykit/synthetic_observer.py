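"""Synthetic rivalry observers: a coupled two-zone renewal process plus a
motor reporting layer, producing button logs the analyzer can consume.

Latent model
------------
Each disc location is a rivalry zone holding an eye-dominance state.  One
zone drives the alternation clock: its dominance durations are Gamma
distributed (shape ``epoch_gamma_shape``, mean ``epoch_mean``) and its
dominant eye flips at every renewal, as in a standard rivalry renewal
process.  At each renewal the second zone re-couples: with probability
``eye_coupling`` it adopts the driving zone's new dominant eye, otherwise the
opposite eye.  Each zone's percept is whatever orientation its dominant eye
is shown at that location, so same-eye (SE) layouts turn eye synchrony into
a grouped percept while different-eye (DE) layouts turn the *same* eye
synchrony into an ungrouped percept — the eye-of-origin grouping effect.
With probability ``mixed_prob`` a renewal passes through a mixed interlude
(exponential, mean ``mixed_mean``) during which neither exclusive percept is
seen.  The central control condition is a single zone.

Motor layer
-----------
Reported percept onsets lag the latent change by a truncated-normal latency;
at each change between the two exclusive percepts the new button is pressed
before the old one is released by a truncated-normal overlap (the transition
signature); each dominance period is dropped wholesale with probability
``lapse_prob``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .experiment_design import (
    ConditionId,
    Eye,
    Orientation,
    TrialCondition,
    build_condition_set,
)
from .event_stream import Button, ButtonIntervalLog, _merge_intervals

__all__ = [
    "PerceptState",
    "ObserverParams",
    "GroupSpec",
    "CohortConfig",
    "default_cohort_config",
    "simulate_latent_process",
    "render_button_log",
    "simulate_cohort",
]


class PerceptState(str, Enum):
    GROUPED_H = "GROUPED_H"
    GROUPED_V = "GROUPED_V"
    UNGROUPED = "UNGROUPED"
    MIXED = "MIXED"


_EXCLUSIVE = (PerceptState.GROUPED_H, PerceptState.GROUPED_V)

_STATE_BUTTONS: dict[PerceptState, tuple[Button, ...]] = {
    PerceptState.GROUPED_H: (Button.LEFT,),
    PerceptState.GROUPED_V: (Button.RIGHT,),
    PerceptState.UNGROUPED: (Button.LEFT, Button.RIGHT),
    PerceptState.MIXED: (),
}


@dataclass(frozen=True)
class ObserverParams:
    """Tunable observer parameters (times in seconds, probabilities in [0,1])."""

    epoch_gamma_shape: float = 3.0
    epoch_mean: float = 3.0
    mixed_prob: float = 0.17
    mixed_mean: float = 2.0
    eye_coupling: float = 0.93
    press_latency_mean: float = 0.35
    press_latency_sd: float = 0.10
    overlap_mean: float = 0.15
    overlap_sd: float = 0.05
    lapse_prob: float = 0.01

    def __post_init__(self) -> None:
        for name in ("epoch_gamma_shape", "epoch_mean", "mixed_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("mixed_prob", "eye_coupling", "lapse_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        for name in ("press_latency_mean", "press_latency_sd",
                     "overlap_mean", "overlap_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def ideal_motor(params: ObserverParams) -> ObserverParams:
    """A noiseless reporting layer: the button log mirrors the latent timeline."""
    return replace(
        params,
        press_latency_mean=0.0, press_latency_sd=0.0,
        overlap_mean=0.0, overlap_sd=0.0, lapse_prob=0.0,
    )


def simulate_latent_process(
    params: ObserverParams,
    condition: TrialCondition,
    duration: float = 60.0,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[float, float, PerceptState]]:
    """Simulate the latent percept timeline for one trial.

    Returns contiguous (t_start, t_end, state) segments partitioning
    [0, duration], adjacent segments having distinct states.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    positions = condition.positions()
    single_zone = len(positions) == 1
    scale = params.epoch_mean / params.epoch_gamma_shape

    def _couple(leader: Eye) -> Eye:
        return leader if rng.random() < params.eye_coupling else leader.other()

    leader = Eye.LEFT if rng.random() < 0.5 else Eye.RIGHT
    follower = leader if single_zone else _couple(leader)

    segments: list[list] = []

    def _append(t0: float, t1: float, state: PerceptState) -> None:
        if t1 <= t0:
            return
        if segments and segments[-1][2] is state:
            segments[-1][1] = t1
        else:
            segments.append([t0, t1, state])

    t = 0.0
    while t < duration:
        d = rng.gamma(params.epoch_gamma_shape, scale)
        o_lead = condition.orientation_at(leader, positions[0])
        if single_zone:
            match = True
        else:
            match = o_lead == condition.orientation_at(follower, positions[1])
        if match:
            state = (PerceptState.GROUPED_H if o_lead is Orientation.H
                     else PerceptState.GROUPED_V)
        else:
            state = PerceptState.UNGROUPED
        _append(t, min(t + d, duration), state)
        t += d
        if t >= duration:
            break
        leader = leader.other()
        follower = leader if single_zone else _couple(leader)
        if rng.random() < params.mixed_prob:
            m = rng.exponential(params.mixed_mean)
            _append(t, min(t + m, duration), PerceptState.MIXED)
            t += m
    return [(t0, t1, s) for t0, t1, s in segments]


def render_button_log(
    latent: Sequence[tuple[float, float, PerceptState]],
    params: ObserverParams,
    rng: np.random.Generator | int | None = None,
    participant_id: str = "sim",
    trial_id: str = "t01",
    condition_id: str = ConditionId.CENTRAL.value,
) -> ButtonIntervalLog:
    """Translate a latent timeline into a two-channel button log."""
    if not latent:
        raise ValueError("latent timeline is empty")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    duration = latent[-1][1]
    n = len(latent)

    latencies = np.maximum(
        rng.normal(params.press_latency_mean, params.press_latency_sd, size=n), 0.0
    )
    lapse_draws = rng.random(n)
    overlaps = np.maximum(
        rng.normal(params.overlap_mean, params.overlap_sd, size=max(n - 1, 1)), 0.0
    )

    starts = np.array([seg[0] for seg in latent]) + latencies
    starts = np.maximum.accumulate(starts)          # report order is preserved
    bounds = np.append(np.minimum(starts, duration), duration)
    reported = lapse_draws >= params.lapse_prob

    per_button: dict[Button, list[tuple[float, float]]] = {
        Button.LEFT: [], Button.RIGHT: []
    }
    for i, (_, _, state) in enumerate(latent):
        a, b = float(bounds[i]), float(bounds[i + 1])
        if not reported[i] or b <= a:
            continue
        release = b
        if (
            i + 1 < n
            and state in _EXCLUSIVE
            and latent[i + 1][2] in _EXCLUSIVE
            and latent[i + 1][2] is not state
            and reported[i + 1]
        ):
            # transition wave: old button released after the new press
            release = min(b + float(overlaps[i]), duration)
        for button in _STATE_BUTTONS[state]:
            per_button[button].append((a, release))

    intervals: list[tuple[Button, float, float]] = []
    for button in (Button.LEFT, Button.RIGHT):
        merged, _ = _merge_intervals(per_button[button])
        intervals.extend((button, a, b) for a, b in merged)
    intervals.sort(key=lambda r: (r[1], r[2], r[0].value))
    return ButtonIntervalLog(
        participant_id=participant_id,
        trial_id=trial_id,
        condition_id=condition_id,
        trial_duration=duration,
        intervals=intervals,
    )


#: Observer fields allowed to vary across participants.
_PARAM_FIELDS = tuple(f.name for f in fields(ObserverParams))


@dataclass(frozen=True)
class GroupSpec:
    """Sampling distribution of one cohort group."""

    name: str
    n_participants: int
    age_mean: float
    age_sd: float
    params: ObserverParams
    params_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError(f"group {self.name}: n_participants must be >= 1")
        if self.age_sd < 0:
            raise ValueError(f"group {self.name}: age_sd must be >= 0")
        for key, sd in self.params_sd.items():
            if key not in _PARAM_FIELDS:
                raise ValueError(f"group {self.name}: unknown parameter {key!r}")
            if sd < 0:
                raise ValueError(f"group {self.name}: sd for {key!r} must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    groups: tuple[GroupSpec, ...]
    trial_duration: float = 60.0
    include_central: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")


_PROB_FIELDS = {"mixed_prob", "eye_coupling", "lapse_prob"}
_MIN_POSITIVE = 0.2  # floor for sampled time-scale parameters (s)


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """The calibrated study-emulation cohort: 17 glaucoma and 14 control
    observers, differing only in mean dominance-epoch duration (glaucoma
    slower, hence lower rivalry rate)."""
    shared = dict(
        epoch_gamma_shape=3.0, mixed_prob=0.17,
        eye_coupling=0.93, press_latency_mean=0.35, press_latency_sd=0.10,
        overlap_mean=0.15, overlap_sd=0.05, lapse_prob=0.01,
    )
    spread = {"epoch_mean": 0.6}
    return CohortConfig(
        groups=(
            GroupSpec("glaucoma", 17, age_mean=61, age_sd=12,
                      params=ObserverParams(epoch_mean=3.8, mixed_mean=2.8, **shared),
                      params_sd=dict(spread)),
            GroupSpec("control", 14, age_mean=53, age_sd=11,
                      params=ObserverParams(epoch_mean=3.0, mixed_mean=2.0, **shared),
                      params_sd=dict(spread)),
        ),
        seed=seed,
    )


def _draw_params(
    spec: GroupSpec, rng: np.random.Generator
) -> ObserverParams:
    values = {}
    for name in _PARAM_FIELDS:
        mean = getattr(spec.params, name)
        sd = spec.params_sd.get(name, 0.0)
        v = float(rng.normal(mean, sd)) if sd > 0 else float(mean)
        if name in _PROB_FIELDS:
            v = min(max(v, 0.0), 1.0)
        elif name in ("press_latency_sd", "overlap_sd",
                      "press_latency_mean", "overlap_mean"):
            v = max(v, 0.0)
        else:
            v = max(v, _MIN_POSITIVE)
        values[name] = v
    return ObserverParams(**values)


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[ButtonIntervalLog], pd.DataFrame]:
    """Simulate the full cohort: every participant runs all 9 trials
    (8 counterbalanced grouping trials plus the central control), each
    ``trial_duration`` seconds, in a per-participant random order.

    Seeds are derived hierarchically (master -> participant), so the output
    is fully reproducible from ``config.seed``.
    """
    conditions = build_condition_set(include_central=config.include_central)
    total = sum(g.n_participants for g in config.groups)
    children = np.random.SeedSequence(config.seed).spawn(total)

    logs: list[ButtonIntervalLog] = []
    meta_rows: list[dict] = []
    k = 0
    for spec in config.groups:
        prefix = spec.name[0]
        for i in range(spec.n_participants):
            child = children[k]
            k += 1
            rng = np.random.default_rng(child)
            pid = f"{prefix}{i + 1:02d}"
            age = float(rng.normal(spec.age_mean, spec.age_sd))
            params = _draw_params(spec, rng)
            order = [conditions[j] for j in rng.permutation(len(conditions))]
            for j, cond in enumerate(order):
                latent = simulate_latent_process(
                    params, cond, duration=config.trial_duration, rng=rng
                )
                logs.append(render_button_log(
                    latent, params, rng,
                    participant_id=pid,
                    trial_id=f"{pid}-t{j + 1:02d}",
                    condition_id=cond.condition_id.value,
                ))
            meta_rows.append({
                "participant_id": pid,
                "group": spec.name,
                "age": age,
                "seed": int(child.generate_state(1, dtype=np.uint32)[0]),
            })
    return logs, pd.DataFrame(meta_rows)
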