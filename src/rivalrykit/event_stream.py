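"""Button-log parsing: percept timelines and rivalry outcome measures.

Observers hold the left button while both discs look horizontal, the right
button while both look vertical, both buttons while the two discs show
different orientations, and no button during mixed (piecemeal/superimposed)
percepts.  A brief both-pressed overlap also occurs at each change of
exclusive dominance, when the newly dominant percept's button is pressed
before the old one is released; those short overlaps mark the transition
wave and are excluded from dominance-time and epoch accounting.

Outcome measures per 60-s trial:

* cumulative time of exclusive dominance of the grouped percept
  (both-horizontal plus both-vertical), of the ungrouped percept, and of the
  mixed (unreported) percept;
* the rivalry rate: perceptual switches per minute, a switch being each
  alternation between the two exclusive grouped percepts;
* the mean dominance epoch: grouped-dominance time divided by the switch
  count (numerically equal, on a 60-s trial, to grouped time over the
  per-minute rate);
* the within/between-hemifield epoch difference
  D = epoch(same eye / different hemifields) - epoch(same eye / same hemifield).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Button",
    "Label",
    "LogValidationError",
    "ButtonIntervalLog",
    "PerceptTimeline",
    "TrialMetrics",
    "EpochDifference",
    "validate_log",
    "resolve_timeline",
    "dominance_times",
    "count_switches",
    "rivalry_rate",
    "mean_epoch",
    "epoch_difference",
    "compute_trial_metrics",
    "metrics_frame",
    "aggregate_by_condition",
    "epoch_differences_frame",
]

DEFAULT_TAU_OVERLAP = 0.4  # s; both-press spans shorter than this, flanked by
#                            the two exclusive percepts, are transition waves


class Button(str, Enum):
    LEFT = "LEFT"    # both discs horizontal
    RIGHT = "RIGHT"  # both discs vertical


class Label(str, Enum):
    GROUPED_H = "GROUPED_H"
    GROUPED_V = "GROUPED_V"
    UNGROUPED = "UNGROUPED"
    UNREPORTED = "UNREPORTED"
    TRANSITION = "TRANSITION"


EXCLUSIVE = (Label.GROUPED_H, Label.GROUPED_V)


class LogValidationError(ValueError):
    """Raised when a raw log row cannot be repaired."""


@dataclass
class ButtonIntervalLog:
    """Raw two-channel press intervals for one trial.

    ``intervals`` rows are (button, t_on, t_off) in seconds on the trial
    clock.  ``warnings`` lists repairs applied by :func:`validate_log`.
    """

    participant_id: str
    trial_id: str
    condition_id: str
    trial_duration: float = 60.0
    intervals: list[tuple[Button, float, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list, compare=False)


@dataclass(frozen=True)
class PerceptTimeline:
    """Exhaustive labeled partition of one trial's time axis."""

    intervals: tuple[tuple[float, float, Label], ...]
    trial_duration: float

    def check(self, atol: float = 1e-9) -> None:
        t = 0.0
        prev = None
        for t0, t1, lab in self.intervals:
            if abs(t0 - t) > atol or t1 <= t0:
                raise ValueError("timeline does not partition the trial")
            if lab == prev:
                raise ValueError("adjacent intervals share a label")
            t, prev = t1, lab
        if abs(t - self.trial_duration) > atol:
            raise ValueError("timeline does not cover the trial")


class DominanceTimes(NamedTuple):
    t_grouped: float
    t_ungrouped: float
    t_mixed: float
    t_transition: float


@dataclass(frozen=True)
class TrialMetrics:
    participant_id: str
    trial_id: str
    condition_id: str
    trial_duration: float
    t_grouped: float
    t_ungrouped: float
    t_mixed: float
    t_transition: float
    n_switches: int
    rivalry_rate: float
    mean_epoch: float

    @property
    def t_both_total(self) -> float:
        """Raw both-pressed time, transition overlaps included (audit value)."""
        return self.t_ungrouped + self.t_transition


@dataclass(frozen=True)
class EpochDifference:
    participant_id: str
    d_epoch: float  # epoch(SE/DH) - epoch(SE/SH), seconds


def _merge_intervals(spans: list[tuple[float, float]]) -> tuple[list[tuple[float, float]], int]:
    """Sort and union overlapping or touching spans; return merge count."""
    spans = sorted(spans)
    merged: list[tuple[float, float]] = []
    n_merges = 0
    for a, b in spans:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            n_merges += 1
        else:
            merged.append((a, b))
    return merged, n_merges


def validate_log(raw: ButtonIntervalLog) -> ButtonIntervalLog:
    """Repair a raw log: clamp times into the trial, sort, and merge
    overlapping/adjacent same-button intervals.

    Each repair is recorded in the returned log's ``warnings``.  Unrepairable
    rows (t_on >= t_off, unknown button, negative trial duration) raise
    :class:`LogValidationError` naming the offending row.
    """
    if raw.trial_duration <= 0:
        raise LogValidationError(
            f"trial {raw.trial_id}: trial_duration must be positive, "
            f"got {raw.trial_duration}"
        )
    warnings: list[str] = []
    per_button: dict[Button, list[tuple[float, float]]] = {
        Button.LEFT: [], Button.RIGHT: []
    }
    for i, (button, t_on, t_off) in enumerate(raw.intervals):
        try:
            button = Button(button)
        except ValueError:
            raise LogValidationError(
                f"trial {raw.trial_id} row {i}: unknown button {button!r}"
            ) from None
        if not (t_on < t_off):
            raise LogValidationError(
                f"trial {raw.trial_id} row {i}: t_on ({t_on}) must be < t_off ({t_off})"
            )
        a = max(0.0, float(t_on))
        b = min(raw.trial_duration, float(t_off))
        if (a, b) != (float(t_on), float(t_off)):
            warnings.append(f"row {i}: clamped [{t_on}, {t_off}] to [{a}, {b}]")
        if b <= a:
            warnings.append(f"row {i}: interval outside trial window, dropped")
            continue
        per_button[button].append((a, b))
    intervals: list[tuple[Button, float, float]] = []
    for button in (Button.LEFT, Button.RIGHT):
        merged, n_merges = _merge_intervals(per_button[button])
        if n_merges:
            warnings.append(
                f"{button.value}: merged {n_merges} overlapping/adjacent interval(s)"
            )
        intervals.extend((button, a, b) for a, b in merged)
    intervals.sort(key=lambda r: (r[1], r[2], r[0].value))
    return ButtonIntervalLog(
        participant_id=raw.participant_id,
        trial_id=raw.trial_id,
        condition_id=raw.condition_id,
        trial_duration=float(raw.trial_duration),
        intervals=intervals,
        warnings=warnings,
    )


def _press_state_label(left: bool, right: bool) -> Label:
    if left and right:
        return Label.UNGROUPED  # provisional; short spans relabeled below
    if left:
        return Label.GROUPED_H
    if right:
        return Label.GROUPED_V
    return Label.UNREPORTED


def resolve_timeline(
    log: ButtonIntervalLog, tau_overlap: float = DEFAULT_TAU_OVERLAP
) -> PerceptTimeline:
    """Convert a validated log into a labeled partition of the trial.

    Both-pressed spans shorter than ``tau_overlap`` that sit between the two
    different exclusive percepts are transition waves (``TRANSITION``); every
    other both-pressed span is a deliberate ungrouped report.  The flanking
    requirement keeps sustained two-button reports in different-eye
    conditions from being eaten as transitions.
    """
    if tau_overlap < 0:
        raise ValueError("tau_overlap must be >= 0")
    T = log.trial_duration
    cuts = {0.0, T}
    for _, a, b in log.intervals:
        cuts.add(a)
        cuts.add(b)
    edges = np.array(sorted(cuts))
    mids = (edges[:-1] + edges[1:]) / 2.0

    def _down(button: Button) -> np.ndarray:
        flat: list[float] = []
        for btn, a, b in log.intervals:
            if btn is button:
                flat.extend((a, b))
        if not flat:
            return np.zeros(mids.shape, dtype=bool)
        return np.searchsorted(np.asarray(flat), mids, side="right") % 2 == 1

    left_down = _down(Button.LEFT)
    right_down = _down(Button.RIGHT)

    # run-length encode the elementary segments
    runs: list[list] = []  # [t0, t1, label]
    for i in range(len(mids)):
        lab = _press_state_label(bool(left_down[i]), bool(right_down[i]))
        if runs and runs[-1][2] is lab:
            runs[-1][1] = edges[i + 1]
        else:
            runs.append([edges[i], edges[i + 1], lab])

    # a provisional UNGROUPED run is exactly a both-pressed span
    for i, (t0, t1, lab) in enumerate(runs):
        if lab is not Label.UNGROUPED:
            continue
        short = (t1 - t0) < tau_overlap
        flanked = (
            0 < i < len(runs) - 1
            and runs[i - 1][2] in EXCLUSIVE
            and runs[i + 1][2] in EXCLUSIVE
            and runs[i - 1][2] is not runs[i + 1][2]
        )
        runs[i][2] = Label.TRANSITION if (short and flanked) else Label.UNGROUPED

    # relabeling cannot create adjacent duplicates, but merge defensively
    merged: list[list] = []
    for t0, t1, lab in runs:
        if merged and merged[-1][2] is lab:
            merged[-1][1] = t1
        else:
            merged.append([t0, t1, lab])
    return PerceptTimeline(
        intervals=tuple((t0, t1, lab) for t0, t1, lab in merged),
        trial_duration=T,
    )


def dominance_times(timeline: PerceptTimeline) -> DominanceTimes:
    """Cumulative time per percept class; components sum to the trial duration."""
    acc = {lab: 0.0 for lab in Label}
    for t0, t1, lab in timeline.intervals:
        acc[lab] += t1 - t0
    return DominanceTimes(
        t_grouped=acc[Label.GROUPED_H] + acc[Label.GROUPED_V],
        t_ungrouped=acc[Label.UNGROUPED],
        t_mixed=acc[Label.UNREPORTED],
        t_transition=acc[Label.TRANSITION],
    )


def count_switches(timeline: PerceptTimeline, tau_gap: float = math.inf) -> int:
    """Perceptual switches: alternations of the exclusive grouped percepts.

    Non-exclusive interludes are skipped regardless of length by default;
    a finite ``tau_gap`` breaks the dominance sequence whenever the
    accumulated non-exclusive time between two exclusive periods exceeds it.
    """
    switches = 0
    last: Label | None = None
    gap = 0.0
    for t0, t1, lab in timeline.intervals:
        if lab in EXCLUSIVE:
            if last is not None and lab is not last and gap <= tau_gap:
                switches += 1
            last = lab
            gap = 0.0
        else:
            gap += t1 - t0
    return switches


def rivalry_rate(n_switches: int, trial_duration: float) -> float:
    """Switches per minute."""
    if n_switches < 0 or trial_duration <= 0:
        raise ValueError("n_switches must be >= 0 and trial_duration > 0")
    return n_switches * 60.0 / trial_duration


def mean_epoch(t_grouped: float, n_switches: int) -> float:
    """Mean exclusive-dominance epoch of the grouped percept (s).

    Grouped-dominance time divided by the switch count; NaN when no switch
    occurred (the epoch is undefined, not zero).
    """
    if t_grouped < 0 or n_switches < 0:
        raise ValueError("t_grouped and n_switches must be non-negative")
    if n_switches == 0:
        return math.nan
    return t_grouped / n_switches


def epoch_difference(
    metrics_se_dh: "TrialMetrics | float", metrics_se_sh: "TrialMetrics | float",
    participant_id: str | None = None,
) -> EpochDifference:
    """D = epoch(SE/DH) - epoch(SE/SH); NaN on either side propagates."""
    def _epoch(m):
        return m.mean_epoch if isinstance(m, TrialMetrics) else float(m)

    if participant_id is None:
        participant_id = (
            metrics_se_dh.participant_id
            if isinstance(metrics_se_dh, TrialMetrics) else ""
        )
    return EpochDifference(
        participant_id=participant_id,
        d_epoch=_epoch(metrics_se_dh) - _epoch(metrics_se_sh),
    )


def compute_trial_metrics(
    log: ButtonIntervalLog,
    tau_overlap: float = DEFAULT_TAU_OVERLAP,
    tau_gap: float = math.inf,
) -> TrialMetrics:
    """Full per-trial pipeline: validate -> timeline -> outcome measures."""
    clean = validate_log(log)
    timeline = resolve_timeline(clean, tau_overlap=tau_overlap)
    times = dominance_times(timeline)
    n_sw = count_switches(timeline, tau_gap=tau_gap)
    return TrialMetrics(
        participant_id=clean.participant_id,
        trial_id=clean.trial_id,
        condition_id=clean.condition_id,
        trial_duration=clean.trial_duration,
        t_grouped=times.t_grouped,
        t_ungrouped=times.t_ungrouped,
        t_mixed=times.t_mixed,
        t_transition=times.t_transition,
        n_switches=n_sw,
        rivalry_rate=rivalry_rate(n_sw, clean.trial_duration),
        mean_epoch=mean_epoch(times.t_grouped, n_sw),
    )


METRIC_COLUMNS = [
    "t_grouped", "t_ungrouped", "t_mixed", "t_transition", "t_both_total",
    "n_switches", "rivalry_rate", "mean_epoch",
]


def metrics_frame(metrics: Iterable[TrialMetrics]) -> pd.DataFrame:
    rows = []
    for m in metrics:
        rows.append({
            "participant_id": m.participant_id,
            "trial_id": m.trial_id,
            "condition_id": m.condition_id,
            "trial_duration": m.trial_duration,
            "t_grouped": m.t_grouped,
            "t_ungrouped": m.t_ungrouped,
            "t_mixed": m.t_mixed,
            "t_transition": m.t_transition,
            "t_both_total": m.t_both_total,
            "n_switches": m.n_switches,
            "rivalry_rate": m.rivalry_rate,
            "mean_epoch": m.mean_epoch,
        })
    return pd.DataFrame(rows)


def aggregate_by_condition(
    metrics: "pd.DataFrame | Iterable[TrialMetrics]",
    expected_conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Average the counterbalanced trial pair within each logical condition.

    One output row per participant x condition.  ``mean_epoch`` averages only
    the trials where it is defined (a single undefined trial does not erase
    its partner); all-undefined pairs stay NaN.  Conditions listed in
    ``expected_conditions`` but absent for a participant appear as NaN rows.
    """
    frame = metrics if isinstance(metrics, pd.DataFrame) else metrics_frame(metrics)
    if frame.empty:
        raise ValueError("no trial metrics to aggregate")
    agg_spec = {c: "mean" for c in METRIC_COLUMNS if c != "mean_epoch"}
    agg_spec["trial_duration"] = "mean"
    grouped = frame.groupby(["participant_id", "condition_id"], sort=False)
    out = grouped.agg(agg_spec)
    out["mean_epoch"] = grouped["mean_epoch"].agg(
        lambda s: np.nan if s.dropna().empty else s.dropna().mean()
    )
    out["n_trials"] = grouped.size()
    out = out.reset_index()
    if expected_conditions is not None:
        full = pd.MultiIndex.from_product(
            [out["participant_id"].unique(), list(expected_conditions)],
            names=["participant_id", "condition_id"],
        )
        out = (
            out.set_index(["participant_id", "condition_id"])
            .reindex(full)
            .reset_index()
        )
    return out


def epoch_differences_frame(per_condition: pd.DataFrame) -> pd.DataFrame:
    """Per-participant epoch difference D = epoch(MO_SE_DH) - epoch(MO_SE_SH)."""
    wide = per_condition.pivot(
        index="participant_id", columns="condition_id", values="mean_epoch"
    )
    for cond in ("MO_SE_DH", "MO_SE_SH"):
        if cond not in wide.columns:
            raise ValueError(f"missing condition {cond} in per-condition metrics")
    return pd.DataFrame({
        "participant_id": wide.index,
        "d_epoch": (wide["MO_SE_DH"] - wide["MO_SE_SH"]).to_numpy(),
    }).reset_index(drop=True)
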