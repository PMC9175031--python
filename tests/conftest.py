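import math

import numpy as np
import pytest

from rivalrykit.event_stream import (
    Button,
    ButtonIntervalLog,
    Label,
    PerceptTimeline,
)

EXCLUSIVE = (Label.GROUPED_H, Label.GROUPED_V)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_log(intervals, duration=60.0, condition="CENTRAL"):
    return ButtonIntervalLog(
        participant_id="p01",
        trial_id="p01-t01",
        condition_id=condition,
        trial_duration=duration,
        intervals=[(b, a, o) for b, a, o in intervals],
    )


def random_log(rng, duration=20.0, max_per_button=5, resolution=1000):
    """A fuzzed log with all endpoints on the 1-ms grid."""
    ticks = int(round(duration * resolution))
    intervals = []
    for button in (Button.LEFT, Button.RIGHT):
        n = int(rng.integers(0, max_per_button + 1))
        if n == 0:
            continue
        cuts = np.sort(rng.choice(ticks + 1, size=2 * n, replace=False))
        for i in range(n):
            a, b = int(cuts[2 * i]), int(cuts[2 * i + 1])
            if b > a:
                intervals.append((button, a / resolution, b / resolution))
    return make_log(intervals, duration=duration)


def grid_scan_timeline(log, tau_overlap=0.4, resolution=1000):
    """Independent 1-ms grid-scan oracle: sample button states on a uniform
    grid, run-length encode, then apply the transition relabeling rule."""
    ticks = int(round(log.trial_duration * resolution))
    left = np.zeros(ticks, dtype=bool)
    right = np.zeros(ticks, dtype=bool)
    for button, a, b in log.intervals:
        i, j = int(round(a * resolution)), int(round(b * resolution))
        (left if button is Button.LEFT else right)[i:j] = True
    state = np.where(left & right, 3, np.where(left, 1, np.where(right, 2, 0)))
    # run-length encode
    change = np.flatnonzero(np.diff(state)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [ticks]])
    label_map = {0: Label.UNREPORTED, 1: Label.GROUPED_H,
                 2: Label.GROUPED_V, 3: Label.UNGROUPED}
    runs = [
        [s / resolution, e / resolution, label_map[int(state[s])]]
        for s, e in zip(starts, ends)
    ]
    for i, (t0, t1, lab) in enumerate(runs):
        if lab is not Label.UNGROUPED:
            continue
        short = (t1 - t0) < tau_overlap - 1e-12
        flanked = (
            0 < i < len(runs) - 1
            and runs[i - 1][2] in EXCLUSIVE
            and runs[i + 1][2] in EXCLUSIVE
            and runs[i - 1][2] is not runs[i + 1][2]
        )
        if short and flanked:
            runs[i][2] = Label.TRANSITION
    return PerceptTimeline(
        intervals=tuple((t0, t1, lab) for t0, t1, lab in runs),
        trial_duration=log.trial_duration,
    )
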