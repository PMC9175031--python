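"""Trial types, counterbalancing, and stimulus geometry for the grouping-rivalry task.

The task probes perceptual grouping during binocular rivalry with two small
grating discs viewed dichoptically.  Identical (same-orientation) targets are
shown either to the same eye (SE) or to different eyes (DE), and either within
one lateral hemifield (SH) or straddling fixation vertically (DH), giving four
logical viewing conditions.  Each is run twice with the orientation-to-eye
(and lateral-hemifield) assignment counterbalanced, for eight grouping trials,
plus one central single-disc control trial.

This module is the single source of truth for that catalog: both the synthetic
observer and the analyzer consume :class:`TrialCondition` records built here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Eye",
    "Orientation",
    "Position",
    "ConditionId",
    "StimulusLayout",
    "TrialCondition",
    "build_condition_set",
    "stimulus_geometry",
    "randomize_order",
    "catalog_frame",
    "write_catalog",
]


class Eye(str, Enum):
    LEFT = "left"
    RIGHT = "right"

    def other(self) -> "Eye":
        return Eye.RIGHT if self is Eye.LEFT else Eye.LEFT


class Orientation(str, Enum):
    H = "H"
    V = "V"

    def orthogonal(self) -> "Orientation":
        return Orientation.V if self is Orientation.H else Orientation.H


class Position(str, Enum):
    """Disc slots, named relative to the fixation cross."""

    LEFT_UPPER = "left-upper"
    LEFT_LOWER = "left-lower"
    RIGHT_UPPER = "right-upper"
    RIGHT_LOWER = "right-lower"
    ABOVE = "above"
    BELOW = "below"
    CENTER = "center"


#: Disc-center coordinates in degrees from fixation (x positive rightward,
#: y positive upward), built from the +/-1 deg horizontal/vertical offsets.
POSITION_COORDS: dict[Position, tuple[float, float]] = {
    Position.LEFT_UPPER: (-1.0, 1.0),
    Position.LEFT_LOWER: (-1.0, -1.0),
    Position.RIGHT_UPPER: (1.0, 1.0),
    Position.RIGHT_LOWER: (1.0, -1.0),
    Position.ABOVE: (0.0, 1.0),
    Position.BELOW: (0.0, -1.0),
    Position.CENTER: (0.0, 0.0),
}


class ConditionId(str, Enum):
    MO_SE_SH = "MO_SE_SH"  # matching orientations, same eye, same hemifield
    MO_SE_DH = "MO_SE_DH"  # matching orientations, same eye, different hemifields
    MO_DE_SH = "MO_DE_SH"  # matching orientations, different eyes, same hemifield
    MO_DE_DH = "MO_DE_DH"  # matching orientations, different eyes, different hemifields
    CENTRAL = "CENTRAL"    # single central rivalry disc (control)


@dataclass(frozen=True)
class StimulusLayout:
    """Geometry of the rivalry display, all values in visual-angle degrees
    (spatial frequency in cycles/deg)."""

    disc_diameter: float = 1.8
    grating_spatial_frequency: float = 4.0
    inter_disc_gap: float = 0.2
    fixation_cross_size: float = 0.5
    horizontal_offset: float = 1.0
    vertical_offset: float = 1.0

    def __post_init__(self) -> None:
        for name in ("disc_diameter", "grating_spatial_frequency",
                     "inter_disc_gap", "fixation_cross_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("horizontal_offset", "vertical_offset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def diagonal_eccentricity(self) -> float:
        """Distance from fixation to a corner disc center (deg)."""
        return stimulus_geometry(self.horizontal_offset, self.vertical_offset)


@dataclass(frozen=True)
class TrialCondition:
    """One trial's dichoptic layout.

    ``per_eye_layout`` lists, for each (eye, position) pair the disc shown
    there, as (eye, position, orientation).  The two eyes always carry
    orthogonal orientations at every position (the rivalrous pair).
    """

    condition_id: ConditionId
    variant_index: int
    per_eye_layout: tuple[tuple[Eye, Position, Orientation], ...]

    def __post_init__(self) -> None:
        if self.variant_index not in (1, 2):
            raise ValueError("variant_index must be 1 or 2")
        for pos in self.positions():
            pair = {e: o for e, p, o in self.per_eye_layout if p == pos}
            if set(pair) != {Eye.LEFT, Eye.RIGHT}:
                raise ValueError(f"position {pos.value} must be seen by both eyes")
            if pair[Eye.LEFT] == pair[Eye.RIGHT]:
                raise ValueError(
                    f"eyes must carry orthogonal orientations at {pos.value}"
                )

    def positions(self) -> tuple[Position, ...]:
        seen: list[Position] = []
        for _, pos, _ in self.per_eye_layout:
            if pos not in seen:
                seen.append(pos)
        return tuple(seen)

    def orientation_at(self, eye: Eye, position: Position) -> Orientation:
        for e, p, o in self.per_eye_layout:
            if e == eye and p == position:
                return o
        raise KeyError((eye, position))


def stimulus_geometry(horizontal_offset: float, vertical_offset: float) -> float:
    """Diagonal eccentricity (deg) of a disc offset from fixation.

    Euclidean norm of the horizontal and vertical offsets; with the default
    +/-1 deg offsets this is sqrt(2) ~= 1.41 deg.
    """
    if horizontal_offset < 0 or vertical_offset < 0:
        raise ValueError("offsets must be non-negative")
    return math.hypot(horizontal_offset, vertical_offset)


def _pair_layout(
    positions: Sequence[Position],
    left_eye_orients: Sequence[Orientation],
) -> tuple[tuple[Eye, Position, Orientation], ...]:
    """Left eye sees the given orientations; right eye the orthogonal ones."""
    rows: list[tuple[Eye, Position, Orientation]] = []
    for pos, o in zip(positions, left_eye_orients):
        rows.append((Eye.LEFT, pos, o))
        rows.append((Eye.RIGHT, pos, o.orthogonal()))
    return tuple(rows)


def build_condition_set(include_central: bool = True) -> list[TrialCondition]:
    """The fixed trial catalog: 8 counterbalanced grouping trials, and
    optionally the central control.

    Variant 1 assigns horizontal gratings to the left eye (and, for
    same-hemifield conditions, uses the left hemifield); variant 2 swaps
    both assignments.
    """
    H, V = Orientation.H, Orientation.V
    sh_positions = {
        1: (Position.LEFT_UPPER, Position.LEFT_LOWER),
        2: (Position.RIGHT_UPPER, Position.RIGHT_LOWER),
    }
    dh_positions = (Position.ABOVE, Position.BELOW)
    conditions: list[TrialCondition] = []
    for variant in (1, 2):
        left_o = H if variant == 1 else V
        conditions.append(TrialCondition(
            ConditionId.MO_SE_SH, variant,
            _pair_layout(sh_positions[variant], (left_o, left_o)),
        ))
        conditions.append(TrialCondition(
            ConditionId.MO_SE_DH, variant,
            _pair_layout(dh_positions, (left_o, left_o)),
        ))
        conditions.append(TrialCondition(
            ConditionId.MO_DE_SH, variant,
            _pair_layout(sh_positions[variant], (left_o, left_o.orthogonal())),
        ))
        conditions.append(TrialCondition(
            ConditionId.MO_DE_DH, variant,
            _pair_layout(dh_positions, (left_o, left_o.orthogonal())),
        ))
    if include_central:
        conditions.append(TrialCondition(
            ConditionId.CENTRAL, 1,
            _pair_layout((Position.CENTER,), (H,)),
        ))
    return conditions


def randomize_order(
    conditions: Sequence[TrialCondition], seed: int | np.random.Generator
) -> list[TrialCondition]:
    """Reproducible random permutation of a trial list."""
    if len(conditions) == 0:
        raise ValueError("conditions must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(conditions))
    return [conditions[i] for i in perm]


def catalog_frame(conditions: Iterable[TrialCondition]) -> pd.DataFrame:
    """Flatten a condition list to one row per (trial, eye, position) disc."""
    rows = []
    for cond in conditions:
        for eye, pos, orient in cond.per_eye_layout:
            rows.append({
                "condition_id": cond.condition_id.value,
                "variant": cond.variant_index,
                "eye": eye.value,
                "position": pos.value,
                "orientation": orient.value,
            })
    return pd.DataFrame(rows)


def write_catalog(conditions: Iterable[TrialCondition], path) -> None:
    catalog_frame(conditions).to_csv(path, index=False)
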