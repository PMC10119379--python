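"""Deterministic trial-design generators for the four search + 2AFC experiments.

Each experiment is a full crossing of its condition cells at a fixed
repetition count:

=====  ======================================  ========================  ======
exp    search target-distractor distance D     foil offset / direction   trials
=====  ======================================  ========================  ======
E1     15, 30, 45, 60, 90, 180                 10 deg, toward or away      300
E2     30, 60, 180                             10/20/60/180 deg, away      432
E3     30, 180 (half search-only trials)       10 deg, toward or away      288
E4     30 on both sides (7-item array)         10 deg, toward or away      240
=====  ======================================  ========================  ======

Distractor direction (clockwise vs counterclockwise from the target hue) is
balanced within each condition cell; trial order and per-trial hues are drawn
from a seeded generator so the same seed reproduces the design bit for bit.

Timing constants of the original procedure (800 ms placeholders, 200 ms
search array, 400 ms in E4) are bookkeeping only and play no computational
role here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List

import numpy as np
import pandas as pd

from .colorspace import rotate

__all__ = [
    "EXPERIMENTS",
    "TrialCondition",
    "Trial",
    "design_experiment",
    "sample_trial_colors",
    "trials_to_frame",
]

EXPERIMENTS = ("E1", "E2", "E3", "E4")

E1_DISTANCES = (15.0, 30.0, 45.0, 60.0, 90.0, 180.0)
E1_REPS_PER_CELL = 25
E2_DISTANCES = (30.0, 60.0, 180.0)
E2_FOIL_DELTAS = (10.0, 20.0, 60.0, 180.0)
E2_REPS_PER_CELL = 36
E3_DISTANCES = (30.0, 180.0)
E3_SIMILARITY_REPS = 36  # per (D, foil_direction) cell
E3_SEARCH_REPS = 72  # per D
E4_DISTANCE = 30.0
E4_REPS_PER_CELL = 60  # per (foil_direction, salient_direction) cell
FOIL_DELTA_DEFAULT = 10.0

SET_SIZE = {"E1": 8, "E2": 8, "E3": 8, "E4": 7}

#: sign of a hue offset for each rotation label (positive = counterclockwise)
DIRECTION_SIGN = {"ccw": 1.0, "cw": -1.0}


@dataclass(frozen=True)
class TrialCondition:
    """One cell of an experiment's design crossing."""

    experiment: str
    D: float
    distractor_direction: str  # "cw" | "ccw"
    foil_distance: float  # NaN on search-only trials
    foil_direction: str  # "toward" | "away" | "none"
    trial_kind: str = "both"  # "both" | "search_report" | "similarity_report"
    salient_direction: str = "none"  # "cw" | "ccw" | "none" (E4 only)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.distractor_direction not in ("cw", "ccw"):
            raise ValueError(f"bad distractor_direction {self.distractor_direction!r}")
        if self.foil_direction not in ("toward", "away", "none"):
            raise ValueError(f"bad foil_direction {self.foil_direction!r}")
        if self.trial_kind not in ("both", "search_report", "similarity_report"):
            raise ValueError(f"bad trial_kind {self.trial_kind!r}")
        if self.salient_direction not in ("cw", "ccw", "none"):
            raise ValueError(f"bad salient_direction {self.salient_direction!r}")


@dataclass(frozen=True)
class Trial:
    """A realized trial: a condition cell plus sampled stimulus values."""

    condition: TrialCondition
    target_hue: float
    distractor_hue: float
    foil_hue: float  # NaN on search-only trials
    target_position: int
    target_side: str  # "left" | "right" | "none" — 2AFC placement of the target
    set_size: int


def _balanced_directions(n: int, first: str) -> List[str]:
    """cw/ccw labels alternating from ``first`` (ceil-half goes to ``first``)."""
    other = "ccw" if first == "cw" else "cw"
    return [first if i % 2 == 0 else other for i in range(n)]


def _conditions_e1() -> List[TrialCondition]:
    cells = []
    for D in E1_DISTANCES:
        for j, foil_dir in enumerate(("toward", "away")):
            # odd repetition count: alternate which label gets the extra
            # trial across the two foil cells so each D is exactly balanced
            dirs = _balanced_directions(E1_REPS_PER_CELL, "cw" if j == 0 else "ccw")
            cells += [
                TrialCondition("E1", D, d, FOIL_DELTA_DEFAULT, foil_dir) for d in dirs
            ]
    return cells


def _conditions_e2() -> List[TrialCondition]:
    cells = []
    for D in E2_DISTANCES:
        for delta in E2_FOIL_DELTAS:
            dirs = _balanced_directions(E2_REPS_PER_CELL, "cw")
            cells += [TrialCondition("E2", D, d, delta, "away") for d in dirs]
    return cells


def _conditions_e3() -> List[TrialCondition]:
    cells = []
    for D in E3_DISTANCES:
        for foil_dir in ("toward", "away"):
            dirs = _balanced_directions(E3_SIMILARITY_REPS, "cw")
            cells += [
                TrialCondition(
                    "E3", D, d, FOIL_DELTA_DEFAULT, foil_dir,
                    trial_kind="similarity_report",
                )
                for d in dirs
            ]
        dirs = _balanced_directions(E3_SEARCH_REPS, "cw")
        cells += [
            TrialCondition(
                "E3", D, d, float("nan"), "none", trial_kind="search_report"
            )
            for d in dirs
        ]
    return cells


def _conditions_e4() -> List[TrialCondition]:
    # Distractors appear at +/-30 deg simultaneously; the recorded direction
    # is the salient one, and the foil is rotated relative to it.
    cells = []
    for foil_dir in ("toward", "away"):
        for salient in ("cw", "ccw"):
            cells += [
                TrialCondition(
                    "E4", E4_DISTANCE, salient, FOIL_DELTA_DEFAULT, foil_dir,
                    salient_direction=salient,
                )
            ] * E4_REPS_PER_CELL
    return cells


_BUILDERS = {
    "E1": _conditions_e1,
    "E2": _conditions_e2,
    "E3": _conditions_e3,
    "E4": _conditions_e4,
}


def sample_trial_colors(condition: TrialCondition, rng: np.random.Generator) -> Trial:
    """Draw the stimulus values for one trial of ``condition``.

    The target hue is uniform over the 360 integer wheel hues; the distractor
    sits at the condition's distance in the recorded rotation direction and
    the foil at its offset toward or away from the distractor side.
    """
    target = float(rng.integers(360))
    sign = DIRECTION_SIGN[condition.distractor_direction]
    distractor = float(rotate(target, sign * condition.D))
    if condition.trial_kind == "search_report":
        foil = float("nan")
        side = "none"
    else:
        foil_sign = sign if condition.foil_direction == "toward" else -sign
        foil = float(rotate(target, foil_sign * condition.foil_distance))
        side = "left" if int(rng.integers(2)) == 0 else "right"
    set_size = SET_SIZE[condition.experiment]
    position = int(rng.integers(set_size))
    return Trial(condition, target, distractor, foil, position, side, set_size)


def design_experiment(which: str, seed: int) -> pd.DataFrame:
    """Generate the full, shuffled trial list for one experiment.

    Returns one row per trial with all condition and stimulus fields; the
    same seed yields an identical table.
    """
    try:
        builder = _BUILDERS[which]
    except KeyError:
        raise ValueError(
            f"unknown experiment {which!r}; expected one of {EXPERIMENTS}"
        ) from None
    rng = np.random.default_rng(seed)
    conditions = builder()
    order = rng.permutation(len(conditions))
    trials = [sample_trial_colors(conditions[i], rng) for i in order]
    return trials_to_frame(trials)


def trials_to_frame(trials: List[Trial]) -> pd.DataFrame:
    """Serialize realized trials to the shared tabular schema."""
    rows = []
    for i, t in enumerate(trials):
        c = t.condition
        rows.append(
            {
                "experiment": c.experiment,
                "trial_index": i,
                "D": c.D,
                "distractor_direction": c.distractor_direction,
                "delta": c.foil_distance,
                "foil_direction": c.foil_direction,
                "trial_kind": c.trial_kind,
                "salient_direction": c.salient_direction,
                "target_hue": t.target_hue,
                "distractor_hue": t.distractor_hue,
                "foil_hue": t.foil_hue,
                "target_position": t.target_position,
                "target_side": t.target_side,
                "set_size": t.set_size,
            }
        )
    return pd.DataFrame(rows)
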