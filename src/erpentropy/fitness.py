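"""Cardiorespiratory fitness: graded cycle-ergometer test and Watt/BMI score.

Fitness is indexed by maximal watt performance on a continuous graded
cycle-ergometer test (start 25 W, +25 W every 2 min at 60 rpm, to voluntary
exhaustion), normalized by body mass index: ``fitness = max_watt / BMI``.
Participants are split into "higher" and "lower" fit groups at the gender-
specific median of this score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GradedTestProtocol",
    "compute_bmi",
    "fitness_score",
    "median_split_by_gender",
    "simulate_graded_test",
    "target_exercise_hr",
]

#: plausible adolescent/adult BMI range; values outside trigger a warning
_BMI_RANGE = (10.0, 60.0)


@dataclass(frozen=True)
class GradedTestProtocol:
    """Incremental test protocol: +`increment_watt` every `stage_s` seconds."""

    start_watt: float = 25.0
    increment_watt: float = 25.0
    stage_s: float = 120.0
    cadence_rpm: float = 60.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")

    def watt_at(self, t_s: float) -> float:
        """Resistance at elapsed time ``t_s`` (last stage begun)."""
        return self.start_watt + self.increment_watt * math.floor(
            t_s / self.stage_s
        )


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, kg/m². Warns if the result falls outside [10, 60]
    (the usual symptom of height given in cm)."""
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    bmi = weight_kg / height_m**2
    if not _BMI_RANGE[0] <= bmi <= _BMI_RANGE[1]:
        warnings.warn(
            f"BMI {bmi:.2f} outside plausible range {_BMI_RANGE}; "
            "check units (height must be in meters)",
            stacklevel=2,
        )
    return bmi


def fitness_score(max_watt: float, bmi: float) -> float:
    """Watt-per-BMI fitness index: ``max_watt / bmi``."""
    if max_watt <= 0 or bmi <= 0:
        raise ValueError("max_watt and bmi must be positive")
    return max_watt / bmi


def median_split_by_gender(
    participants: pd.DataFrame,
    score_col: str = "fitness_score",
    gender_col: str = "gender",
) -> tuple[pd.DataFrame, dict]:
    """Median split of the fitness score, separately per gender.

    Scores strictly above the gender median go to the "higher" group, scores
    at or below it to "lower" (deterministic tie rule).  Returns the table
    with a ``fitness_group`` column added and the per-gender medians.
    """
    if participants[score_col].isna().any():
        raise ValueError("missing fitness scores")
    genders = participants[gender_col].unique()
    counts = participants[gender_col].value_counts()
    if (counts < 2).any():
        raise ValueError("need at least 2 participants per gender")
    out = participants.copy()
    medians: dict = {}
    groups = pd.Series(index=out.index, dtype=object)
    for g in genders:
        mask = out[gender_col] == g
        med = float(out.loc[mask, score_col].median())
        medians[g] = med
        groups[mask] = np.where(
            out.loc[mask, score_col] > med, "higher", "lower"
        )
        if (groups[mask] == "lower").all():
            warnings.warn(
                f"all {g} scores at or below the median {med}; "
                "degenerate split (all assigned to 'lower')",
                stacklevel=2,
            )
    out["fitness_group"] = groups
    return out, medians


def simulate_graded_test(
    capacity_watt: float,
    protocol: GradedTestProtocol = GradedTestProtocol(),
    seed: int | np.random.Generator | None = None,
    max_hr: float = 197.0,
    rest_hr: float = 72.0,
    hr_noise_sd: float = 3.0,
) -> dict:
    """Simulate one graded test to exhaustion.

    ``capacity_watt`` is the highest load the participant can sustain for a
    full stage.  Exhaustion occurs a random fraction of the way into the
    first unsustainable stage, so ``max_watt`` (the last stage begun) is the
    quantized capacity.  Stage heart rates rise linearly with load with
    participant noise, capped at ``max_hr`` and made monotone — a simulation
    convenience, not an empirical HR model.

    Returns dict with max_duration_s, max_watt, stage_hr (list, one entry
    per stage begun).
    """
    if capacity_watt <= protocol.start_watt:
        raise ValueError(
            f"capacity {capacity_watt} W must exceed the starting load "
            f"{protocol.start_watt} W"
        )
    rng = np.random.default_rng(seed)
    n_sustained = int(
        math.floor((capacity_watt - protocol.start_watt) / protocol.increment_watt)
    ) + 1
    frac = float(rng.uniform(0.05, 0.95))
    duration = (n_sustained + frac) * protocol.stage_s
    max_watt = protocol.watt_at(duration)
    n_stages = n_sustained + 1
    watts = protocol.start_watt + protocol.increment_watt * np.arange(n_stages)
    slope = (max_hr - rest_hr) / max(capacity_watt, watts[-1])
    hr = rest_hr + slope * watts + rng.normal(0.0, hr_noise_sd, n_stages)
    hr = np.maximum.accumulate(np.minimum(hr, max_hr))
    return {
        "max_duration_s": float(duration),
        "max_watt": float(max_watt),
        "stage_hr": [float(h) for h in hr],
    }


def target_exercise_hr(max_hr: float, fraction: float = 0.6) -> float:
    """Exercise-bout target heart rate: 60% of individual maximum."""
    if max_hr <= 0:
        raise ValueError("max_hr must be positive")
    return fraction * max_hr
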