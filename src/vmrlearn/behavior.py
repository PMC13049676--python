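"""Reach-direction summaries and learning/retention metrics.

Learning amount is the mean compensatory reach direction over the late
adaptation trials (201–300) expressed as a percentage of the 30° rotation;
retention amount is the same quantity over the no-vision trials (301–500).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .task import TrialRecord, trials_to_frame

ROTATION_MAGNITUDE_DEG = 30.0


@dataclass(frozen=True)
class PhaseDefinition:
    """Trial ranges (inclusive, 1-based) of the four analysis phases.

    Only the late-adaptation and no-vision ranges are externally fixed; the
    early-adaptation and early/late no-vision splits halve their blocks.
    """

    early_adapt: tuple[int, int] = (101, 200)
    late_adapt: tuple[int, int] = (201, 300)
    early_no_vision: tuple[int, int] = (301, 400)
    late_no_vision: tuple[int, int] = (401, 500)
    full_no_vision: tuple[int, int] = (301, 500)

    def __post_init__(self) -> None:
        for name in ("early_adapt", "late_adapt", "early_no_vision", "late_no_vision"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"invalid range for {name}")


def _as_frame(trials: Sequence[TrialRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    return trials_to_frame(trials)


def _range_mean(df: pd.DataFrame, trial_range: tuple[int, int]) -> float:
    lo, hi = trial_range
    sel = df.loc[(df["trial"] >= lo) & (df["trial"] <= hi), "theta_deg"].dropna()
    if sel.empty:
        raise ValueError(f"no trials in range {trial_range}")
    return float(sel.mean())


def reach_direction(
    endpoint_xy: tuple[float, float],
    start_xy: tuple[float, float] = (0.0, 0.0),
    target_angle_deg: float = 90.0,
) -> float:
    """Signed angular reach direction where the hand crossed the 8-cm circle.

    Positive angles are clockwise of the target direction (the compensatory
    direction for a counterclockwise rotation); 0° is a reach straight at
    the target. ``target_angle_deg`` is the target's direction in standard
    math convention (default 90° = straight ahead).
    """
    dx = endpoint_xy[0] - start_xy[0]
    dy = endpoint_xy[1] - start_xy[1]
    if math.hypot(dx, dy) == 0:
        raise ValueError("endpoint coincides with start: direction undefined")
    hand_angle = math.degrees(math.atan2(dy, dx))
    # clockwise-positive difference, wrapped to (−180, 180]
    diff = target_angle_deg - hand_angle
    diff = (diff + 180.0) % 360.0 - 180.0
    return diff


def phase_means(
    trials: Sequence[TrialRecord] | pd.DataFrame,
    phases: PhaseDefinition | None = None,
) -> dict[str, float]:
    """Mean reach direction in each of the four analysis phases."""
    phases = phases or PhaseDefinition()
    df = _as_frame(trials)
    return {
        name: _range_mean(df, getattr(phases, name))
        for name in ("early_adapt", "late_adapt", "early_no_vision", "late_no_vision")
    }


def learning_amount(
    trials: Sequence[TrialRecord] | pd.DataFrame,
    phases: PhaseDefinition | None = None,
) -> float:
    """Mean reach direction over late adaptation, as % of the rotation."""
    phases = phases or PhaseDefinition()
    return _range_mean(_as_frame(trials), phases.late_adapt) / ROTATION_MAGNITUDE_DEG * 100.0


def retention_amount(
    trials: Sequence[TrialRecord] | pd.DataFrame,
    phases: PhaseDefinition | None = None,
) -> float:
    """Mean reach direction over the no-vision block, as % of the rotation."""
    phases = phases or PhaseDefinition()
    return _range_mean(_as_frame(trials), phases.full_no_vision) / ROTATION_MAGNITUDE_DEG * 100.0


def behavior_summary(
    trials: Sequence[TrialRecord] | pd.DataFrame,
    phases: PhaseDefinition | None = None,
) -> dict[str, float]:
    """Phase means plus learning/retention percentages and the final score."""
    phases = phases or PhaseDefinition()
    df = _as_frame(trials)
    out = {f"mean_{k}_deg": v for k, v in phase_means(df, phases).items()}
    out["learning_pct"] = learning_amount(df, phases)
    out["retention_pct"] = retention_amount(df, phases)
    out["total_score"] = float(df["cum_points"].iloc[-1])
    return out
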