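"""Visuomotor rotation task simulator with reward/punishment scoring.

Simulates a 550-trial session — baseline (1–100), adaptation (101–300,
30° counterclockwise cursor rotation), no-vision (301–500) and washout
(501–550) — for a single-state learner, together with the graded point
system used to deliver reward or punishment feedback during adaptation.

Sign convention: reach direction ``theta`` is positive in the clockwise
(compensatory) direction, so full compensation of the −30° rotation is
``theta = +30``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

Condition = Literal["reward", "punishment"]
SpeedLabel = Literal["ok", "slow", "fast"]
Block = Literal["baseline", "adaptation", "no_vision", "washout"]

CONDITIONS = ("reward", "punishment")
SPEED_LABELS = ("ok", "slow", "fast")

#: starting balance per condition; the running total is clipped to [0, 800]
START_POINTS: Mapping[str, int] = {"reward": 0, "punishment": 800}
MAX_POINTS = 800
MIN_POINTS = 0

# Table of per-trial points indexed by error bin:
# bin 0 = target hit, 1 = <10° error, 2 = <20°, 3 = <30°, 4 = ≥30° (worst).
_POINT_BINS = {
    "reward": (4, 3, 2, 1, 0),
    "punishment": (0, -1, -2, -3, -4),
}


@dataclass(frozen=True)
class TaskSchedule:
    """Block structure and task constants of one session."""

    n_trials: int = 550
    baseline: tuple[int, int] = (1, 100)
    adaptation: tuple[int, int] = (101, 300)
    no_vision: tuple[int, int] = (301, 500)
    washout: tuple[int, int] = (501, 550)
    rotation_deg: float = -30.0  # counterclockwise cursor rotation in adaptation
    endpoint_radius_cm: float = 8.0
    slow_threshold_mm_s: float = 312.0
    fast_threshold_mm_s: float = 469.0

    def __post_init__(self) -> None:
        ranges = [self.baseline, self.adaptation, self.no_vision, self.washout]
        covered = []
        for lo, hi in ranges:
            if lo > hi:
                raise ValueError(f"invalid block range ({lo}, {hi})")
            covered.extend(range(lo, hi + 1))
        if sorted(covered) != list(range(1, self.n_trials + 1)):
            raise ValueError("block ranges must partition 1..n_trials without overlap")
        if self.slow_threshold_mm_s >= self.fast_threshold_mm_s:
            raise ValueError("slow threshold must be below fast threshold")

    def block_of(self, trial: int) -> Block:
        for name in ("baseline", "adaptation", "no_vision", "washout"):
            lo, hi = getattr(self, name)
            if lo <= trial <= hi:
                return name  # type: ignore[return-value]
        raise ValueError(f"trial {trial} outside 1..{self.n_trials}")

    def rotation_at(self, trial: int) -> float:
        return self.rotation_deg if self.block_of(trial) == "adaptation" else 0.0


@dataclass(frozen=True)
class AdaptationParams:
    """Parameters of the single-state learner used for simulation.

    The learner keeps an internal compensation state ``u`` (degrees) that is
    updated trial-to-trial:

    * adaptation:  u ← retention_rate_adapt·u + learn_rate·(30 − u)
    * no-vision:   u ← retention_rate_no_vision·u
    * washout:     u ← retention_rate_adapt·u + learn_rate·(0 − u)

    Executed reach direction is ``u`` plus zero-mean Gaussian motor noise.
    """

    learn_rate: float = 0.15
    retention_rate_adapt: float = 1.0
    retention_rate_no_vision: float = 0.97
    motor_noise_sd_deg: float = 3.0
    hit_halfwidth_deg: float = 1.8  # ≈ atan(0.25 cm / 8 cm): target half-width
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learn_rate", "retention_rate_adapt", "retention_rate_no_vision"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.motor_noise_sd_deg < 0:
            raise ValueError("motor noise SD must be >= 0")
        if self.hit_halfwidth_deg < 0:
            raise ValueError("hit halfwidth must be >= 0")


@dataclass
class TrialRecord:
    trial: int
    block: Block
    theta_deg: float
    endpoint_error_deg: float  # NaN when no feedback is shown (no-vision block)
    max_speed_mm_s: float
    speed_label: SpeedLabel
    hit: bool
    points: int
    cum_points: int
    condition: Condition


def assign_points(
    endpoint_error_deg: float,
    hit: bool,
    speed_label: str,
    condition: str,
) -> int:
    """Per-trial points for the reward/punishment feedback scheme.

    Error bins: hit → best bin; then <10°, <20°, <30°, ≥30°. Movements
    labelled slow or fast count as the worst bin regardless of accuracy.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if speed_label not in SPEED_LABELS:
        raise ValueError(f"unknown speed label {speed_label!r}")
    bins = _POINT_BINS[condition]
    if speed_label != "ok":
        return bins[4]
    if hit:
        return bins[0]
    err = float(endpoint_error_deg)
    if err < 0 or not math.isfinite(err):
        raise ValueError("endpoint error must be finite and >= 0")
    if err < 10:
        return bins[1]
    if err < 20:
        return bins[2]
    if err < 30:
        return bins[3]
    return bins[4]


def session_total(per_trial_points: Iterable[int], condition: str) -> int:
    """Accumulate points from the condition's starting balance, clipping the
    running total to [0, 800] after every trial."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    total = START_POINTS[condition]
    for p in per_trial_points:
        total = min(MAX_POINTS, max(MIN_POINTS, total + int(p)))
    return total


def _draw_speed(rng: np.random.Generator, schedule: TaskSchedule) -> float:
    """Valid-speed draw: normal between the slow/fast thresholds, resampled
    until inside (truncation). Slow/fast events occur only via injection."""
    lo, hi = schedule.slow_threshold_mm_s, schedule.fast_threshold_mm_s
    mu, sd = 0.5 * (lo + hi), (hi - lo) / 6.0
    for _ in range(1000):
        v = rng.normal(mu, sd)
        if lo < v < hi:
            return v
    return mu


def simulate_participant(
    schedule: TaskSchedule,
    params: AdaptationParams,
    condition: str,
    speed_injection: Mapping[int, str] | None = None,
) -> list[TrialRecord]:
    """Simulate one participant's 550-trial session.

    ``speed_injection`` maps trial numbers to forced labels ("slow"/"fast")
    to emulate the rare invalid-speed trials; all other trials are valid.
    Points are awarded only during the adaptation block. In the no-vision
    block no endpoint feedback exists, so endpoint error is NaN and ``hit``
    is False.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    speed_injection = dict(speed_injection or {})
    rng = np.random.default_rng(params.seed)
    target = -schedule.rotation_deg  # +30° compensation during adaptation

    u = 0.0
    cum = START_POINTS[condition]
    records: list[TrialRecord] = []
    for trial in range(1, schedule.n_trials + 1):
        block = schedule.block_of(trial)
        noise = rng.normal(0.0, params.motor_noise_sd_deg) if params.motor_noise_sd_deg else 0.0
        theta = u + noise

        label = speed_injection.get(trial, "ok")
        if label == "ok":
            speed = _draw_speed(rng, schedule)
        elif label == "slow":
            speed = 0.9 * schedule.slow_threshold_mm_s
        elif label == "fast":
            speed = 1.1 * schedule.fast_threshold_mm_s
        else:
            raise ValueError(f"unknown injected speed label {label!r}")

        if block == "no_vision":
            error = math.nan
            hit = False
            points = 0
        else:
            # cursor = hand + rotation; target at 0 → angular miss of cursor
            error = abs(theta + schedule.rotation_at(trial))
            hit = error <= params.hit_halfwidth_deg and label == "ok"
            points = (
                assign_points(error, error <= params.hit_halfwidth_deg, label, condition)
                if block == "adaptation"
                else 0
            )
        cum = min(MAX_POINTS, max(MIN_POINTS, cum + points))
        records.append(
            TrialRecord(
                trial=trial,
                block=block,
                theta_deg=theta,
                endpoint_error_deg=error,
                max_speed_mm_s=speed,
                speed_label=label,  # type: ignore[arg-type]
                hit=hit,
                points=points,
                cum_points=cum,
                condition=condition,  # type: ignore[arg-type]
            )
        )

        if block == "adaptation":
            u = params.retention_rate_adapt * u + params.learn_rate * (target - u)
        elif block == "no_vision":
            u = params.retention_rate_no_vision * u
        elif block == "washout":
            u = params.retention_rate_adapt * u + params.learn_rate * (0.0 - u)
        # baseline: veridical feedback, state stays at 0

    return records


def trials_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tidy trial table, one row per trial."""
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# Cohort generation with planted individual-difference structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """Planted mapping from late-adaptation alpha ERD to retention.

    Retention target (%) = ``intercept_pct`` + ``slope_per_erd_pct`` ×
    (condition × late alpha ERD) + N(0, ``noise_sd_pct``), with condition
    coded 1 for reward and 0 for punishment, so the ERD–retention link
    exists only in the reward group. Defaults reproduce the final-model
    coefficients (intercept 35.7, slope 0.34) with residual spread chosen
    so the interaction explains roughly a third of retention variance.
    """

    intercept_pct: float = 35.7
    slope_per_erd_pct: float = 0.34
    noise_sd_pct: float = 14.0


@dataclass(frozen=True)
class FeatureDistributions:
    """Population distributions of the planted EEG features.

    ERD values are percentages (positive = desynchronization); FRN is the
    success-minus-failure difference-wave amplitude in microvolts
    (typically negative). ``meas_sd_*`` is the extraction/measurement noise
    added to the ground truth when features are read out without running
    the full EEG pipeline.
    """

    alpha_mean: float = 50.0
    alpha_sd: float = 15.0
    alpha_late_shift: float = 5.0
    beta_mean: float = 40.0
    beta_sd: float = 12.0
    beta_late_shift: float = 4.0
    frn_mean: float = -3.0
    frn_sd: float = 2.0
    frn_late_shift: float = 1.0
    #: early/late test-retest correlation of each feature (shared-component
    #: construction); band-power and ERP features are only moderately stable
    #: across task phases within a session
    test_retest_rho: float = 0.5
    erd_clip: tuple[float, float] = (5.0, 95.0)
    #: measurement noise matched to the EEG extractors' recovery error on
    #: noisy synthetic epochs (ERD points / microvolts)
    meas_sd_erd: float = 2.0
    meas_sd_frn: float = 0.5


@dataclass
class Participant:
    pid: int
    condition: Condition
    params: AdaptationParams
    trials: list[TrialRecord]
    truth: dict
    measured: dict


def _geometric_mean_factor(r: float, n: int = 200) -> float:
    """Mean of r, r², …, r**n — fraction of the initial state retained on
    average over an n-trial geometric decay."""
    if r >= 1.0:
        return 1.0
    if r <= 0.0:
        return 0.0
    return r * (1.0 - r**n) / (n * (1.0 - r))


def _invert_retention_rate(target_fraction: float, n: int = 200) -> float:
    """Decay rate whose n-trial geometric mean equals ``target_fraction``."""
    if target_fraction >= _geometric_mean_factor(1.0 - 1e-12, n):
        return 1.0
    if target_fraction <= 0.0:
        return 0.0
    return brentq(lambda r: _geometric_mean_factor(r, n) - target_fraction, 1e-9, 1.0 - 1e-12)


def _asymptote_deg(lr: float, ra: float, target: float = 30.0) -> float:
    denom = lr + 1.0 - ra
    return target * lr / denom if denom > 0 else target


def simulate_cohort(
    n_per_group: int = 32,
    effect: EffectSpec | None = None,
    seed: int = 0,
    features: FeatureDistributions | None = None,
    schedule: TaskSchedule | None = None,
    motor_noise_sd_deg: float = 3.0,
) -> list[Participant]:
    """Simulate a two-group cohort with planted, recoverable ground truth.

    Each participant carries ground-truth alpha/beta ERD and FRN values for
    the early and late adaptation phases, a retention target generated from
    ``effect`` (reward-group-only dependence on late alpha ERD), behavior
    simulated so that the measured retention matches that target, and
    noisy "measured" feature values emulating EEG extraction error.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 participants per group")
    effect = effect or EffectSpec()
    fd = features or FeatureDistributions()
    schedule = schedule or TaskSchedule()
    rng = np.random.default_rng(seed)

    if fd.alpha_sd == 0:
        warnings.warn("degenerate effect spec: zero variance in planted alpha ERD", stacklevel=2)

    def _early_late(mean: float, sd: float, shift: float) -> tuple[float, float]:
        # shared/independent component mix -> corr(early, late) = rho
        a, b = np.sqrt(fd.test_retest_rho), np.sqrt(1.0 - fd.test_retest_rho)
        shared = rng.standard_normal()
        early = mean + sd * (a * shared + b * rng.standard_normal())
        late = mean + shift + sd * (a * shared + b * rng.standard_normal())
        return early, late

    participants: list[Participant] = []
    conditions = ["reward"] * n_per_group + ["punishment"] * n_per_group
    for pid, condition in enumerate(conditions):
        lo, hi = fd.erd_clip
        alpha_early, alpha_late = _early_late(fd.alpha_mean, fd.alpha_sd, fd.alpha_late_shift)
        alpha_early, alpha_late = float(np.clip(alpha_early, lo, hi)), float(np.clip(alpha_late, lo, hi))
        beta_early, beta_late = _early_late(fd.beta_mean, fd.beta_sd, fd.beta_late_shift)
        beta_early, beta_late = float(np.clip(beta_early, lo, hi)), float(np.clip(beta_late, lo, hi))
        frn_early, frn_late = _early_late(fd.frn_mean, fd.frn_sd, fd.frn_late_shift)

        code = 1.0 if condition == "reward" else 0.0
        retention_target = (
            effect.intercept_pct
            + effect.slope_per_erd_pct * code * alpha_late
            + rng.normal(0.0, effect.noise_sd_pct)
        )
        retention_target = float(np.clip(retention_target, 1.0, 99.0))

        lr = rng.uniform(0.1, 0.3)
        ra = rng.uniform(0.97, 1.0)
        u_late = _asymptote_deg(lr, ra)
        achievable = u_late / 30.0 * 100.0
        planted_retention = min(retention_target, achievable)
        r_nv = _invert_retention_rate(planted_retention / achievable)

        params = AdaptationParams(
            learn_rate=lr,
            retention_rate_adapt=ra,
            retention_rate_no_vision=r_nv,
            motor_noise_sd_deg=motor_noise_sd_deg,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        trials = simulate_participant(schedule, params, condition)

        truth = {
            "alpha_erd_early": alpha_early,
            "alpha_erd_late": alpha_late,
            "beta_erd_early": beta_early,
            "beta_erd_late": beta_late,
            "frn_early": frn_early,
            "frn_late": frn_late,
            "retention_target_pct": planted_retention,
            "learn_rate": lr,
            "retention_rate_adapt": ra,
            "retention_rate_no_vision": r_nv,
        }
        measured = {
            "alpha_erd_early": alpha_early + rng.normal(0, fd.meas_sd_erd),
            "alpha_erd_late": alpha_late + rng.normal(0, fd.meas_sd_erd),
            "beta_erd_early": beta_early + rng.normal(0, fd.meas_sd_erd),
            "beta_erd_late": beta_late + rng.normal(0, fd.meas_sd_erd),
            "frn_early": frn_early + rng.normal(0, fd.meas_sd_frn),
            "frn_late": frn_late + rng.normal(0, fd.meas_sd_frn),
        }
        participants.append(
            Participant(
                pid=pid,
                condition=condition,  # type: ignore[arg-type]
                params=params,
                trials=trials,
                truth=truth,
                measured=measured,
            )
        )
    return participants
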