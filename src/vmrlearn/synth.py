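"""Synthetic epoched EEG with planted, recoverable ground truth.

Go-cue-locked epochs span −3 to +4 s and carry alpha/beta oscillations
over a C3-centered sensorimotor cluster whose amplitude drops in the
movement-preparatory window (−1 to 0 s) by a planted event-related
desynchronization percentage. Feedback-locked epochs span −0.2 to +0.6 s
and carry a smooth outcome-dependent component whose success-minus-failure
difference wave has a planted mean amplitude in the 200–350 ms window at a
fronto-central cluster. A 1/f background can be added everywhere;
channels outside the target cluster carry background only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .eeg import EpochedEEG

#: left sensorimotor cluster: C3 and its six surrounding channels
DEFAULT_C3_CLUSTER = ["C3", "FC3", "FC5", "C1", "C5", "CP3", "CP5"]
#: fronto-central cluster: FCz and its surrounding 7 electrodes
DEFAULT_FCZ_CLUSTER = ["FCz", "Fz", "Cz", "FC1", "FC2", "F1", "F2", "AFz"]
#: extra non-cluster channels (mastoids included for re-referencing)
DEFAULT_EXTRA_CHANNELS = ["Pz", "Oz", "M1", "M2"]

ALPHA_BAND = (8.0, 13.0)
BETA_BAND = (15.0, 30.0)


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-phase feature values.

    ERD percentages are positive for desynchronization and must not exceed
    100 (the preparatory amplitude scales by sqrt(1 − ERD/100)). FRN values
    are the planted mean of the success-minus-failure difference wave in
    the 200–350 ms window, in microvolts.
    """

    alpha_erd_pct: Mapping[str, float]
    beta_erd_pct: Mapping[str, float]
    frn_uv: Mapping[str, float]
    alpha_hz: float = 10.0
    beta_hz: float = 22.0
    alpha_amp_uv: float = 10.0
    beta_amp_uv: float = 5.0
    alpha_band: tuple[float, float] = ALPHA_BAND
    beta_band: tuple[float, float] = BETA_BAND

    def __post_init__(self) -> None:
        for m in (self.alpha_erd_pct, self.beta_erd_pct):
            for phase, v in m.items():
                if v > 100:
                    raise ValueError(f"ERD {v}% > 100% in phase {phase!r}: amplitude would be imaginary")
        if not ALPHA_BAND[0] <= self.alpha_hz <= ALPHA_BAND[1]:
            raise ValueError("alpha center frequency outside the 8-13 Hz band")
        if not BETA_BAND[0] <= self.beta_hz <= BETA_BAND[1]:
            raise ValueError("beta center frequency outside the 15-30 Hz band")


def pink_noise(
    n_samples: int,
    rng: np.random.Generator,
    exponent: float = 1.0,
    size: tuple[int, ...] = (),
) -> np.ndarray:
    """Unit-variance 1/f^exponent noise, generated by spectral shaping."""
    shape = size + (n_samples,)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _raised_cosine_step(t: np.ndarray, start: float, width: float) -> np.ndarray:
    """Smooth 0→1 transition over [start, start+width]."""
    s = np.clip((t - start) / width, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * s))


def _prep_envelope(
    t: np.ndarray, erd_pct: float, ramp_s: float = 0.2, release_s: float = 1.0
) -> np.ndarray:
    """Amplitude envelope of the planted sensorimotor rhythm.

    Full amplitude during the reference period, dropping to
    sqrt(1 − ERD/100) from −1 s (movement preparation) with a raised-cosine
    ramp placed just inside the window so the reference period keeps full
    amplitude. The suppression persists through movement execution
    (desynchronization does not rebound at movement onset) and releases at
    ``release_s`` after the go cue."""
    f = np.sqrt(max(0.0, 1.0 - erd_pct / 100.0))
    down = _raised_cosine_step(t, -1.0, ramp_s)  # onset just inside the window
    up = _raised_cosine_step(t, release_s, ramp_s)  # rebound after movement
    gate = down * (1.0 - up)
    return 1.0 + (f - 1.0) * gate


def _band_comb(
    t: np.ndarray,
    band: tuple[float, float],
    amp_uv: float,
    trial_index: int,
    n_trials: int,
    q_offset: int = 0,
) -> np.ndarray:
    """Band-limited oscillation: an equal-amplitude comb of integer-hertz
    tones spanning the band.

    A physiological rhythm occupies its whole band rather than a single
    line, and the comb gives every 1-Hz analysis bin direct spectral
    support, so power ratios are well defined band-wide. Tone phases
    follow an equispaced per-trial schedule (tone j in trial i has phase
    2π·(q_offset+j)·i/n_trials), which makes all cross-tone interference
    terms cancel exactly in the trial-averaged power: the average spectrum
    is deterministic, not a sampling estimate.
    """
    tones = np.arange(int(np.ceil(band[0])), int(np.floor(band[1])) + 1)
    per_tone = amp_uv / np.sqrt(len(tones))
    out = np.zeros_like(t)
    for j, f0 in enumerate(tones):
        phase = 2.0 * np.pi * (q_offset + j) * trial_index / n_trials
        out += per_tone * np.sin(2.0 * np.pi * f0 * t + phase)
    return out


def generate_go_epochs(
    gt: GroundTruth,
    phase: str,
    n_trials: int,
    noise_sd_uv: float = 2.0,
    seed: int = 0,
    srate: float = 1000.0,
    cluster: Sequence[str] | None = None,
    extra_channels: Sequence[str] | None = None,
    noise_exponent: float = 1.0,
) -> EpochedEEG:
    """Go-cue-locked epochs (−3 to +4 s) with planted alpha/beta ERD."""
    if n_trials < 1:
        raise ValueError("need at least one trial")
    cluster = list(cluster if cluster is not None else DEFAULT_C3_CLUSTER)
    extra = list(extra_channels if extra_channels is not None else DEFAULT_EXTRA_CHANNELS)
    channels = cluster + extra
    rng = np.random.default_rng(seed)

    n_samples = int(round(7.0 * srate))
    t = -3.0 + np.arange(n_samples) / srate

    env_a = _prep_envelope(t, float(gt.alpha_erd_pct[phase]))
    env_b = _prep_envelope(t, float(gt.beta_erd_pct[phase]))

    n_alpha_tones = int(np.floor(gt.alpha_band[1])) - int(np.ceil(gt.alpha_band[0])) + 1
    data = np.zeros((n_trials, len(channels), n_samples))
    for i in range(n_trials):
        osc = env_a * _band_comb(t, gt.alpha_band, gt.alpha_amp_uv, i, n_trials)
        osc = osc + env_b * _band_comb(
            t, gt.beta_band, gt.beta_amp_uv, i, n_trials, q_offset=n_alpha_tones
        )
        data[i, : len(cluster), :] = osc
    if noise_sd_uv > 0:
        data += noise_sd_uv * pink_noise(
            n_samples, rng, noise_exponent, size=(n_trials, len(channels))
        )

    return EpochedEEG(
        data=data,
        srate=srate,
        t0_offset_s=-3.0,
        channels=channels,
        event_kind="go_cue",
        trial_labels=[phase] * n_trials,
        meta={
            "phase": phase,
            "seed": seed,
            "ground_truth": {
                "alpha_erd_pct": float(gt.alpha_erd_pct[phase]),
                "beta_erd_pct": float(gt.beta_erd_pct[phase]),
                "alpha_hz": gt.alpha_hz,
                "beta_hz": gt.beta_hz,
            },
        },
    )


def _frn_template(t: np.ndarray, frn_uv: float, center_s: float = 0.275, sd_s: float = 0.04) -> np.ndarray:
    """Smooth component peaking inside 200–350 ms, scaled so its mean over
    the [0.2, 0.35] s window equals ``frn_uv`` exactly."""
    g = np.exp(-0.5 * ((t - center_s) / sd_s) ** 2)
    win = (t >= 0.2 - 1e-9) & (t <= 0.35 + 1e-9)
    return frn_uv * g / g[win].mean()


def generate_feedback_epochs(
    gt: GroundTruth,
    phase: str,
    outcome_labels: Sequence[str],
    noise_sd_uv: float = 2.0,
    seed: int = 0,
    srate: float = 1000.0,
    cluster: Sequence[str] | None = None,
    extra_channels: Sequence[str] | None = None,
    noise_exponent: float = 1.0,
    common_erp_uv: float = 4.0,
) -> EpochedEEG:
    """Feedback-locked epochs (−0.2 to +0.6 s) with a planted FRN.

    The noiseless success-minus-failure difference wave over the cluster
    has mean amplitude ``gt.frn_uv[phase]`` within 200–350 ms; a common
    outcome-independent evoked component (cancelled by the difference) is
    added for realism.
    """
    labels = list(outcome_labels)
    if not labels:
        raise ValueError("outcome labels must be nonempty")
    classes = set(labels)
    if not classes <= {"success", "failure"}:
        raise ValueError(f"unknown outcome labels {sorted(classes - {'success', 'failure'})}")
    if len(classes) < 2:
        raise ValueError("both success and failure trials are required for a difference wave")

    cluster = list(cluster if cluster is not None else DEFAULT_FCZ_CLUSTER)
    extra = list(extra_channels if extra_channels is not None else DEFAULT_EXTRA_CHANNELS)
    channels = cluster + extra
    rng = np.random.default_rng(seed)

    n_samples = int(round(0.8 * srate))
    t = -0.2 + np.arange(n_samples) / srate

    diff = _frn_template(t, float(gt.frn_uv[phase]))
    common = common_erp_uv * np.exp(-0.5 * ((t - 0.3) / 0.08) ** 2)

    data = np.zeros((len(labels), len(channels), n_samples))
    for i, lab in enumerate(labels):
        sign = +0.5 if lab == "success" else -0.5
        data[i, : len(cluster), :] = common + sign * diff
    if noise_sd_uv > 0:
        data += noise_sd_uv * pink_noise(
            n_samples, rng, noise_exponent, size=(len(labels), len(channels))
        )

    return EpochedEEG(
        data=data,
        srate=srate,
        t0_offset_s=-0.2,
        channels=channels,
        event_kind="feedback",
        trial_labels=labels,
        meta={
            "phase": phase,
            "seed": seed,
            "ground_truth": {"frn_uv": float(gt.frn_uv[phase])},
        },
    )
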