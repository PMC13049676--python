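"""Event-related desynchronization: time-frequency power and peak features.

Power is estimated with a 1-s Hanning-tapered sliding window advancing in
0.1-s steps (90% overlap), averaged across trials; ERD is the percentage
power decrease relative to the mean spectrum of a pre-movement reference
period, ``ERD(f,t) = (R(f) − A(f,t)) / R(f) × 100`` (positive =
desynchronization). Peak ERD is located in the preparatory window (−1 to
0 s) separately per band and averaged over ±0.2 s × ±2 Hz around the peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .eeg import EpochedEEG

_TOL = 1e-9


@dataclass
class TimeFrequencyMap:
    power: np.ndarray  # (n_freqs, n_times) trial-averaged PSD, µV²/Hz
    erd_pct: np.ndarray  # (n_freqs, n_times), %
    freqs: np.ndarray  # Hz
    times: np.ndarray  # s, window centers
    ref_power: np.ndarray  # (n_freqs,), mean PSD over the reference window


@dataclass
class ERDFeature:
    band: tuple[float, float]
    phase: str | None
    peak_time_s: float
    peak_freq_hz: float
    value_pct: float


def bandpass(epochs: EpochedEEG, low_hz: float, high_hz: float, order: int = 4) -> EpochedEEG:
    """Zero-phase Butterworth band-pass applied per trial and channel."""
    nyq = epochs.srate / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz must lie inside (0, {nyq}) Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=epochs.srate, output="sos")
    padlen = min(3 * (2 * order + 1), epochs.n_samples - 1)
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1, padlen=padlen)
    return epochs.copy_with(filtered)


def rereference(
    epochs: EpochedEEG,
    scheme: str = "common_average",
    mastoids: Sequence[str] = ("M1", "M2"),
) -> EpochedEEG:
    """Re-reference to the common average or to linked mastoids."""
    if scheme == "common_average":
        ref = epochs.data.mean(axis=1, keepdims=True)
    elif scheme == "linked_mastoids":
        try:
            idx = [epochs.channel_index(m) for m in mastoids]
        except KeyError as exc:
            raise ValueError(f"mastoid channel missing: {exc}") from None
        ref = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown re-referencing scheme {scheme!r}")
    return epochs.copy_with(epochs.data - ref)


def cluster_average(epochs: EpochedEEG, channel_list: Sequence[str]) -> EpochedEEG:
    """Sample-wise mean over the listed channels, as a one-channel epoch set."""
    idx = [epochs.channel_index(c) for c in channel_list]
    mean = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    return epochs.copy_with(mean, channels=["+".join(channel_list)])


def tf_power(
    epochs: EpochedEEG,
    win_s: float = 1.0,
    step_s: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trial-averaged sliding-window Hanning PSD of single-channel epochs.

    Returns ``(power, freqs, times)`` with power shaped (n_freqs, n_times).
    Windows whose 1-s support would extend beyond the epoch are dropped.
    Frequency resolution is 1/win_s (1 Hz for the default 1-s window).
    """
    if epochs.data.shape[1] != 1:
        raise ValueError("tf_power expects single-channel epochs; apply cluster_average first")
    L = int(round(win_s * epochs.srate))
    hop = int(round(step_s * epochs.srate))
    if L > epochs.n_samples:
        raise ValueError("epoch shorter than one analysis window")
    x = epochs.data[:, 0, :]  # (n_trials, n_samples)
    win = signal.get_window("hann", L, fftbins=True)
    segs = sliding_window_view(x, L, axis=-1)[:, ::hop, :]  # (n_trials, n_win, L)
    spec = np.fft.rfft(segs * win, axis=-1)
    # one-sided PSD scaling
    scale = 2.0 / (epochs.srate * (win**2).sum())
    psd = (np.abs(spec) ** 2) * scale
    psd[..., 0] /= 2.0
    if L % 2 == 0:
        psd[..., -1] /= 2.0
    power = psd.mean(axis=0).T  # (n_freqs, n_windows)
    freqs = np.fft.rfftfreq(L, d=1.0 / epochs.srate)
    starts = np.arange(segs.shape[1]) * hop
    times = epochs.t0_offset_s + (starts + L / 2.0) / epochs.srate
    return power, freqs, times


def erd_map(
    power: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    ref_window: tuple[float, float] = (-2.0, -1.0),
    rel_floor: float = 1e-2,
) -> TimeFrequencyMap:
    """ERD percentage map relative to the reference-period mean spectrum.

    The reference comprises window centers in [ref_lo, ref_hi): half-open
    at the boundary shared with the preparatory window, so the window
    centered exactly on the boundary (whose support reaches 0.5 s into the
    preparatory period) does not leak desynchronization into the baseline.

    The power ratio is meaningless at frequencies whose reference spectrum
    carries essentially no energy (for a narrowband signal, bins outside
    its spectral support hold only taper leakage); rows with reference
    power below ``rel_floor`` of the spectrum's maximum are therefore
    marked NaN and ignored by the peak extractor.
    """
    lo, hi = ref_window
    mask = (times >= lo - _TOL) & (times < hi - _TOL)
    if not mask.any():
        raise ValueError("reference window not covered by the time axis")
    ref = power[:, mask].mean(axis=1)
    if np.all(ref == 0):
        raise ValueError("reference power is zero everywhere: ERD undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        erd = (ref[:, None] - power) / ref[:, None] * 100.0
    degenerate = ref < rel_floor * ref.max()
    if degenerate.all():
        raise ValueError("reference power is degenerate at every frequency: ERD undefined")
    if degenerate.any():
        erd[degenerate, :] = np.nan
    return TimeFrequencyMap(
        power=power, erd_pct=erd, freqs=np.asarray(freqs), times=np.asarray(times), ref_power=ref
    )


def extract_peak_erd(
    tfmap: TimeFrequencyMap,
    band: tuple[float, float],
    search_window: tuple[float, float] = (-1.0, 0.0),
    phase: str | None = None,
    avg_halfwidth_s: float = 0.2,
    avg_halfwidth_hz: float = 2.0,
) -> ERDFeature:
    """Peak ERD in band × search window, averaged over ±0.2 s × ±2 Hz.

    The peak is the first-occurring maximum in (frequency, time) scan
    order; the averaging neighborhood is inclusive of its endpoints and is
    truncated at the map edges.
    """
    fmask = (tfmap.freqs >= band[0] - _TOL) & (tfmap.freqs <= band[1] + _TOL)
    tmask = (tfmap.times >= search_window[0] - _TOL) & (tfmap.times <= search_window[1] + _TOL)
    if not fmask.any() or not tmask.any():
        raise ValueError("empty search region for peak ERD")
    sub = tfmap.erd_pct[np.ix_(fmask, tmask)]
    if np.all(np.isnan(sub)):
        raise ValueError("search region is entirely undefined (NaN)")
    flat = np.nanargmax(sub)
    fi, ti = np.unravel_index(flat, sub.shape)
    peak_freq = float(tfmap.freqs[fmask][fi])
    peak_time = float(tfmap.times[tmask][ti])

    nf = (tfmap.freqs >= peak_freq - avg_halfwidth_hz - _TOL) & (
        tfmap.freqs <= peak_freq + avg_halfwidth_hz + _TOL
    )
    nt = (tfmap.times >= peak_time - avg_halfwidth_s - _TOL) & (
        tfmap.times <= peak_time + avg_halfwidth_s + _TOL
    )
    value = float(np.nanmean(tfmap.erd_pct[np.ix_(nf, nt)]))
    return ERDFeature(
        band=band, phase=phase, peak_time_s=peak_time, peak_freq_hz=peak_freq, value_pct=value
    )


def erd_features_from_epochs(
    epochs: EpochedEEG,
    cluster: Sequence[str],
    bands: dict[str, tuple[float, float]] | None = None,
    ref_window: tuple[float, float] = (-2.0, -1.0),
    phase: str | None = None,
) -> dict[str, ERDFeature]:
    """Cluster-average → sliding-window power → ERD map → per-band peaks."""
    bands = bands or {"alpha": (8.0, 13.0), "beta": (15.0, 30.0)}
    clustered = cluster_average(epochs, cluster)
    power, freqs, times = tf_power(clustered)
    tfmap = erd_map(power, freqs, times, ref_window)
    return {
        name: extract_peak_erd(tfmap, band, phase=phase) for name, band in bands.items()
    }
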