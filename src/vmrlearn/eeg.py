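"""Epoched EEG container and its on-disk representation.

Epochs are stored as a trials × channels × samples array in microvolts.
On disk an epoch set is a raw row-major float32 binary file plus a JSON
sidecar holding shape, sampling rate, epoch timing, channel labels and
per-trial labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np


@dataclass
class EpochedEEG:
    data: np.ndarray  # (n_trials, n_channels, n_samples), microvolts
    srate: float
    t0_offset_s: float  # time of sample 0 relative to the event
    channels: list[str]
    event_kind: str  # "go_cue" or "feedback"
    trial_labels: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel labels")
        if self.trial_labels is not None and len(self.trial_labels) != self.data.shape[0]:
            raise ValueError("trial_labels length does not match trial axis")
        if self.srate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the event."""
        return self.t0_offset_s + np.arange(self.n_samples) / self.srate

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None

    def copy_with(self, data: np.ndarray, channels: list[str] | None = None) -> "EpochedEEG":
        return replace(self, data=data, channels=channels if channels is not None else list(self.channels))

    # -- persistence --------------------------------------------------------

    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.bin`` (row-major float32) and ``<prefix>.json``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        bin_path = prefix.with_suffix(".bin")
        json_path = prefix.with_suffix(".json")
        np.ascontiguousarray(self.data, dtype=np.float32).tofile(bin_path)
        sidecar = {
            "shape": list(self.data.shape),
            "dtype": "float32",
            "order": "C",
            "srate": self.srate,
            "t0_offset_s": self.t0_offset_s,
            "channels": self.channels,
            "event_kind": self.event_kind,
            "trial_labels": self.trial_labels,
            "meta": self.meta,
        }
        json_path.write_text(json.dumps(sidecar, indent=1))
        return bin_path, json_path

    @classmethod
    def load(cls, prefix: str | Path) -> "EpochedEEG":
        prefix = Path(prefix)
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        shape = tuple(sidecar["shape"])
        data = np.fromfile(prefix.with_suffix(".bin"), dtype=np.float32).reshape(shape)
        return cls(
            data=data.astype(float),
            srate=sidecar["srate"],
            t0_offset_s=sidecar["t0_offset_s"],
            channels=list(sidecar["channels"]),
            event_kind=sidecar["event_kind"],
            trial_labels=sidecar["trial_labels"],
            meta=sidecar.get("meta", {}),
        )
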