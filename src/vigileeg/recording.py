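"""Core container for multi-channel scalp EEG.

Channels follow the international 10-20 placement; only the eight dry-electrode
sites used by wearable vigilance headsets are accepted: pre-frontal (Fp1, Fp2),
temporal (T3, T4), central (C3, C4) and occipital (O1, O2).  Samples are in
microvolts (µV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recognised 10-20 electrode labels, in canonical order.
CHANNELS_1020 = ("Fp1", "Fp2", "T3", "T4", "C3", "C4", "O1", "O2")

#: Pre-frontal sites that carry blink artifacts.
PREFRONTAL = ("Fp1", "Fp2")

#: Occipital sites where the drowsiness band-power contrast is expressed.
OCCIPITAL = ("O1", "O2")


@dataclass
class EEGRecording:
    """Multi-channel sampled EEG signal.

    Parameters
    ----------
    fs : int
        Sampling rate in Hz (positive; 512 for the target hardware).
    channels : tuple of str
        Ordered, unique labels from :data:`CHANNELS_1020`.
    data : ndarray, shape (n_channels, n_samples)
        Per-channel samples in µV; all channels equal length.
    meta : dict
        Free-form provenance (seed, schedule, source file, ...).
    """

    fs: int
    channels: tuple
    data: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.channels = tuple(self.channels)
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        unknown = [c for c in self.channels if c not in CHANNELS_1020]
        if unknown:
            raise ValueError(
                f"unknown channel label(s) {unknown}; expected a subset of "
                f"{CHANNELS_1020}"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel labels")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data must be (n_channels, n_samples); got shape "
                f"{self.data.shape} for {len(self.channels)} channels"
            )
        if self.data.shape[1] < self.fs:
            raise ValueError("recording must hold at least one full second")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def n_seconds(self) -> int:
        """Number of whole seconds (trailing partial second discarded)."""
        return self.n_samples // self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples by 10-20 label."""
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in recording ({self.channels})"
            ) from None
        return self.data[idx]

    def copy_with(self, data: np.ndarray, **meta) -> "EEGRecording":
        return EEGRecording(
            fs=self.fs,
            channels=self.channels,
            data=data,
            meta={**self.meta, **meta},
        )
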