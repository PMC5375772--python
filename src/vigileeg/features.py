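"""Per-second spectral features for vigilance classification.

Each whole second of a (denoised) channel is turned into a one-sided power
spectral density via a Hanning-windowed FFT, converted to a log10 scale, and
summarised as the log power in the three classical rhythm bands used for
drowsiness staging: theta (4-8 Hz), alpha (8-14 Hz) and beta (14-34 Hz).
The feature at time t averages the band-power vectors of seconds t-r ... t
(the "time window" r), reflecting the assumption that the driver's state is
constant over the preceding r seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import periodogram

#: Floor applied to linear power before taking log10 (avoids -inf on silence).
LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class RhythmBand:
    """A named frequency band, half-open: low <= f < high (Hz)."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError(f"require 0 < low < high, got [{self.low}, {self.high})")

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.low) & (freqs < self.high)


#: Default rhythm bands. Half-open intervals resolve the shared 8 Hz and
#: 14 Hz edges; the three bands tile [4, 34) without overlap.
DEFAULT_BANDS = (
    RhythmBand("theta", 4.0, 8.0),
    RhythmBand("alpha", 8.0, 14.0),
    RhythmBand("beta", 14.0, 34.0),
)


@dataclass
class EpochPSD:
    """One-sided log10 PSD of a single one-second epoch.

    ``freqs`` are the bin centres (resolution fs/N; 1 Hz for one-second
    epochs), ``log_psd`` the per-bin log10 power. The linear power is
    recoverable as ``10 ** log_psd`` (values at the floor represent silence).
    """

    epoch_index: int
    freqs: np.ndarray
    log_psd: np.ndarray

    @property
    def linear_psd(self) -> np.ndarray:
        return 10.0 ** self.log_psd


@dataclass
class FeatureMatrix:
    """Band-power feature vectors x_i with labels y_i in {+1, -1}.

    One row per labelled second t >= r; ``r`` is the averaging window in
    seconds, ``channel`` the 10-20 label the features came from. ``scaling``
    holds the per-dimension (min, max) of the training data when the matrix
    has been scaled (see :func:`scale_features`).
    """

    X: np.ndarray
    y: np.ndarray
    r: int
    channel: str
    band_names: tuple
    t_index: np.ndarray
    scaling: Optional[np.ndarray] = None  # shape (2, n_dims): row 0 min, row 1 max

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite feature values")
        if self.r < 0:
            raise ValueError("r must be a non-negative integer")
        if len(self.y) and not np.all(np.isin(self.y, (-1, 1))):
            raise ValueError("labels must be +1 (alert) or -1 (drowsy)")

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n_dims(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X[idx],
            y=self.y[idx],
            r=self.r,
            channel=self.channel,
            band_names=self.band_names,
            t_index=self.t_index[idx],
            scaling=self.scaling,
        )


def epoch_psd(segment: np.ndarray, fs: int, epoch_index: int = 0) -> EpochPSD:
    """One-sided log10 PSD of a single one-second segment.

    The segment is Hanning-windowed and the periodogram scaled so the sum of
    linear bins times the 1-Hz bin width estimates the signal power (window
    power correction); linear powers are floored at ``LOG_FLOOR`` before the
    log.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1 or len(segment) != fs:
        raise ValueError(
            f"epoch must be exactly one second ({fs} samples), got {segment.shape}"
        )
    freqs, psd = periodogram(segment, fs=fs, window="hann", scaling="density")
    # bin width is fs/N = 1 Hz for one-second epochs, so density == per-bin power
    log_psd = np.log10(np.maximum(psd, LOG_FLOOR))
    return EpochPSD(epoch_index=epoch_index, freqs=freqs, log_psd=log_psd)


def band_power(psd: EpochPSD, band: RhythmBand) -> float:
    """log10 of the summed linear power in ``band`` (half-open [low, high))."""
    nyq = psd.freqs[-1]
    if band.low >= nyq or band.high > nyq + 1e-9:
        raise ValueError(
            f"band [{band.low}, {band.high}) outside spectrum [0, {nyq}]"
        )
    mask = band.contains(psd.freqs)
    linear = psd.linear_psd[mask]
    # bins at the silence floor carry no real power; keep the floor on the sum
    linear = np.where(psd.log_psd[mask] <= np.log10(LOG_FLOOR), 0.0, linear)
    total = float(np.sum(linear))
    return float(np.log10(max(total, LOG_FLOOR)))


def band_power_vector(psd: EpochPSD, bands: Sequence[RhythmBand]) -> np.ndarray:
    return np.array([band_power(psd, b) for b in bands])


def feature_at_time(
    psd_series: Sequence[EpochPSD],
    t: int,
    r: int,
    bands: Sequence[RhythmBand] = DEFAULT_BANDS,
) -> np.ndarray:
    """Mean band-power vector over seconds t-r ... t inclusive (r+1 epochs)."""
    if r < 0:
        raise ValueError("r must be >= 0")
    if t - r < 0:
        raise ValueError(f"insufficient history: t={t} < r={r}")
    window = psd_series[t - r : t + 1]
    return np.mean([band_power_vector(p, bands) for p in window], axis=0)


def extract_features(
    recording,
    labels: Sequence[int],
    channel: str,
    r: int = 0,
    bands: Sequence[RhythmBand] = DEFAULT_BANDS,
) -> FeatureMatrix:
    """Featurise one channel of a (denoised) recording.

    ``labels`` holds one +-1 vigilance label per whole second. One feature
    row is produced for each second t >= r, so m = total_seconds - r.
    """
    labels = np.asarray(labels, dtype=int)
    total_seconds = recording.n_seconds
    if len(labels) != total_seconds:
        raise ValueError(
            f"label length {len(labels)} != whole seconds {total_seconds}"
        )
    sig = recording.channel(channel)
    fs = recording.fs
    psds = [
        epoch_psd(sig[t * fs : (t + 1) * fs], fs, epoch_index=t)
        for t in range(total_seconds)
    ]
    rows = [feature_at_time(psds, t, r, bands) for t in range(r, total_seconds)]
    t_index = np.arange(r, total_seconds)
    return FeatureMatrix(
        X=np.asarray(rows).reshape(len(rows), len(bands)),
        y=labels[r:],
        r=r,
        channel=channel,
        band_names=tuple(b.name for b in bands),
        t_index=t_index,
    )


def scale_features(
    train: FeatureMatrix, apply_to: Optional[FeatureMatrix] = None
):
    """Affinely scale each dimension so the training column spans [-1, +1].

    The map fitted on ``train`` is applied unchanged to ``apply_to``
    (values outside the training range map outside [-1, 1], as in libsvm-style
    scaling). Constant training columns map to 0 everywhere.

    Returns ``(train_scaled, apply_scaled_or_None, scaling)`` where scaling is
    an array of shape (2, n_dims): row 0 the per-dimension training minima,
    row 1 the maxima.
    """
    if train.m == 0:
        raise ValueError("empty training matrix")
    lo = train.X.min(axis=0)
    hi = train.X.max(axis=0)
    scaling = np.vstack([lo, hi])

    def _apply(X):
        span = hi - lo
        out = np.zeros_like(X)
        ok = span > 0
        out[:, ok] = -1.0 + 2.0 * (X[:, ok] - lo[ok]) / span[ok]
        return out

    train_s = FeatureMatrix(
        X=_apply(train.X), y=train.y, r=train.r, channel=train.channel,
        band_names=train.band_names, t_index=train.t_index, scaling=scaling,
    )
    applied = None
    if apply_to is not None:
        applied = FeatureMatrix(
            X=_apply(apply_to.X), y=apply_to.y, r=apply_to.r,
            channel=apply_to.channel, band_names=apply_to.band_names,
            t_index=apply_to.t_index, scaling=scaling,
        )
    return train_s, applied, scaling


def apply_scaling(X: np.ndarray, scaling: np.ndarray) -> np.ndarray:
    """Apply a stored (min, max) scaling to raw feature rows."""
    lo, hi = scaling[0], scaling[1]
    span = hi - lo
    out = np.zeros_like(np.asarray(X, dtype=float))
    ok = span > 0
    out[:, ok] = -1.0 + 2.0 * (X[:, ok] - lo[ok]) / span[ok]
    return out
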