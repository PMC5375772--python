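"""Wavelet denoising of EEG channels.

Each channel is decomposed six levels deep with the Daubechies-5 (db5)
wavelet. At 512 Hz the detail levels cover dyadic bands D1 (128-256 Hz)
down to D6 (4-8 Hz) and the approximation A6 covers 0-4 Hz. D1, D2 and A6
fall outside the 3-100 Hz hardware passband / rhythm range and are treated
as noise; reconstructing from D3-D6 alone (32-64, 16-32, 8-16 and 4-8 Hz)
keeps the theta/alpha/beta content and strips slow drift, blink residue and
high-frequency interference. Whole levels are removed — no coefficient
thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Set, Tuple

import numpy as np
import pywt

from .recording import EEGRecording

WAVELET = "db5"
LEVELS = 6
BOUNDARY_MODE = "symmetric"

#: Detail levels retained by default denoising (4-64 Hz at fs=512).
DEFAULT_KEEP = frozenset({"D3", "D4", "D5", "D6"})

LEVEL_NAMES = ("A6", "D6", "D5", "D4", "D3", "D2", "D1")  # pywt coeff order


@dataclass
class WaveletDecomposition:
    """Six-level db5 decomposition of one channel.

    ``approx`` is A6; ``details`` maps "D1".."D6" to coefficient arrays.
    The full set inverts back to the input (perfect reconstruction).
    """

    wavelet: str
    levels: int
    approx: np.ndarray
    details: dict
    boundary_mode: str
    original_length: int

    def coeff_list(self, keep: Iterable[str] = LEVEL_NAMES) -> List[np.ndarray]:
        """pywt-ordered coefficient list with non-kept levels zeroed."""
        keep = set(keep)
        unknown = keep - set(LEVEL_NAMES)
        if unknown:
            raise ValueError(f"unknown level name(s): {sorted(unknown)}")
        coeffs = [self.approx if "A6" in keep else np.zeros_like(self.approx)]
        for lev in range(self.levels, 0, -1):
            name = f"D{lev}"
            c = self.details[name]
            coeffs.append(c if name in keep else np.zeros_like(c))
        return coeffs


def band_edges(level: int, fs: float) -> Tuple[float, float]:
    """Nominal dyadic frequency band (low, high) of detail level D_level.

    D_j spans (fs/2^(j+1), fs/2^j): at 512 Hz, D3 = 32-64 Hz, D4 = 16-32 Hz,
    D5 = 8-16 Hz, D6 = 4-8 Hz.
    """
    if not 1 <= level <= LEVELS:
        raise ValueError(f"level must be in 1..{LEVELS}, got {level}")
    if fs <= 0:
        raise ValueError("fs must be positive")
    return fs / 2 ** (level + 1), fs / 2 ** level


def decompose(signal: np.ndarray, fs: float = 512) -> WaveletDecomposition:
    """Six-level db5 DWT of one channel (symmetric boundary extension)."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D")
    if len(signal) < 2 ** LEVELS:
        raise ValueError(
            f"signal too short for {LEVELS}-level decomposition: "
            f"{len(signal)} < {2 ** LEVELS} samples"
        )
    coeffs = pywt.wavedec(signal, WAVELET, mode=BOUNDARY_MODE, level=LEVELS)
    details = {f"D{LEVELS - i}": c for i, c in enumerate(coeffs[1:])}
    return WaveletDecomposition(
        wavelet=WAVELET,
        levels=LEVELS,
        approx=coeffs[0],
        details=details,
        boundary_mode=BOUNDARY_MODE,
        original_length=len(signal),
    )


def reconstruct_selected(
    decomp: WaveletDecomposition, keep: Iterable[str]
) -> np.ndarray:
    """Inverse DWT keeping only the named levels (others zeroed).

    Equivalent to summing the per-level partial reconstructions; keeping all
    levels reproduces the input to numerical precision.
    """
    coeffs = decomp.coeff_list(keep)
    out = pywt.waverec(coeffs, decomp.wavelet, mode=decomp.boundary_mode)
    return out[: decomp.original_length]


def denoise_channel(signal: np.ndarray, keep: Set[str] = DEFAULT_KEEP) -> np.ndarray:
    return reconstruct_selected(decompose(signal), keep)


def denoise(recording: EEGRecording, keep: Iterable[str] = DEFAULT_KEEP) -> EEGRecording:
    """Replace every channel by its D3-D6 reconstruction (default)."""
    keep = set(keep)
    cleaned = np.vstack([denoise_channel(ch, keep) for ch in recording.data])
    return recording.copy_with(cleaned, denoised=sorted(keep))
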