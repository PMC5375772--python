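"""Synthetic labelled EEG with alert/drowsy spectral structure.

Emulates the features of drowsy scalp EEG relevant to vigilance
classification: at occipital sites the drowsy state carries more theta
(4-8 Hz) and alpha (8-14 Hz) power and less beta (14-34 Hz) power than the
alert state, with intermittent alpha bursting; blink artifacts (<5 Hz)
contaminate the pre-frontal channels and EMG bursts (>30 Hz) all channels;
everything rides on 1/f background noise. Amplitudes are in µV, sampling at
512 Hz by default (hardware passband 3-100 Hz).

All randomness flows from one integer seed through a `numpy.random.SeedSequence`
spawn tree, split per segment / channel / component, so identical inputs give
bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .features import DEFAULT_BANDS, RhythmBand
from .recording import CHANNELS_1020, EEGRecording, OCCIPITAL, PREFRONTAL

ALERT, DROWSY = "alert", "drowsy"

#: SVM label convention: +1 alert, -1 drowsy.
STATE_LABELS = {ALERT: +1, DROWSY: -1}


@dataclass(frozen=True)
class BurstSpec:
    """Intermittent amplitude bursting of one rhythm (e.g. drowsy alpha)."""

    rhythm: str
    duration_s: float = 2.0
    rate_per_min: float = 6.0
    amplitude_multiplier: float = 2.0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("burst duration must be positive")
        if self.rate_per_min < 0 or self.amplitude_multiplier < 0:
            raise ValueError("burst rate and multiplier must be >= 0")


@dataclass(frozen=True)
class ArtifactSpec:
    """Blink (pre-frontal, <5 Hz) and EMG (all channels, 30-100 Hz) artifacts."""

    blink_rate_per_min: float = 15.0
    blink_amplitude: float = 80.0
    emg_rate_per_min: float = 4.0
    emg_amplitude: float = 15.0

    def __post_init__(self):
        if min(self.blink_rate_per_min, self.blink_amplitude,
               self.emg_rate_per_min, self.emg_amplitude) < 0:
            raise ValueError("artifact rates and amplitudes must be >= 0")


@dataclass(frozen=True)
class StateProfile:
    """Generative description of one vigilance state.

    ``band_amplitudes`` maps rhythm name -> {"occipital": µV, "frontal": µV}
    RMS amplitudes (the "frontal" group covers every non-occipital site).
    """

    state: str
    band_amplitudes: Dict[str, Dict[str, float]]
    burst_spec: Optional[BurstSpec] = None
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    noise_exponent: float = 1.0
    noise_rms: float = 5.0

    def __post_init__(self):
        if self.state not in (ALERT, DROWSY):
            raise ValueError(f"state must be alert/drowsy, got {self.state!r}")
        for rhythm, groups in self.band_amplitudes.items():
            for grp, amp in groups.items():
                if amp < 0:
                    raise ValueError(f"negative amplitude for {rhythm}/{grp}")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be >= 0")

    def amplitude(self, rhythm: str, channel: str) -> float:
        group = "occipital" if channel in OCCIPITAL else "frontal"
        return self.band_amplitudes[rhythm][group]


#: schedule entries are (state, integer seconds)
StateSchedule = List[Tuple[str, int]]


def validate_schedule(schedule: StateSchedule) -> None:
    if not schedule:
        raise ValueError("empty schedule")
    for state, dur in schedule:
        if state not in (ALERT, DROWSY):
            raise ValueError(f"unknown state {state!r}")
        if int(dur) != dur or dur <= 0:
            raise ValueError(f"durations must be positive integers, got {dur}")


def alternating_schedule(
    seconds_per_state: int, segment_s: int = 60, start: str = ALERT
) -> StateSchedule:
    """Alternating alert/drowsy segments totalling seconds_per_state each.

    Interleaving keeps every contiguous cross-validation block mixed-class,
    which is how the evaluation experiments lay out their sessions.
    """
    if seconds_per_state % segment_s:
        raise ValueError("seconds_per_state must be a multiple of segment_s")
    other = DROWSY if start == ALERT else ALERT
    n = seconds_per_state // segment_s
    out: StateSchedule = []
    for _ in range(n):
        out.append((start, segment_s))
        out.append((other, segment_s))
    return out


def default_profiles(
    theta_alpha_db: float = 6.0, beta_db: float = -3.0
) -> Tuple[StateProfile, StateProfile]:
    """Alert and drowsy profiles with the canonical occipital contrast.

    Relative to alert, the drowsy occipital theta and alpha power is raised
    by ``theta_alpha_db`` (default +6 dB) and beta lowered by ``|beta_db|``
    (default -3 dB); frontal-group amplitudes are state-independent. The
    drowsy profile adds alpha bursting; both states carry blink and EMG
    artifacts and 1/f background noise.
    """
    up = 10.0 ** (theta_alpha_db / 20.0)    # dB on power -> amplitude factor
    down = 10.0 ** (beta_db / 20.0)
    alert_amps = {
        "theta": {"occipital": 4.0, "frontal": 3.0},
        "alpha": {"occipital": 6.0, "frontal": 2.0},
        "beta": {"occipital": 4.0, "frontal": 2.0},
    }
    drowsy_amps = {
        "theta": {"occipital": 4.0 * up, "frontal": 3.0},
        "alpha": {"occipital": 6.0 * up, "frontal": 2.0},
        "beta": {"occipital": 4.0 * down, "frontal": 2.0},
    }
    alert = StateProfile(
        state=ALERT,
        band_amplitudes=alert_amps,
        burst_spec=None,
        artifact_spec=ArtifactSpec(blink_rate_per_min=15.0),
    )
    drowsy = StateProfile(
        state=DROWSY,
        band_amplitudes=drowsy_amps,
        burst_spec=BurstSpec(rhythm="alpha"),
        artifact_spec=ArtifactSpec(blink_rate_per_min=6.0),
    )
    return alert, drowsy


def _band(name: str) -> RhythmBand:
    for b in DEFAULT_BANDS:
        if b.name == name:
            return b
    raise KeyError(name)


def generate_rhythm(
    band: RhythmBand,
    rms_amplitude: float,
    duration_s: float,
    fs: int,
    seed,
) -> np.ndarray:
    """Band-limited oscillation: sum of random-phase sinusoids in the band.

    Frequencies are drawn uniformly in [band.low, band.high); the sum is
    rescaled to the requested RMS, so the empirical RMS is exact.
    """
    if fs <= 2 * band.high:
        raise ValueError(
            f"Nyquist violation: fs={fs} must exceed 2*{band.high}"
        )
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    if rms_amplitude == 0:
        return np.zeros(n)
    k = 40
    freqs = rng.uniform(band.low, band.high, size=k)
    phases = rng.uniform(0, 2 * np.pi, size=k)
    t = np.arange(n) / fs
    sig = np.sum(np.sin(2 * np.pi * freqs[:, None] * t[None, :]
                        + phases[:, None]), axis=0)
    rms = np.sqrt(np.mean(sig ** 2))
    if rms > 0:
        sig *= rms_amplitude / rms
    return sig


def generate_background(
    noise_rms: float, exponent: float, duration_s: float, fs: int, seed
) -> np.ndarray:
    """1/f^exponent background noise via spectral shaping of white noise."""
    if not 0 <= exponent <= 2:
        raise ValueError(f"exponent must be in [0, 2], got {exponent}")
    if fs <= 0 or duration_s <= 0:
        raise ValueError("fs and duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    if noise_rms == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    sig = np.fft.irfft(spec * shape, n=n)
    rms = np.sqrt(np.mean(sig ** 2))
    if rms > 0:
        sig *= noise_rms / rms
    return sig


def _raised_cosine_gate(n_total: int, starts: np.ndarray, width: int) -> np.ndarray:
    """Sum of Hann-shaped gates of ``width`` samples at ``starts`` (clipped)."""
    gate = np.zeros(n_total)
    win = np.hanning(width)
    for s in starts:
        s = int(s)
        e = min(s + width, n_total)
        if s < n_total:
            gate[s:e] = np.maximum(gate[s:e], win[: e - s])
    return gate


def _blink_pulse(fs: int, duration_s: float, amplitude: float) -> np.ndarray:
    """Biphasic pulse with spectral content below 5 Hz."""
    n = int(round(duration_s * fs))
    t = np.linspace(0, 1, n, endpoint=False)
    return amplitude * np.sin(2 * np.pi * t) * np.hanning(n)


def _poisson_starts(rng, rate_per_min: float, duration_s: float,
                    fs: int, width: int) -> np.ndarray:
    n_events = rng.poisson(rate_per_min * duration_s / 60.0)
    max_start = max(int(duration_s * fs) - width, 1)
    return rng.integers(0, max_start, size=n_events)


def _segment_channel(
    state_profile: StateProfile,
    channel: str,
    duration_s: float,
    fs: int,
    rng_children,
) -> np.ndarray:
    """Synthesize one channel over one constant-state segment."""
    n = int(round(duration_s * fs))
    child = iter(rng_children)
    sig = np.zeros(n)
    burst = state_profile.burst_spec
    for band in DEFAULT_BANDS:
        amp = state_profile.amplitude(band.name, channel)
        rhythm = generate_rhythm(band, amp, duration_s, fs, next(child))
        sig += rhythm
        if burst is not None and burst.rhythm == band.name:
            rng_b = np.random.default_rng(next(child))
            width = int(round(burst.duration_s * fs))
            starts = _poisson_starts(rng_b, burst.rate_per_min, duration_s,
                                     fs, width)
            gate = _raised_cosine_gate(n, starts, width)
            sig += (burst.amplitude_multiplier - 1.0) * gate * rhythm
    sig += generate_background(
        state_profile.noise_rms, state_profile.noise_exponent,
        duration_s, fs, next(child),
    )
    art = state_profile.artifact_spec
    # EMG bursts (30-100 Hz) on every channel
    rng_e = np.random.default_rng(next(child))
    if art.emg_rate_per_min > 0 and art.emg_amplitude > 0:
        emg_band = RhythmBand("emg", 30.0, 100.0)
        n_events = rng_e.poisson(art.emg_rate_per_min * duration_s / 60.0)
        for _ in range(n_events):
            dur = rng_e.uniform(0.2, 1.0)
            width = int(round(dur * fs))
            start = int(rng_e.integers(0, max(n - width, 1)))
            noise = rng_e.standard_normal(width)
            # shape white noise into the EMG band with an FFT mask
            spec = np.fft.rfft(noise)
            f = np.fft.rfftfreq(width, d=1.0 / fs)
            spec[(f < emg_band.low) | (f >= emg_band.high)] = 0
            noise = np.fft.irfft(spec, n=width)
            rms = np.sqrt(np.mean(noise ** 2))
            if rms > 0:
                noise *= art.emg_amplitude / rms
            sig[start:start + width] += noise * np.hanning(width)
    # blink artifacts on pre-frontal channels only
    if channel in PREFRONTAL and art.blink_rate_per_min > 0:
        rng_k = np.random.default_rng(next(child))
        n_events = rng_k.poisson(art.blink_rate_per_min * duration_s / 60.0)
        for _ in range(n_events):
            dur = rng_k.uniform(0.3, 0.5)
            pulse = _blink_pulse(fs, dur, art.blink_amplitude)
            start = int(rng_k.integers(0, max(n - len(pulse), 1)))
            sig[start:start + len(pulse)] += pulse
    return sig


def generate_recording(
    schedule: StateSchedule,
    profiles: Optional[Tuple[StateProfile, StateProfile]] = None,
    channels: Sequence[str] = CHANNELS_1020,
    fs: int = 512,
    seed: int = 0,
) -> Tuple[EEGRecording, np.ndarray]:
    """Generate a labelled multi-channel recording from a state schedule.

    Returns the recording and a per-second label vector (+1 alert,
    -1 drowsy). Blink artifacts appear only on Fp1/Fp2 and the band-power
    contrast between states only at O1/O2.
    """
    validate_schedule(schedule)
    channels = tuple(channels)
    unknown = [c for c in channels if c not in CHANNELS_1020]
    if unknown:
        raise ValueError(f"unknown channel label(s): {unknown}")
    if profiles is None:
        profiles = default_profiles()
    by_state = {p.state: p for p in profiles}

    root = np.random.SeedSequence(seed)
    seg_seeds = root.spawn(len(schedule))
    per_channel = [[] for _ in channels]
    labels = []
    for (state, dur), seg_seed in zip(schedule, seg_seeds):
        prof = by_state[state]
        chan_seeds = seg_seed.spawn(len(channels))
        for ci, (chan, cseed) in enumerate(zip(channels, chan_seeds)):
            children = cseed.spawn(8)  # components: 3 bands + burst + noise + emg + blink
            per_channel[ci].append(
                _segment_channel(prof, chan, dur, fs, children)
            )
        labels.extend([STATE_LABELS[state]] * int(dur))
    data = np.vstack([np.concatenate(parts) for parts in per_channel])
    rec = EEGRecording(
        fs=fs, channels=channels, data=data,
        meta={"seed": seed, "schedule": list(schedule), "synthetic": True},
    )
    return rec, np.asarray(labels, dtype=int)
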