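# Methods

`vigileeg` implements a per-second EEG vigilance classifier of the kind used
in driver-fatigue monitoring, together with a synthetic EEG generator that
makes the whole pipeline testable without clinical recordings. This note
describes the models, the defaults and the design choices; every number
quoted here is computed by the test suite or by `scripts/acceptance.py`.

## The detection pipeline

**Signal model.** Scalp EEG sampled at 512 Hz (hardware passband 3–100 Hz)
from up to eight 10–20 sites. Drowsiness — the transition into NREM stage-1
sleep — expresses spectrally at the occipital sites O1/O2: theta (4–8 Hz)
and alpha (8–14 Hz) power rise, beta (14–34 Hz) power falls, and the alpha
rhythm bursts intermittently. Blink artifacts (<5 Hz, pre-frontal) and EMG
bursts (>30 Hz, all sites) contaminate the record.

**Wavelet denoising.** Each channel is decomposed six levels deep with the
Daubechies-5 wavelet (symmetric boundary extension). The detail levels tile
the spectrum dyadically — `band_edges(j, fs) = (fs/2^(j+1), fs/2^j)`, so at
512 Hz D3–D6 cover 32–64, 16–32, 8–16 and 4–8 Hz. D1, D2 (above 64 Hz) and
the A6 approximation (below 4 Hz) lie outside both the hardware passband
and the rhythm range and are discarded wholesale; the signal is rebuilt
from D3–D6 by zeroing the other coefficient sequences and inverting once.
No coefficient thresholding is applied — whole levels only. Keeping all
levels reproduces the input to <1e-8 max abs error (checked on 100 random
signals); mid-band tones at 10/25/50 Hz retain ≥80 % energy while 1 Hz and
120 Hz tones retain ≤2 % (the residue is filter roll-off). Boundary
coefficients of the symmetric extension carry a few percent of a short
signal's energy, which is why level-concentration checks use ≥8 s inputs.

**Features.** Each whole second is Hanning-windowed and turned into a
one-sided periodogram with window power correction (`scipy.signal.periodogram`,
density scaling; at one-second epochs the 1 Hz bin width makes density equal
per-bin power). Powers are floored at 1e-12 and logged (base 10). A band
feature is log10 of the *sum* of linear bin powers over a half-open band
[low, high) — half-open so the shared 8 and 14 Hz edges are counted once.
The feature vector at second t averages the per-second band-power vectors
of seconds t−r … t inclusive (r+1 terms, in the log domain), under the
modelling assumption that the vigilance state is constant over those r
seconds. Features are scaled per dimension to the training range [−1, +1],
libsvm-style; constant columns map to 0.

**Classifier.** A soft-margin SVM trained in the dual, RBF kernel
κ(x, x′) = exp(−g‖x−x′‖²) by default. The optimiser is a Platt-style SMO
over a precomputed Gram matrix with an error cache and the standard
second-choice hierarchy (max |E₁−E₂| over the non-bound set, then the
non-bound set, then all points), KKT tolerance 1e-3. On every small fixture
the dual objective agrees with an independent SLSQP QP solve to 1e-3, and
held-out predictions agree with libsvm (scikit-learn's SVC) on ≥98 % of
seconds. The bias is recomputed after convergence as the mean KKT residual
over free support vectors. Ties at f(x) = 0 classify as drowsy — the
fail-safe direction for an alarm system. Labels are +1 alert, −1 drowsy;
*evaluation* nevertheless treats drowsy as the positive class
(sensitivity = detected drowsy time / actual drowsy time,
false-positive rate = alert time flagged drowsy / actual alert time), and
that sign mapping lives in one place (`ConfusionCounts`).

**Model selection and validation.** Per-second features are serially
dependent, so cross-validation splits the timeline into contiguous blocks
(default 3), never shuffled rows; scaling is refitted on each training
split. Grid search covers C ∈ 2^{−5..15}, g ∈ 2^{−15..3} in powers of two
(the standard libsvm lattice); ties resolve to the smallest C, then g. The
pipeline defaults C = 32, g = 2, chosen once from the middle of the
plateau that the grid search shows on synthetic data. Metrics pool
held-out seconds across blocks (micro-average); per-prediction wall time
is recorded but never asserted, being hardware-dependent.

## The synthetic generator

Each constant-state segment of a schedule is synthesised per channel as

* one band-limited rhythm per band: 40 sinusoids with frequencies drawn
  uniformly in the band and random phases, rescaled to the profile's RMS
  amplitude (µV);
* 1/f^α background noise via spectral shaping of white noise (α = 1,
  RMS 5 µV by default), slope verified by periodogram fit;
* in the drowsy state, alpha bursts: Hann-shaped gates (2 s, 6/min) that
  multiply the alpha rhythm by 2;
* blink artifacts only on Fp1/Fp2: biphasic 0.3–0.5 s pulses, 80 µV,
  15/min alert and 6/min drowsy; EMG bursts on all channels: 30–100 Hz
  noise, 0.2–1 s, 15 µV RMS, 4/min.

Alert occipital RMS amplitudes are theta 4, alpha 6, beta 4 µV; the drowsy
state scales occipital theta/alpha by +6 dB and beta by −3 dB (power dB;
the contrast is a config parameter). Non-occipital amplitudes are
state-independent, so only O1/O2 carry class information. All randomness
derives from one integer seed through a `SeedSequence` spawn tree split per
segment/channel/component; identical inputs give bit-identical recordings.

What the generator does *not* emulate: volume-conduction mixing between
channels, non-stationary spectral drift within a state, eye movements
beyond the blink pulse, inter-subject variability, or realistic alpha peak
shape (the uniform in-band frequency draw puts more power near band edges
than real alpha does, which leaks across the 14 Hz edge in coarse
spectral estimates — band-power oracles therefore use ≥4096-sample Welch
windows). Passing tests show the pipeline recovers a known spectral
contrast under realistic noise and artifacts; they do not certify
performance on human EEG.

## Evaluation protocol choices

* **Schedules.** Evaluation recordings interleave 60-s alert/drowsy
  segments (e.g. 10 segments for 300 s per state) so that every contiguous
  CV block contains both classes. Long single-state blocks would make
  held-out blocks single-class and turn the null experiment into a test of
  fold imbalance rather than calibration.
* **Transition seconds.** A second whose r-window spans a state change has
  no well-defined label under the constant-state assumption (recordings
  collected as separate alert/drowsy sessions contain no such seconds);
  `steady_state_mask` drops them from training and scoring. Without this,
  boundary-contaminated labels accumulate linearly with r and mask the
  benefit of averaging.
* **Problem sizes.** The r-sweep experiments use 300 s per state (≈600
  feature seconds) and the null-calibration runs 120 s per state across
  ten seeds; both finish in seconds and are large enough that the reported
  rates are stable to a percent or two.
* **Null calibration.** With identical profiles for both states the
  features carry no class signal and pooled CV accuracy sits near chance
  (mean ≈ 0.45–0.5 over ten seeds; slightly below 0.5 because block-wise
  training imbalance biases the majority class against the held-out block).

## Known limitations

* The EDF codec covers the subset this package writes (uniform rate,
  one-second records, 16-bit, µV); it is not a general EDF+ reader.
* The SMO solver targets problems of a few thousand rows; it precomputes
  the full Gram matrix.
* Per-channel models only (3-dimensional features from one channel);
  cross-channel fusion is out of scope.
* `detect` assumes the stream starts alert; the first scored second being
  drowsy counts as a transition and raises a warning event.
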