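# Methods

This note documents the models, parameter choices and numerical
decisions behind the package, and what its validation does and does not
establish.

## Signal chain

Stages run in a fixed order: band-pass filter → ICA artifact removal →
segmentation → surface-Laplacian CSD → multitaper coherence →
beta-band topography → cluster permutation test. CSD is computed
sample-wise in the time domain before any spectral estimation, so the
coherence always refers to reference-free signals.

### Band-pass filter

A Hamming-windowed-sinc FIR band-pass, 3–45 Hz, of order ⌈3.3·fs/1 Hz⌉
rounded to odd (3301 taps at 1000 Hz). This order places the Hamming
transition inside 1 Hz at the low edge with a ≈53 dB stopband, so
passband ripple stays under 1% and gain at 1.5 Hz and 50 Hz is ≤ 0.01.
The taps are explicitly symmetrised after design so linear phase is
bit-exact. Application is forward–backward ("two-pass"), which squares
the magnitude response and cancels all phase; it is implemented as a
single convolution with the taps' autocorrelation via block overlap-add
FFTs, with reflection padding of one kernel length at the edges. Force
channels pass through unfiltered; the EMG gets the same band as the EEG
and is never rectified.

### ICA artifact removal

A deterministic fixed-point ICA (FastICA, seeded) on the EEG block,
components ordered by back-projected variance. Component scores:

- **blink** — |Pearson r| between the component and the < 5 Hz low-passed
  frontal-electrode average (electrodes with y > 0.5 on the unit sphere);
- **ecg** — regularity of a prominent-peak train (peaks ≥ 3.5 SD, minimum
  spacing 0.33 s): the fraction of inter-peak intervals within 15% of
  the median, gated to a 0.8–2 Hz rate; 0 with fewer than 5 peaks;
- **line** — fraction of component power within 50 ± 1 Hz.

Components with any score above 0.7 (configurable) are removed. These
scores are an explicit, reproducible stand-in for the manual component
selection typical of clinical practice. Separation quality — and hence
how much genuine beta activity leaks into a removed component — improves
with channel count; the validation suite checks the ≤ 10% beta-power
side-effect bound at 24 channels and clean-data false-rejection at 10.

### Segmentation

Each trial contributes non-overlapping 1-s epochs tiling
[start + 2 s, end); the first 2 s are skipped because the protocol
allots them for reaching the target force, so epochs sample the steady
contraction only. An 11-s trial yields exactly 9 epochs; 20 trials/run ×
2 runs give 360 epochs per session. Trials shorter than 3 s contribute
nothing; epoch counts obey Σ floor((len − 2)/1) exactly.

### Surface Laplacian / CSD

Spherical-spline Laplacian on an idealised unit-sphere head with the
canonical constants of that family: spline flexibility m = 4,
regularisation λ = 1e-5 on the diagonal of G, 50 Legendre terms. The
spline system is solved with an explicit zero-sum constraint on the
coefficients, so a spatially constant potential maps to exactly zero and
the output is invariant to the recording reference. Sign convention is
source-positive. No realistic head geometry is attempted — consistent
with the idealised montage (a deterministic Fibonacci-spiral cap
restricted to z ≥ −0.2 stands in for a 128-channel geodesic net).

### Multitaper coherence

1-s epochs give a 1 Hz grid; NW = 2 with K = 3 Slepian tapers adds
±2 Hz spectral smoothing, keeping the 15–30 Hz band well resolved while
tripling the per-epoch averaging. Tapers are the exact symmetric DPSS
eigenvectors (orthonormal to machine precision). Coherence is reported
as magnitude (not squared) because the downstream z-transform and its
1/(d−2) bias term are defined for the magnitude; degrees of freedom are
d = 2KL with no overlap deflation (epochs never overlap). Topographies
are the band-mean coherence per electrode over 15–30 Hz inclusive, ties
broken by montage order, and per-session statistics use each session's
own peak electrode (tolerating small cap-placement shifts between
sessions).

### Cluster permutation test

Z(f) = ((atanh C1 − n1) − (atanh C2 − n2))/√(n1+n2) with n_i = 1/(d_i−2);
coherence is clipped at 1 − 1e-12 before atanh. Positive Z means
condition 1 exceeds condition 2, so the one-sided test of "condition 1
greater" clusters strictly supra-threshold runs of adjacent in-band
frequencies (default threshold 1.645, the one-sided z at α = 0.05) and
takes the maximum cluster mass — the canonical statistic of the
cluster-based framework. Random partitions reassign pooled segments to
pseudo-conditions of the original sizes; the per-epoch tapered
cross-spectra are precomputed once, so each of the 5,000 partitions only
averages cached products. The Monte Carlo p uses the add-one estimator
(1 + #{null ≥ observed})/(1 + B), which never returns 0 and implements
"at least as large" with ≥. Options: a two-sided mode with sign-split
clusters (for the no-difference null), trial-level exchangeability (for
within-trial autocorrelation), and a selection-aware mode that re-picks
the peak electrode inside every partition (off by default, matching a
fixed-electrode analysis).

## Synthetic sessions and ground truth

The generator emulates a visually-guided elbow-flexion task: 11-s
trials, 2-s gaps, 20 trials/run, 2 runs/session, 1000 Hz, a force
channel ramping to 3 N within 2 s and holding with small jitter. A
shared cortical source s(t) — white noise shaped by order-2 Butterworth
band-passes of ±4 Hz around 18 and 24 Hz (two broad beta peaks, as seen
in real CMC spectra) — is mixed linearly: channel i records
g_i·s + noise with g_i = exp(−2·greatcircle(i, target)) peaked at the
electrode nearest the contralateral "motor cortex" direction (40°
lateral of the vertex); the EMG records κ·s(t − 10 ms) + noise,
amplitude-modulated to silence outside contractions. Because mixing is
linear with independent white channel noise, the expected magnitude
coherence is closed-form:

    C_i(f) = g_i κ S(f) / sqrt((g_i² S(f) + σ_e²)(κ² S(f) + σ_m²))

with S(f) the source spectrum in driving-noise units (evaluated exactly
from the shaping filters' frequency response). Defaults put the source
scale and both noise SDs at 20 µV, so κ = 1 gives a peak coherence of
≈ 0.5 at the target electrode — the upper range of healthy beta-band
CMC, chosen so validation simulations are well powered. A session
"after recovery" is modelled purely as a larger κ (doubled in the
validation scenarios); a pure conduction delay leaves coherence
magnitude untouched and only exercises phase handling. Optional
artifacts (frontal 0.3 Hz blink lobes, a 1.2 Hz cardiac spike train at
low gain, 30 µV of 50 Hz line with random per-channel gain) draw from
the same seeded stream, so sessions are bit-reproducible.

What the generator does **not** model: volume conduction through a
realistic head, a reference-electrode subtraction (channels are
generated reference-free), motor-unit pool EMG, nonstationary coupling
within a trial, and non-Gaussian background EEG. Passing tests therefore
demonstrate correctness of the estimators and the test under the linear
mixed-source model, not robustness to every property of clinical data.

## Numerical choices

- EDF output is 16-bit with per-channel physical ranges set from the
  data extrema plus 5% headroom; markers are EDF+ annotations with
  onsets in seconds; recordings are zero-padded to whole 1-s records.
  Sample indexing is 0-based and trial windows are half-open.
- The consistency validation compares the multitaper estimate at the
  target electrode in sensor space to the closed form, after filtering
  (which cancels in coherence) but before CSD: CSD recombines channels
  and deliberately changes sensor-space coherence, so the closed form
  applies pre-CSD; CSD has its own exact contracts (constant → 0,
  reference invariance, linearity) and the topography-recovery check.
- Multitaper smoothing (±2 Hz) slightly biases the estimate where the
  true curve bends; tolerances in mid-band point checks carry a 0.01
  allowance for it. The ±0.05-RMS consistency bound absorbs it at
  L = 360.
- Pipeline stage seeds derive from the global seed by fixed offsets, so
  any stage can be re-run in isolation and full runs are byte-identical
  under a fixed seed.

## Problem sizes in the validation suite

Simulation-heavy checks are scaled to desk hardware while keeping the
protocol's segment counts: consistency uses 10 sessions of 360 epochs at
16 electrodes (coherence at one electrode pair is unaffected by montage
size); topography recovery uses 20 full 128-electrode sessions;
calibration uses 500 null session pairs with 200 partitions each
(the add-one estimator then rejects at 10/201 ≈ 0.0497 under the null);
power uses 100 gain-doubled pairs at 180 epochs/condition. The
acceptance script uses the same designs at 100/60 replicates and 1,000
partitions for the session comparisons.

## Known limitations

- The montage is synthetic; real electrode coordinate files can be
  supplied (.sfp) but no digitiser formats are parsed.
- ICA separation (and thus artifact removal purity) degrades below ~16
  channels and for near-Gaussian artifact sources.
- The permutation test assumes exchangeability of 1-s segments between
  sessions under the null; slow within-session drifts violate it
  (trial-level exchange mitigates, long-term nonstationarity does not).
- Force channels are carried and written but not otherwise analysed.
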