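# Methods

This note documents the models, numerical choices and known limitations of
`nirsblock`.  It is written for users who need to judge what the package's
synthetic validation does and does not demonstrate about real infant fNIRS
data.

## The forward model (synthetic cohorts)

### Design

A session is 14 stimulus blocks (7 HL + 7 LH) of 15 s (10 stimuli, 1.5 s
SOA) in strictly alternating order; every block, including the first, is
preceded by a silent baseline drawn independently and uniformly from
{18, 20, 22} s.  The first condition is randomized per participant (the
counterbalancing policy is configurable: `fixed_HL`, `fixed_LH`,
`randomized`).  With the mean 20 s baseline the schedule is 490 s
(~8.2 min).  The recording continues 32 s past the last block so that the
final epoch window fits.

### Hemodynamic response

No infant HRF is canonical, so the kernel is a stand-in with contract
properties rather than a physiological claim: a double-gamma shape
(gamma-like main lobe, optional delayed undershoot lobe, shape parameter 6)
with `kernel(0) = 0` and a unique maximum of exactly 1 at `peak_time`
(default 5.5 s; undershoot at 12 s, ratio 0.2).  Because a nonzero
undershoot shifts the raw argmax, the kernel's maximum is located
numerically (dense grid + bounded scalar minimization, tolerance 1e-10) and
the time axis rescaled so the peak lands at `peak_time`.  The per-block
regressor is the boxcar-kernel convolution, peak-normalized, so configured
amplitudes are peak concentration changes in uM.

Default condition amplitudes (uM): 0.10 on non-ROI channels, 0.20 on right
ROI channels for both conditions, and 0.35 (HL) vs 0.15 (LH) on left ROI
channels.  These were fixed once to place group effect sizes in the
d ≈ 0.3–1 range typical of infant prosody block designs; deoxy-Hb is the
configured negative fraction (default −1/3) of the noiseless oxy signal
plus independent noise.

### Noise and artifacts

Concentration-domain noise per channel and chromophore, each with random
phase: very-low-frequency drift (0.002 Hz, 0.3 uM), spontaneous
low-frequency oscillations (0.04 Hz, 0.3 uM — deliberately inside the
analysis band, as in real recordings, where they are the dominant noise
source and the reason block averaging and permutation inference are needed
at all), Mayer waves (0.1 Hz, 0.15 uM), respiration (0.5 Hz, 0.05 uM), and
white noise (sd 0.1 uM).  Optics: the modified Beer-Lambert law with a
shipped extinction table approximating a standard hemoglobin absorption
compilation at 695/830 nm (cm⁻¹ uM⁻¹; overridable), 3 cm source-detector
distance, PPF = 1.  The absolute concentration scale under this convention
is arbitrary; all inference is scale invariant.  Intensities are
`I0 · exp(−dOD)` with 0.3% multiplicative measurement noise.

Motion events occur at Poisson times per scan and hit all channels and
both wavelengths coherently (head movement), with independent amplitude
and sign per channel: spikes (0.5/min, 0.1–0.6 OD, ~0.4 s wide gaussian
bumps) and baseline shifts (0.2/min, 0.1–0.3 OD steps persisting to the
end of the scan).  Artifact amplitudes are one to two orders of magnitude
above the hemodynamic OD signal (~0.001–0.004 OD), as in real infant data.
The ground truth records the contaminated samples, the true amplitudes and
the noiseless concentration series.

### Reproducibility

Everything is a pure function of (config, seed).  Participant `i` uses the
stream `SeedSequence([master_seed, i])`; the design scheduler and each
inference family derive their own streams the same way (families via a
CRC-32 of the family label).  Identical seeds reproduce scan containers
byte for byte.

## The inverse chain (preprocessing)

Fixed order, logged per scan: prune → OD → detect → spline → wavelet →
re-detect/flag → band-pass → concentration.  Stages are shape-preserving;
channel availability only ever shrinks.

Choices the upstream literature leaves open, and what this package does:

* **OD convention** — natural log (`−ln(I/mean I)`), not log10.
* **Motion detection** — per channel, both wavelengths (either triggers).
  Within each 1 s sliding window the peak-to-peak OD excursion is compared
  with `AMPthresh` (4 OD) and with `STDEVthresh` (15) times the standard
  deviation of the channel's *sample-to-sample differences*.  The
  difference-based reference level is the semantics of the widely used
  reference implementation: slow physiology contributes almost nothing to
  it, so fast artifact excursions stand out, whereas a threshold of 15
  raw-signal standard deviations could never catch a 10-sd spike.
  Triggered windows are flagged with a ±1 s (`tMask`) margin.
  *Degenerate input:* on mathematically noise-free data the adaptive
  threshold collapses (any smooth change is infinitely many sigma) and the
  detector flags aggressively; the package's clean-input validation
  therefore uses a vanishing instrument-noise floor (relative sd 1e-4)
  rather than strictly zero noise.  Real recordings always carry shot
  noise, so this regime does not occur in practice.
* **Spline correction** — within each flagged segment a cubic smoothing
  spline (penalized least squares, `lam = (1−p)/p`, p = 0.99) is fitted
  and subtracted; then all segments are rejoined sequentially by matching
  each segment's leading ~1 s mean level to the previous segment's
  trailing level.  This removes step artifacts without introducing
  discontinuities; clean segments keep their waveform exactly and can only
  receive a constant offset (irrelevant after band-passing).  Segments at
  recording edges anchor one-sidedly; segments shorter than 4 samples are
  mean-corrected.
* **Wavelet filtering** — db2, per level interquartile fences
  `[Q1 − 0.5·IQR, Q3 + 0.5·IQR]`; detail coefficients outside the fences
  are zeroed.  The decomposition depth is the deepest level whose
  approximation band still contains the hemodynamic frequencies
  (approximation cutoff `fs/2^(L+1) ≥ 0.1 Hz`; L = 5 at 10 Hz,
  overridable).  Deeper decomposition would place the response itself in
  detail levels where its coefficients are outliers and get zeroed —
  i.e., maximum feasible depth destroys the signal the pipeline exists to
  estimate.  A zero-IQR level is left untouched.
* **Block validity** — motion detection is re-run on the corrected OD; a
  block is invalid on a channel if its −3..30 s epoch window overlaps any
  flagged sample on that channel.
* **Band-pass** — 3rd-order Butterworth, 0.01–0.09 Hz, applied
  forward-backward (zero phase).
* **Pruning boundary** — SNR exactly equal to the threshold is retained;
  zero-variance (constant) channels count as infinite SNR.

## Block averaging and exclusion

Epoch grid: −3 s to 30 s inclusive at both ends (331 samples at 10 Hz),
baseline = mean over [−3, 0), statistic = mean over [0, 30] of the
baseline-corrected average of valid blocks.  The pre-onset baseline window
necessarily contains the tail of the previous (opposite-condition) block's
response — a property of the paradigm, not of this implementation; it
attenuates but does not invert condition differences.  Summary cells exist
only where a condition has at least `min_valid_blocks_per_condition` (3)
valid blocks; an ROI channel is available only if both conditions do; a
participant is retained only with at least `min_available_rois` (5) of the
6 ROI channels.  Blocks are averaged within participant before any group
statistic; blocks are never pooled across participants.

## Inference

Per family (age group × {HL, LH, HL−LH} × {oxy, deoxy}): channel-wise
t statistics (`t = mean/(sd/√n)`, df = n−1), Cohen's `d = mean/sd = t/√n`,
and a max-|t| permutation null of 10,000 draws.  One sign per participant
per permutation, applied jointly to all channels — this preserves the
spatial correlation of the summaries, which is what makes the max-|t|
correction exact rather than conservative-by-independence.  Label swapping
in the paired families is implemented as sign-flipping the
within-participant differences (algebraically identical, same stream).
Channels with fewer than 2 contributors, or zero variance, are dropped
from the max with a logged warning; per-channel n (and df) follow the
available participants.  Corrected p uses add-one smoothing
`(1+b)/(1+m)` — never exactly zero, exact for the identity permutation —
with a relative 1e-9 tie guard so that permutations reproducing the
observed magnitude count toward the tail regardless of floating-point
evaluation order.

Calibration evidence (recomputed by `scripts/acceptance.py` and the test
suite, not asserted from memory): on 500 global-null cohorts (n = 30, six
channels with equicorrelation 0.3, 2,000 permutations) the family-wise
corrected rejection rate at α = 0.05 falls within [0.03, 0.07]; a
standardized paired effect of 0.8 on one left ROI channel (n = 30) is
detected with corrected p ≤ 0.05 in well over 80% of cohorts and
localizes to the injected channel.  Sampled corrected p agrees with
exhaustive sign-flip enumeration (n ≤ 10, up to 3 channels) within
3 binomial standard errors at 10,000 draws.

## Problem sizes used in validation

The shipped checks use ROI-only layouts (6 channels), cohorts of 12–30
participants, 2,000-permutation nulls for Monte-Carlo sweeps (10,000 for
single-family checks), 500 cohorts for error calibration and 100 for
power — sizes chosen so the full validation suite completes in minutes on
one CPU while keeping Monte-Carlo error well inside the asserted margins.

## What the synthetic validation does not show

The generator emulates the statistical structure of infant block-design
recordings, not their full physiology: no systemic/superficial-layer
component distinct from the cerebral signal, no short-separation channels,
no heart-rate pulsation (above band at 10 Hz sampling but aliased in real
systems), no slow state changes (sleep/fuss transitions), and motion
statistics far simpler than real infant movement.  Passing tests therefore
demonstrate that the pipeline implements its stated operations correctly
and that the inference machinery is calibrated — not that the pipeline's
corrections are optimal for any particular real dataset.  The HRF and
noise defaults are stand-ins and should be treated as configuration, not
as empirical claims about infants.  SNIRF import is a possible extension;
the package reads its own documented CSV/JSON scan containers (and an
equivalent HDF5 variant).
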