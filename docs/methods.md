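# Methods

`mirrorloop` simulates and analyzes sensorimotor EEG collected while an
observer watches virtual finger movements — either passively or as feedback
of a P300 speller that the observer controls — and quantifies three families
of neural signatures: mu/beta event-related desynchronization (ERD),
post-error low-beta synchronization (ERS), and error-related potentials
(ErrP).  This note documents the generative model, the analysis chain, the
numerical choices, and what the synthetic benchmark does and does not
establish about real data.

## Study design being emulated

Each simulated subject completes three sessions:

* **Voluntary execution block** (default 20 movements): used only to
  calibrate subject-specific mu and beta frequency subranges.
* **Passive observation** (60 movements, 2 s each — 1 s flexion, 1 s
  extension — separated by 2.5–4.5 s rest): half the movements are announced
  by a cue 1 s before onset ("AAO"), half start unexpectedly ("AO"). The
  split is exactly balanced, then shuffled.
* **P300-speller feedback session** (40 trials): each trial flashes 4
  fingers 10 times each (100 ms flash, 200 ms inter-stimulus interval — 40
  flashes per trial), then, after a 2 s anticipation gap, plays the decoded
  finger's flexion as feedback. On exactly 15 randomly chosen trials the
  loop deliberately shows a *different* finger, so a perfect decoder's
  feedback accuracy is exactly 25/40 = 62.5%.

The 2 s anticipation gap and the 3 s inter-trial interval are not dictated
by the task literature values above; they were fixed once at design time (the
gap must exceed the 0.7 s pre-feedback analysis window; see below).
The rest epochs for the passive sessions are taken 0.5–2.5 s after movement
*offset* — inside the guaranteed 2.5 s minimum rest — and 4–2 s before
feedback onset for the speller session.

## Generative model

Signals are produced by linear forward mixing, `X = Σ aᵢ sᵢ(t) + noise`,
with per-source isotropic Gaussian scalp patterns on great-circle distance
(unit-sphere 10-10 layout computed geometrically; pattern width 0.4–0.6 rad)
and a fixed 2:1 left-hemisphere weighting for the sensorimotor sources
(right-hand task).  Source time-courses:

* **Oscillatory sources** are band-limited Gaussian noise carriers
  (4th-order Butterworth on white noise, unit rms) multiplied by a
  condition-dependent amplitude envelope.  The mu source (subject-specific
  ~5 Hz band inside 6–15 Hz, centered near C3, 4 µV rms) declines linearly
  in dB from 1 s before an *anticipated* onset to −3 dB at onset and to
  −6 dB at the flexion apex, recovering during extension; for unexpected
  (AO) movements the pre-onset decline is absent.  The beta source (15–25 Hz,
  2.5 µV) declines only after onset.  The low-beta ERS source (12–17 Hz,
  3 µV) carries a raised-sine +3 dB bump inside 0.8–1.75 s after onset on
  error-feedback trials only.  An occipital 8–12 Hz alpha source (4 µV,
  constant) acts as the spatial confound CSP must reject.
* **Transient sources** are Hann-windowed monophasic deflections: Ne
  (−1.5 µV, 250 ms), Pe (+8 µV, 500 ms), Ip (−1.5 µV, 700 ms) time-locked to
  erroneous feedback at FCz; a P300 (+5 µV, 350 ms, Pz) locked to attended
  flashes only.  Ne and Ip are deliberately sub-threshold so that, like the
  reported findings, only the Pe contrast reaches group significance; the
  Pe amplitude was set so the error contrast shows the large effect size the
  phenomenon is known for.
* **Noise**: per-channel independent 1/f (exponent 1, 8 µV rms) plus a
  volume-conducted shared 1/f term (4 µV); optional blink (60 µV frontopolar
  Hann transients, 0.15/s) and bursty temporal-muscle (25–40 Hz, 8 µV)
  artifact sources.

Between-subject variability is a lognormal multiplier (σ = 0.2) on every
effect magnitude, plus a ±1 Hz jitter of the mu source band.  All randomness
flows from one `SeedSequence` root, one spawned stream per subject;
identical spec + seed reproduces recordings bit-for-bit.

Because the closed loop cannot be simulated acausally, the generator assumes
the attended finger is decoded correctly, applies the forced-error injection
itself, and labels trials accordingly; the analysis re-decodes offline from
the synthesized EEG and reports that accuracy separately.

## Analysis chain

1. **Preprocessing** — zero-phase 4th-order Butterworth 1–40 Hz (an optional
   mains notch exists but is off by default: the simulated amplifier notch
   already ran at acquisition); seeded FastICA (fixed-point negentropy,
   deflation) fitted once per subject on 10×-decimated data from the longest
   session; components with |r| ≥ 0.8 against the mean of Fp1/Fp2 are ocular,
   components with ≥ 40% of absolute map weight on T7/T8/FT7/FT8 muscular
   (on this 48-channel montage, a perfectly focal temporal source tops out
   near 50%, diffuse sources near 15%); flagged components are projected
   out; average reference last.  Epoch rejection replaces visual inspection
   with a |value| > 120 µV criterion.
2. **Band calibration** — Morlet ERD/S map of the execution block at C3;
   the subject band is the contiguous set of frequencies at least half as
   deep as the deepest post-onset ERD, clipped to the search range (mu
   6–15 Hz, beta 12–30 Hz), minimum width 2 Hz, falling back to the full
   range if no ERD exists.
3. **CSP** — per band and session, two-class (active vs rest) common
   spatial patterns from trace-normalized epoch covariances with iterative
   Frobenius-outlier cleaning (robust z > 2.5, at most 20% rejected, never
   below 3 epochs), 10⁻³ shrinkage toward the scaled identity, generalized
   eigenproblem `C_a w = λ(C_a + C_r) w`.  Six candidates (three per
   eigenvalue tail); retained components need ≥ 60% of absolute pattern
   weight over the FC/C/CP rows (falling back to the single most central
   candidate if none passes — CSP patterns estimated from a few dozen noisy
   epochs scatter around the ideal topography).  For the ERS band the active
   class is the error-trial 0.75–1.8 s window and only the high-eigenvalue
   tail is eligible, because a synchronization source *raises* active-class
   variance.
4. **ERD/S** — *induced* power: the per-condition evoked response is
   subtracted from each component epoch (with a √(n/(n−1)) variance
   restoration) before the wavelet transform, so phase-locked transients —
   the error potentials in particular — cannot masquerade as band-power
   differences between conditions.  Then: complex Morlet transform, temporal amplitude-envelope FWHM
   140 ms (hence cycles grow with frequency; spectral power FWHM
   (2 ln 2)/(π·0.14) ≈ 4.46 Hz), grid 3–30 Hz in 0.3 Hz steps where needed;
   kernels are L2-normalized, truncated at ±5σ, and DC-corrected for
   admissibility (only material below ~8 Hz).  Power is divided by the
   median resting power per frequency (median over rest epochs × time
   points), log-scaled to dB, and collapsed by the median over epochs, band
   frequencies and retained components.  Edge samples within half the
   kernel support are flagged and excluded from reference statistics.
   The per-frequency (not band-pooled) reference preserves the 1/f shape.
5. **Statistics** — per-time F = t² (paired or one-sample, n−1 dof);
   TFCE with E = 0.5, H = 2, dh = 0.1 integrated to the map maximum;
   sign-flip permutation null of the map maximum (exhaustive enumeration of
   2ⁿ flips when n ≤ 12 and affordable), p = (1 + #{null ≥ obs})/(1 + n_perm).
   Spatio-temporal ERP contrasts use a fixed cluster-forming threshold
   F = 20, spatial adjacency = electrode pairs within 0.5 rad (median 7
   neighbors), time contiguity, cluster mass = summed F.  Cohen's d for a
   cluster is the paired effect size of per-subject cluster means (sample
   sd, n−1).  ERD/S time-courses are decimated ×10 (to 50 Hz) before the
   1-D tests; the wavelet's 140 ms envelope makes finer sampling redundant.
6. **Speller decoding** — flash epochs 0–0.8 s, 0.5–12 Hz, 12 centro-parietal
   channels, 20 ms block means (480 features); shrinkage LDA (lsqr,
   Ledoit–Wolf) trained in 5-fold cross-validation grouped by trial; a
   trial's finger is the argmax of mean flash scores, ties to the lowest
   index.

## Numerical and design choices worth knowing

* The FWHM convention interprets the 140 ms as the *amplitude*-envelope
  width; this reproduces the quoted 4.5 Hz spectral width (the power-envelope
  reading would give ≈ 3.15 Hz and is rejected).
* F = t² is invariant under a global sign flip, so an exhaustive null at
  n = 5 has minimum attainable p = 2/32; tests on such tiny designs must
  choose α accordingly.
* TFCE for permutation nulls runs in a numba kernel computing only the
  per-permutation maximum; the public `tfce_enhance` is the reference
  implementation, and both are pinned to a brute-force threshold-integral
  oracle at 10⁻⁹ in the tests.
* Degenerate inputs: zero-variance time points give F = 0 (or a capped,
  flagged value when the mean is nonzero); zero between-subject spread makes
  Cohen's d infinite with a warning; an empty rest reference or an
  all-rejected epoch set raises.
* The detection rule used in recovery reports: cluster p < α and ≥ 50% of
  the cluster's time extent inside the generating window.

## Problem sizes

Default analyses use the full study geometry (20 subjects, 48 channels,
500 Hz, 40 speller trials, 60 passive actions).  The test suite runs the
end-to-end recovery check on five seeds at 1 000 permutations per contrast
(permutation p-values are valid at any count; α is unchanged), the
null-calibration check on 200 replicate cohorts at 500 permutations, and the
zero-noise ERD/ERS round-trips at 240–250 events so the median-based readout
noise (≈ 0.2 dB) is small against the 0.5 dB tolerance.

## What the synthetic benchmark does and does not show

The generator reproduces the *assumed* signal structure: linear mixing,
stationary 1/f background, narrowband Gaussian carriers, fixed-shape
transients, and exactly the trial arithmetic of the tasks.  Passing tests
therefore demonstrate that the pipeline recovers known effects at realistic
SNR and controls false positives under this model.  They do not establish
robustness to non-stationary artifacts, correlated noise with realistic
spatial structure, electrode drift or bridging, imperfect event timing, or
non-Gaussian oscillatory dynamics (e.g. mu rhythm's arc shape), and the
Gaussian-pattern forward model is far simpler than a boundary-element head
model.  Conclusions about real recordings require the usual caution.

## Known limitations

* ICA on mixtures containing *Gaussian* band-limited sources cannot isolate
  them (they carry no non-Gaussianity); only sparse/bursty artifacts are
  reliably removed.  Artifact removal slightly perturbs overlapping brain
  signal, visible as a small decoding-accuracy cost.
* Classic EDF quantizes to 16 bits of the per-file amplitude range; round
  trips are exact only to that least significant bit.
* The central-pattern criterion is montage-specific; other montages need
  their own central row set and possibly a different threshold.
* No bad-channel interpolation, resampling, or current-source-density
  transform; multiclass CSP and single-trial ErrP classification are out of
  scope.
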