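# Methods

## Scope

`earbci` re-implements a complete ear-EEG endogenous-BCI analysis as a
reusable, tested pipeline. Because no public recordings exist for this
paradigm, the package pairs the analysis with a synthetic-data
generator whose *structure* (not its numbers) mirrors the
neurophysiology the analysis assumes. Green tests therefore establish
that the pipeline recovers known injected effects with the correct
sign, band, topography and timing, and that it is unbiased under null
effects — they do not certify performance on real recordings.

## The synthetic world

**Sources and mixing.** Channel signals are linear mixtures of a small
set of sources plus independent 1/f^k noise per channel (k = 1 by
default, RMS 5 µV after 1–50 Hz filtering; generated by FFT-domain
spectral shaping). Each source projects to the 31 electrodes with
weight `exp(-d/spread)` where `d` is the distance in a fixed 2-D
layout of the montage and `spread = 0.6` (head radius 1). A physical
forward model is deliberately not used: only the qualitative leakage
ordering (occipital ≫ ear > central > frontal for occipital sources)
needs to be right, and exponential distance decay guarantees it.

**Alpha.** Two partially independent occipital alpha sources sit at
(±0.3, −0.95), each a 10 Hz sinusoid (amplitude 10 µV) with a slow
±0.5 Hz frequency random walk and a mild waxing/waning amplitude
envelope (SD 0.25, ~1 s correlation). A *bilateral pair* rather than
one midline source is essential: the ear ROI is re-referenced to the
opposite ear's mean, and a midline source projects mirror-symmetrically
onto the two ears, so a single source would be almost completely
cancelled by the cross-ear reference and the ear region would lose its
alpha — contradicting the phenomenon the analysis is built to measure.

**Beta/gamma.** Two bilateral fronto-central sources at (±0.4, 0.5)
emit 14–50 Hz band-limited Gaussian noise (RMS 14 µV). Their anterior
placement makes broadband desynchronization strongest fronto-centrally,
the opposite regional gradient to the alpha synchronization — matching
the reported physiology.

**Condition modulation.** Eyes-closed multiplies alpha amplitude by
`ec_alpha_gain = 2.0`. Mental arithmetic multiplies alpha amplitude by
`ma_alpha_ers = 1.8` (alpha ERS) and β/γ source *power* by
`ma_beta_gamma_erd = 0.7` (broadband ERD); the light-cognitive task
applies `lc_alpha_gain = 1.1` only. Envelopes ramp with a raised-cosine
kernel over ~0.5 s at event boundaries. Task gains are additionally
jittered per trial on the log scale, `g -> g^(1 + 0.7 z)` with
`z ~ N(0,1)`, modelling trial-to-trial variation in task engagement.
Two properties of this parameterization matter:

* a unit gain stays exactly unity, so *null worlds stay null* — the
  calibration tests (chance-level accuracy, ~0 dB SNR) are exact;
* the jitter applies to MA/LC only; the eye-closure alpha increase is
  treated as automatic, keeping the EC/EO SNR estimates stable.

The effect sizes are calibration choices for a realistic synthetic
benchmark (per-region accuracies land in the 75–90 % range, EC/EO SNRs
of roughly 0.3/2/6/5 dB for frontal/central/occipital/ear), not claims
about any particular dataset. Per-subject effect gains are additionally
jittered (lognormal, SD 0.10) by the study runners so group tables have
realistic between-subject spread.

**Blinks.** Eye blinks are ~300 ms raised-cosine transients at Poisson
times with an exponential frontal-dominant profile normalized to 1 at
the frontopolar electrodes (default 180 µV, 0.4/min in the study
runner). They exist to exercise peak-to-peak rejection; EMG/ECG and
movement artifacts are not modelled.

## Analysis choices

* **Filtering.** "Zero-phase 4th order" is read as a 4th-order
  Butterworth design applied forward–backward (`sosfiltfilt`), i.e.
  zero phase and 8th-order magnitude. Downsampling keeps every 5th
  sample after the 1–50 Hz bandpass and warns if no adequate lowpass
  preceded it.
* **Referencing.** CAR within each 6-channel scalp ROI; the ear ROI
  references each side to the opposite ear's pre-reference mean. The
  scalp reference condition ("all electrodes") is CAR over the 25 scalp
  channels, exposed as a fifth pseudo-region.
* **Rejection scope.** Peak-to-peak is computed per channel over the
  full −2–10 s epoch and maximized over the union of ROI channels (24
  of 31); a trial is dropped when that maximum *strictly* exceeds the
  threshold. Thresholds default to the reported group means (126.67 µV
  task, 196 µV EC/EO) and are per-run configurable. Note that with
  strong per-trial engagement jitter an occasional artifact-free,
  high-alpha trial can legitimately exceed the task threshold.
* **EC/EO SNR.** STFT frames (1 s Hann, 50 % overlap) are assigned to a
  condition only when the full window lies inside one block. Alpha
  power (8–13 Hz) is averaged over frames and over the ROI's six
  channels in the *power* domain before the dB transform.
* **ERD/ERS.** Per 1 Hz-wide bin: zero-phase order-2 Butterworth
  bandpass, squared analytic-signal magnitude, trial average, percent
  change vs. the −2–0 s baseline mean. Epochs are reflect-padded by 1 s
  before filtering/Hilbert so edge transients fall outside the analyzed
  window; a bounded few-percent residual remains on strongly
  deterministic signals (see the flat-profile test).
* **CSP.** Per-trial covariances over the 0–10 s task window are
  trace-normalized before class averaging. The generalized eigenproblem
  is solved by whitening the composite covariance `C1 + C2` *in its
  numerical column space*: directions whose composite eigenvalue is
  below 1e-7 of the largest are discarded (with a 1e-8·trace ridge as
  an additional stabilizer). This matters because CAR makes a
  6-channel ROI exactly rank-5; a ridge alone lifts the null direction
  into the eigenbasis, where it becomes a zero-variance
  "most-discriminative" component whose log-variance feature is
  numerical noise and destabilizes the classifier. "Two first and last
  components" is read as 2+2 per band (20 features over 5 bands);
  1+1 is available via `n_keep=1`.
* **Shrinkage LDA.** The analytic Ledoit–Wolf intensity toward ν·I
  (ν = mean eigenvalue) is computed on class-centered pooled data;
  the implementation agrees with scikit-learn's estimator to 1e-10 and
  scikit-learn serves only as a cross-check in the tests. Two
  estimator facts worth knowing: with data whose true covariance *is*
  isotropic the optimal intensity approaches 1 (the target is the
  truth), and with exactly 2 samples the estimated estimation-variance
  degenerates to 0. A decision score of exactly 0 is assigned to the
  positive class (the lexicographically second label — MA for MA/LC).
* **Cross-validation.** Stratified 10-fold, repeated 10 times with
  per-repetition fold seeds derived from one master seed. CSP filters
  and the classifier are fit on training folds only. Band filtering and
  per-trial covariances are label-free and therefore computed once; a
  deliberate `fit_csp_on_all` ablation reproduces the classic CSP
  leakage mistake for diagnostics and is off by default.
* **Statistics.** Friedman uses the tie-corrected rank statistic with
  the χ²(k−1) approximation; an exact within-row permutation
  enumeration is available for tiny tables. Wilcoxon signed-rank is
  exact (2ⁿ sign enumeration, valid under ties) for n ≤ 15 and uses
  the tie-corrected normal approximation beyond; post-hocs are
  two-sided with Bonferroni-corrected α = 0.05/6 for all ROI pairs.

## Reproducibility

Every stochastic step receives a seed derived from a single
`SeedSequence`; simulations are bit-identical under a fixed seed, and
study runners write a manifest (full config + package version) whose
re-run reproduces outputs byte-for-byte. EDF output uses a minimal
built-in writer (plain EDF, 1 s records, 16-bit physical scaling), so
round-trips are exact up to the per-channel quantization step.

## Known limitations

The generator does not model biophysical volume conduction, realistic
artifact families other than blinks, non-stationary noise floors,
electrode impedance drift, or inter-subject anatomical variability; its
trial-to-trial variability is a single lognormal engagement factor.
Consequently the absolute accuracies and SNRs produced here are
properties of the chosen synthetic world. The reported group tables of
the original experiment are reproduced *in structure* (same pipeline,
same statistics), not in value — the underlying recordings were never
deposited.
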