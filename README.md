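# earbci

Analysis pipeline for **endogenous brain–computer interfacing with
ear-EEG**: EEG recorded from a handful of electrodes behind the ears
instead of a full scalp cap. The scientific question the package
addresses is whether behind-the-ear electrodes pick up enough
self-modulated brain activity — no external stimuli — to discriminate
two mental tasks reliably, compared with conventional scalp regions.

The package implements, end to end and fully tested:

* a 31-channel montage (25 scalp 10–20 electrodes + R1–R3/L1–L3 behind
  the ears) partitioned into four 6-electrode regions of interest
  (frontal, central, occipital, ear);
* both experimental paradigms as event schedules — alternating 30 s
  eyes-closed/eyes-open (EC/EO) blocks, and a main experiment of 5
  sessions × (10 mental-arithmetic + 10 light-cognitive trials), each
  trial 5 s instruction + 10 s task + 10–15 s rest;
* a **synthetic EEG generator** (1/f background, bilateral occipital
  ~10 Hz alpha sources with distance-decaying mixing, fronto-central
  broadband β/γ sources, condition-dependent gain modulation, frontal
  blink artifacts) so every stage has ground truth without any data
  download;
* preprocessing: zero-phase 4th-order Butterworth 1–50 Hz bandpass,
  downsampling to 200 Hz, per-ROI common average reference (CAR; the
  ear ROI uses a modified CAR referencing each side to the opposite
  ear's mean), epoching −2–10 s around task onset, −2–0 s baseline
  correction, and peak-to-peak artifact rejection (default threshold
  126.67 µV for task data, 196 µV for EC/EO);
* spectral analysis: STFT (1 s Hann window, 50 % overlap), the
  eyes-closed/eyes-open alpha signal-to-noise ratio

  $$\mathrm{SNR} = 10\,\log_{10}\!\left(\frac{\alpha_{EC}}{\alpha_{EO}}\right)\ \mathrm{dB},$$

  and event-related (de)synchronization maps
  $\mathrm{ERD/ERS}(f,t) = 100\,(P(f,t) - R(f))/R(f)$ in % vs. the
  pre-task baseline;
* classification: **multi-band common spatial patterns** (δ 1–3, θ 4–7,
  α 8–13, β 14–29, γ 30–50 Hz; filters from the generalized eigenproblem
  $C_1 w = \lambda (C_1 + C_2) w$, first and last two components per
  band, log-variance features) + **shrinkage LDA** (Ledoit–Wolf
  regularized pooled covariance), evaluated with 10×10-fold stratified
  cross-validation, CSP re-fit inside every training fold;
* group statistics: Friedman test across ROIs, Wilcoxon signed-rank
  post-hocs, Bonferroni correction.

## Worked example

```python
import earbci as eb

cfg = eb.RunConfig(n_subjects=2, seed=3)          # two synthetic subjects
result = eb.run_ec_eo_study(cfg)
print(result["summary"].to_string(index=False))
```

prints

```
      roi  snr_db_mean  snr_db_std
  frontal     0.335941    0.228851
  central     1.965580    0.193777
occipital     6.056661    0.252057
      ear     4.970770    0.108674
```

i.e. closing the eyes raises occipital alpha power by ~6 dB in this
synthetic cohort, and the ear electrodes — which sit close to the
occipital lobe — retain most of that contrast (~5 dB), while frontal
electrodes see almost none. This occipital > ear > central > frontal
ordering is forced by the generator's distance-decaying source mixing
and is what makes ear-EEG plausible for alpha-based applications.

The classification study runs the same way:

```python
result = eb.run_ma_lc_study(eb.RunConfig(n_subjects=5, seed=1, compute_maps=False))
print(result["roi_mean_accuracy"])
```

which simulates five subjects at the full experimental scale,
preprocesses and artifact-rejects their trials, and reports per-region
mean 10×10-fold CV accuracies (~84–90 % with the default injected
effect sizes — every region, including the ear, above the 70 % bound
usually quoted for usable binary communication). `result["stats"]`
holds the Friedman test across the four ROIs and the Bonferroni-corrected
Wilcoxon post-hocs.

A thin CLI wraps the same functions:

```sh
earbci simulate --paradigm ec-eo --seed 1 --out out/   # EDF + schedule CSV
earbci snr --out out/ec_eo --subjects 2 --seed 3
earbci classify --out out/ma_lc --seed 1 --no-maps
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the pipeline's headline quantities from scratch: it builds
the montage and paradigm schedule, simulates five subjects with the
default effect structure, runs the full preprocessing + multi-band
CSP/sLDA cross-validation per region, and writes the resulting
accuracy bound together with the structural counts (trials per
condition, electrodes per ROI, total electrodes) as JSON.

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical choices, and what the synthetic benchmark does and does not
establish.
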