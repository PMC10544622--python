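# Methods

This note records the models, assumptions and numerical choices behind
`mepkit`, in the order the pipeline runs.

## 1. Synthetic MEP cohorts

### What is emulated

One *trace* is a 100 ms window sampled at 20 kHz (2000 samples) from one
muscle channel of one patient.  The generator emulates exactly the
statistics the downstream pipeline consumes:

* **Window geometry** — 2000 samples; a train of five alternating-sign
  triangular stimulation-artifact pulses at 2, 4, 6, 8, 10 ms (amplitude 3.0
  normalized units, 5 samples wide), entirely before the 17.5 ms cutoff.
* **Blanks** — with probability `blank_rate` a window contains no MEP (the
  stimulation threshold for that muscle was not reached).  Defaults
  0.25 / 0.29 / 0.70 / 0.79 for EXT / APB / TA / AH echo the published
  per-muscle preselection survival ratios: lower-limb channels contain far
  more blanks under supratentorial threshold stimulation.
* **MEP morphology** — 1–3 damped-cosine bursts
  `A · exp(−t/τ) · cos(2πft)`, rescaled **after sampling** so the sampled
  peak-to-peak equals the drawn amplitude exactly.  Per-muscle frequency
  (600 / 500 / 400 / 320 Hz) and decay (0.28 / 0.72 / 0.90 / 1.13 ms) were
  tuned once so the median number of prominence-qualifying peaks is
  1 / 2 / 2 / 2.  Additional bursts start 2–10 ms after the first with
  0.4–0.9 of its amplitude.
* **Onset latency** — normal, truncated to [17.5 ms, 80 ms].  The
  underlying (μ, σ) per muscle were solved with Brent's method so the mean
  of the *sample-quantized* truncated distribution equals the target
  first-peak latency (17.53 / 20.01 / 24.69 / 31.03 ms).  The EXT target
  sits 0.03 ms above the cutoff; any distribution on [17.5, 100] with that
  mean is necessarily concentrated at the cutoff (one-sided variance bound
  ≈ 1.6 ms), so the published EXT latency SD cannot be reproduced jointly
  with its mean and is not a calibration target.  For the same reason the
  burst uses cosine phase: its first extremum falls *on* the onset sample,
  otherwise the mean first-peak latency could never reach 17.53 ms.
* **Amplitude** — `min(LogNormal(ln median, σ_log), cap)`, i.e. a
  heavy-tailed draw saturated at a per-muscle cap, emulating the finite
  amplifier range.  The saturation atom is load-bearing: normalization
  divides by each patient's largest absolute sample, and with ~100 traces
  per channel the patient maximum sits at the cap with high probability,
  which is what makes the *normalized* amplitude means stable enough to
  calibrate (target means 0.09 / 0.34 / 0.20 / 0.11).  σ_log = 1.2
  (1.4 for AH); medians and caps were calibrated by damped fixed-point
  iteration against full simulated cohorts and frozen as defaults.
* **Patient heterogeneity** — a lognormal per-patient gain (σ = 0.4)
  multiplies the whole trace.  Because preselection thresholds are relative
  and normalization is per patient, the gain cancels exactly in all
  normalized statistics; it matters only for raw-unit exports.
* **Noise** — white Gaussian, SD 1e-4 normalized units.  The noise floor is
  deliberately far below the MEP scale so that preselection attrition comes
  from blanks (as in the emulated data flow, where blanks are removed in
  preprocessing) rather than from noise peaks.  Blank windows are still
  rejected robustly: for pure noise the prominence threshold (2 SDs of the
  rectified trace) is scale-free and dozens of noise peaks exceed it,
  tripping the >10-peaks bound.

Reproducibility: a cohort is a pure function of its `GeneratorConfig`
(including the seed).  Each patient owns a `SeedSequence`-spawned child
stream, so per-patient data is independently reproducible.

### What is *not* emulated

No volume conduction, anesthesia effects, electrode impedance drift,
stimulation-intensity titration, acquisition cadence, or the hardware
30 Hz–5 kHz band-pass (band-limited noise is approximated by a low noise
floor).  Rectified-AUC means are reported but not calibrated — the
published AUC values are not jointly consistent with the amplitude/latency
targets under any single-burst-family waveform, and nothing downstream
consumes them as targets.  A green calibration test therefore establishes
that the pipeline reproduces the *summary statistics* it was calibrated to,
not that the classifiers face realistically hard data; real recordings are
noisier and more heterogeneous, and classification scores on synthetic
cohorts are expected to be optimistic.

## 2. Preselection

* Peaks are detected on the rectified signal so both polarities count.
* The prominence threshold is 2 × SD of the rectified **post-cutoff**
  segment of the same trace.  Using the full trace would let the artifact
  train dominate the SD and silence genuine peaks.
* A window is an MEP iff 1 ≤ peaks ≤ 10; accepted windows lose samples
  0–349 (17.5 ms), keeping 1650.
* Normalization divides each of a patient's accepted traces by the largest
  absolute sample over **all** of that patient's accepted traces (across
  muscles, matching the per-patient reading of the published description);
  after it the patient maximum equals exactly 1 in floating point.
* Tie-break: for plateau maxima the leftmost plateau sample is the peak
  index.  A constant post-cutoff segment (SD = 0) has no peaks.

## 3. Features

* **Onset latency** — baseline mean μ over the final 20 ms of the window;
  threshold 2 × SD of the whole analyzed trace; the onset is the first
  post-cutoff sample with |x − μ| > 2σ.  The whole-trace σ follows the
  literal published definition; a baseline-only σ would degenerate (white
  noise crosses 2σ_noise within a millisecond of the cutoff in every
  trace, destroying the feature).  Adding a constant to the trace shifts μ
  and leaves σ unchanged, so the onset is translation invariant.
* **End of signal** — onset latency of the time-reversed trace mapped back
  to forward time (the last excursion from baseline).  The alternative
  reading (sign-flipped trace) would measure the negative phase's onset,
  not an end, and is rejected.
* **Imputation** — a trace with no threshold crossing gets onset = cutoff
  and end = window end (logged); this keeps the feature matrix rectangular
  without discarding gated traces.  If the baseline σ is 0 the criterion
  degenerates to "first nonzero deviation".
* **AUC** — trapezoidal integral of |x| over the post-cutoff window, in
  normalized units × ms.
* **PCA** — `sklearn.decomposition.PCA(n_components=0.95, svd_solver="full")`
  fitted on training rows only: the smallest k whose cumulative explained
  variance reaches 0.95.  A zero-variance matrix yields a 0-component model
  that refuses to transform.

## 4. Learning

* **Split** — whole patients are assigned 28:8 uniformly at random by seed;
  two-class paradigms drop rows of that same split rather than re-splitting.
* **SMOTE** — implemented in-package (no imbalanced-learn in the runtime):
  each synthetic row is `x + u(x′ − x)`, `u ~ U[0,1)`, with x′ one of the
  k = 5 nearest same-class neighbors (k is clipped to class size − 1);
  all classes are raised to the majority count; originals are preserved.
  Augmentation happens on the raw 1650-dimension training matrix *before*
  compression; PCA is then fitted on the balanced matrix and the 7 features
  are recomputed from the interpolated signals, so every representation
  sees the same balanced training population and the test set never
  touches a fitted transform.
* **Grids** — the study's exact grids are unpublished; declared substitutes
  bracket common defaults: RF trees {100, 300, 500} × depth {∞, 10, 20};
  kNN k {1, 3, 5, 11, 21} × {euclidean, manhattan}; logistic-regression
  C {0.01, 0.1, 1, 10, 100}.  Scoring is mean stratified k-fold CV accuracy
  (10 folds by default; stratification prevents folds missing a class);
  ties resolve to the first grid point.
* **Logistic regression** on 1650-dimension raw data gets `max_iter=2000`;
  non-convergence is a logged warning, not an error (raw-trace logistic
  regression is expected to be the weak cell).
* **Score vectors** — random forest: mean tree-vote probabilities; kNN:
  neighbor-vote fractions; logistic regression: model probabilities.  Rows
  sum to 1.

## 5. Evaluation

* Accuracy = trace/total of the count confusion matrix (exact identity,
  asserted in tests).
* Macro F1 = unweighted mean over classes of 2TP/(2TP+FP+FN); a class with
  no true and no predicted members contributes 0 (documented convention).
* ROC AUC: binary — rank AUC with ties counted half; multiclass — macro
  mean of one-vs-rest AUCs (the published convention is unstated; every
  report is stamped with `"macro one-vs-rest"`).  A one-vs-rest split with
  a single class present is skipped with a warning.
* The 4×4 muscle confusion matrix aggregates to a 2×2 upper/lower-extremity
  matrix by summing within-limb cells; counts are conserved and limb
  accuracy can only gain from within-limb confusions.

## 6. Orchestration and seeds

A `RunConfig` (YAML-serializable, hash-stamped) fully determines a run.
The run seed expands into per-stage seeds via
`SeedSequence(seed, spawn_key=(stage_index,))`, stage order
generate = 0, split = 1, so stages can be re-run in isolation.  All stage
counts (generated / accepted / rejected / per-cell) are logged.

## 7. Known limitations

* The synthetic world is exactly as hard as its calibration: latency
  separation between muscles is the dominant class signal, so classifiers
  reach higher scores than reported on real data; directional patterns
  (which algorithm wins, which representation rescues which) reproduce, but
  absolute scores on real cohorts are not claimed.
* EDF support is the minimal 16-bit subset needed for the archive layout
  (one channel per patient-muscle pair, one sweep per data record);
  vendor-specific IOM exports and EDF+ annotations are out of scope.
* Calibration SDs: amplitude SDs emerge close to the published values as a
  by-product of the saturated-lognormal family; latency SDs for muscles
  whose mean hugs the cutoff are mathematically incompatible with the
  published means (see §1) and are not targeted.
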