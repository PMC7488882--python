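# Methods

## The timing problem and the measurement model

Acute ischemia changes two MR-visible tissue properties on very different
schedules. Water diffusion collapses within minutes of onset and stays low
for days: the apparent diffusion coefficient (ADC) is therefore a *detector*
of ischemia with no time information. The transverse relaxation time T2 of
the lesion instead rises gradually, to good approximation linearly over the
first hours. The lesion-to-contralateral intensity ratio of a quantitative
T2 map is therefore a candidate clock for the 270-minute (4.5 h)
thrombolysis window, with weighted images (DWI, T2w, FLAIR) as cheaper but
confounded surrogates.

`strokeclock` implements that analysis end to end and, because clinical
cohorts of this kind are not publicly deposited, pairs it with a synthetic
cohort generator that reproduces the statistical structure the analysis
assumes.

## Phantom model

Geometry: a 3D grid (default 64×64×24 voxels at 2 mm isotropic; a
quarter-size preset is used in fast tests), axis 0 is left/right with the
mid-sagittal plane at index (nx−1)/2. The head is an axis-aligned ellipsoid
of nonischemic tissue containing two midline-symmetric ventricle-like CSF
blobs and one ellipsoidal lesion confined to a single hemisphere (bilateral
lesions are an exclusion criterion of the emulated analysis, and the
generator enforces it).

Per-compartment defaults (all overridable in `PhantomSpec`):

| compartment | ADC (µm²/ms) | T2 (ms) | PD (a.u.) | T1 (ms) |
|---|---|---|---|---|
| nonischemic tissue | 0.77 | 80 | 100 | 1200 |
| CSF | 3.0 | 2000 | 100 | 4000 |
| lesion | 0.50 | 80 × (1 + s·t) | 100 | 1400 |

The tissue and lesion ADC values are calibrated to the reported cohort
medians/means for nonischemic (0.77) and ischemic (≈0.5) tissue; CSF and T1
values are plausible 3T literature values. Lesion T2 grows linearly in
minutes from onset with slope s = 6.0e-4 /min by default. No human growth
rate is established; the slope is a calibration choice that keeps the T2
ratio in the empirically observed range (≈1.09–1.34 over onsets of
2.4–9.5 h) and it is the single most consequential generator parameter: all
timing information in a synthetic cohort flows through it.

Forward models (per voxel):

* multi-echo T2 train: S(TE) = PD·exp(−TE/T2), one volume per TE;
* diffusion: S_dir = S₀·exp(−b·g<sup>T</sup>D g·10⁻³) with b in s/mm² and
  diffusivities in µm²/ms; isotropic (D = ADC·I) unless an anisotropy option
  sets per-axis factors (mean-diffusivity preserving). Repeated b = 0
  acquisitions are averaged into S₀, as a scanner would;
* FLAIR: PD·|1 − 2e^(−TI/T1) + e^(−TR/T1)|·e^(−TE/T2); with TI = 2500 ms the
  CSF compartment (T1 = 4000 ms) is suppressed to < 10% of tissue signal.

Acquisition presets mirror three site-style 3T protocols: TE trains
{20,40,60,80,100}, {9.5,66,123}, {7.7,77,177} ms; diffusion b = 0 + 1000
s/mm² with 3 or 20 gradient directions; FLAIR TI 2500 ms where acquired.

Noise is Rician — the magnitude of a complex Gaussian channel pair — with
sigma expressed as a fraction of tissue proton density (default 3%,
a realistic parenchymal SNR at 3T); a Gaussian option exists for debugging.
Every cohort is reproducible from one integer seed: per-patient seeds are
spawned from it, and onset times come from a stratified sampler that fixes
the class split (16/35 within the window for the full-cohort preset, 5/17
for the FLAIR-subcohort preset) with uniform onsets over the observed
per-stratum ranges.

What the generator does **not** emulate: anatomy (three compartments only,
no partial-volume gradients), bias fields, distortion/ghosting, motion,
registration error, lesion heterogeneity, or any nonlinear/saturating T2
time course. Tests passing on these phantoms certify the pipeline's
arithmetic and statistical behavior, not clinical accuracy.

## Quantitative maps

* Three-direction ADC: ADC = −ln(S₁S₂S₃/S₀³)/(3b), equivalently the mean of
  the per-direction apparent diffusivities; stored in µm²/ms
  (= 10⁻³ mm²/s), so every exponent is b·ADC·10⁻³.
* ≥6 directions: log-linear least-squares tensor fit, MD = trace/3; on
  isotropic input MD equals the scalar ADC to rounding error. Rank of the
  direction design matrix is checked and collinear sets rejected.
* Effective DWI: S₀·exp(−1000·ADC·10⁻³), i.e. synthesized at b = 1000 s/mm²
  regardless of the acquired scheme. Combined with the three-direction ADC
  this reproduces the geometric mean of the weighted volumes exactly — an
  identity the tests verify to 1e-10.
* T2w: voxelwise sum over the TE series (no bias correction; synthetic data
  are bias-free, and a corrected volume can be supplied externally).
* T2: voxelwise mono-exponential fit. Default objective is log-linear
  weighted least squares with weights ∝ signal² (the first-order
  equivalent of unweighted least squares in signal space, robust and
  closed-form); an optional Gauss-Newton refinement minimizes the true
  signal-space residual. Both agree to <0.1% on noiseless data; the default
  is the log-linear fit because the refinement changes nothing at the SNRs
  simulated here. Voxels with any nonpositive echo, a non-decaying series,
  or T2 outside (0, 5000] ms are flagged in an explicit validity mask —
  never encoded as sentinel values.

Rician noise biases fitted T2 upward at low SNR (the noise floor flattens
the tail of the decay); the test suite pins the sign of that bias and its
monotone decrease with proton density.

## Lesion VOI and mirrored reference

A voxel is called ischemic iff

1. adc_low < ADC < adc_high (defaults 0.30 / 0.55 µm²/ms; the literature
   quotes ranges 0.2–0.4 and 0.55–0.6, and both bounds are exposed),
2. ADC < median − HWHM of nonischemic ADC (the adaptive rule), and
3. 30 < T2 < 200 ms (suppresses CSF).

The adaptive rule is circular — nonischemic statistics need a lesion
estimate — and is resolved with exactly one bootstrap pass: the initial
nonischemic set is the brain minus all voxels passing the absolute ADC
window, then the full rule is applied once. The HWHM is half the full width
at half maximum of a Silverman-bandwidth Gaussian-KDE of the nonischemic ADC
values (the estimator is not prescribed anywhere; a kernel-smoothed
histogram is the least arbitrary choice and its FWHM equals 2.355σ on
Gaussian data, which the tests check). For runtime the KDE subsamples to
10,000 values by deterministic striding and evaluates on a 1024-point grid;
on near-constant input it degenerates to half a histogram-bin width. The
nonischemic set spans all non-lesion brain (not only the contralateral
hemisphere); a config switch is not provided because on symmetric phantoms
the two are identical.

The candidate mask is refined to its largest 26-connected component plus any
component at least half its size (multifocal strokes); connectivity and the
fraction are configurable. The reference VOI is the voxelwise reflection of
the ischemic VOI about the mid-sagittal plane within each axial slice, with
the T2 limits re-applied as the automatic stand-in for manual CSF editing.
A VOI that touches or crosses the midline is an error (the bilateral
exclusion); so is a reference emptied by the T2 filter.

## Ratios and labels

The timing biomarker is mean(map | ischemic VOI) / mean(map | reference
VOI), computed on each map's native units — hence invariant to any global
intensity scaling, which is the point of using ratios across sites and
sequences. The within-window label is onset ≤ 270 min; the boundary itself
is ambiguous between "within 4.5 h" and a strict "< 270 min" convention, so
a `strict_boundary` flag selects the open interval (no simulated or real
patient sits exactly on the boundary in practice).

## Classifier evaluation

Direction is explicit everywhere: "within window" means ratio ≤ cutoff for
T2, T2w, DWI and FLAIR (they grow with time) and ratio ≥ cutoff for ADC.

* **AUC** is the Mann-Whitney probability (ties = ½), computed from
  midranks; the ROC polyline comes from scikit-learn. The 95% CI is
  Clopper-Pearson ("binomial exact") on the concordant-pair count out of
  n₊·n₋ pairs; the p-value against AUC = 0.5 is the two-sided Mann-Whitney
  test. Paired AUC differences use the DeLong covariance-aware z-test with
  Bonferroni adjustment over all pairs.
* **Youden cutoff**: exhaustive search over midpoints of adjacent sorted
  unique scores (plus one sentinel beyond each extreme) maximizing
  J = sens + spec − 1 computed in exact rational arithmetic. Ties are broken
  toward the cutoff classifying more patients as *beyond* the window —
  favoring specificity, i.e. treatment safety; the direction argument makes
  the alternative explicit if wanted.
* **Diagnostic metrics** are exact fractions on counts with normal
  approximation CIs p ± 1.96·√(p(1−p)/n) on each metric's own denominator;
  zero denominators flag the metric undefined rather than raising.
* **F1** = 2TP/(2TP+FP+FN). The default CI treats F1 as a proportion over
  the n scored items (SE = √(F1(1−F1)/n)), the convention that reproduces
  the published intervals for this analysis; a multinomial delta-method SE
  is available as an option.
* **Logistic regression** is a statsmodels maximum-likelihood fit reporting
  β, SE, t = β/SE, two-sided p, the likelihood-ratio χ² against the
  intercept-only null with df = number of predictors, and
  AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) with k parameters including the
  intercept (so n > k+1 is required). Perfect separation raises a typed
  ConvergenceError instead of returning divergent coefficients.
* **PRG/AUPRG**: precision and recall are mapped to gains
  g(v) = (v − π)/((1−π)v) so the always-positive baseline sits at 0 and a
  perfect classifier at 1. The AUPRG integrates precision-gain over
  recall-gain ∈ [0,1]; the crossing into nonnegative recall-gain is
  interpolated linearly in count space and the curve ends at the
  all-positive point (1, 0). Perfect rankings score exactly 1; random
  rankings score ≈ 0 in expectation (slightly negative, by Jensen) and can
  be negative — that is informative, not an error. This is the
  class-imbalance-robust view used for the FLAIR subcohort, where 5/17
  positives make ROC AUC overly optimistic.
* **Free-marginal kappa**: P₀ is the mean over items of pairwise rater
  agreement; κ = (P₀ − 1/k)/(1 − 1/k) with k = 3 rating categories
  (match / mismatch / no response — the only k consistent with the printed
  agreement/kappa pair this emulates). The CI is a normal approximation from
  the between-item variance of per-item agreement. Majority adjudication
  takes the majority of non-abstaining raters and sends exact ties
  (including 2-2 splits) to the arbitrator.

## Pipeline and reproducibility

`run_pipeline` executes simulate → maps → voi → ratios → evaluate against a
single run directory; every stage reads only files, so stages are
individually re-runnable and idempotent. Volumes are NIfTI-1 (.nii.gz,
series in the 4th dimension), tables CSV, results JSON; the manifest lists
every artifact with a SHA-256 checksum and identical configs yield
byte-identical manifests (verified in tests). Typed errors separate config
problems, data problems (e.g. the no-evident-lesion outcome), and model
non-convergence, and the CLI maps them to distinct exit codes.

## Test problem sizes

The default test grid is 64×64×24 at 2 mm (quarter-size 32×32×16 for
pipeline round-trips), cohorts of 35 (end-to-end), 6 (noiseless ratio
properties) and 3 (pipeline determinism); oracle cross-checks run
exhaustively at n ≤ 5 (AUC), over 500 random instances (Youden), and over
all rankings at n = 8 (AUPRG). These sizes keep the full suite around half
a minute while leaving every assertion at full precision.

## Known limitations

* The phantom's lesion is homogeneous; real lesions have ADC/T2 gradients,
  so the threshold segmentation is easier here than in patients.
* The linear T2 growth model is exact in the generator, so correlation- and
  AUC-type results on synthetic cohorts are upper bounds, not estimates of
  clinical performance; the published patient-level values (r ≈ 0.5,
  AUC ≈ 0.77) are *not* reproducible without the clinical data.
* The HWHM rule uses one bootstrap pass; a fixed-point iteration could
  differ on low-contrast data.
* FLAIR simulation ignores flow, magnetization transfer and multi-slice
  effects; it exists to exercise the FLAIR-ratio plumbing, not to model the
  contrast quantitatively.
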