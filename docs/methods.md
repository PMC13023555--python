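# Methods

## Signal models and noise

A T2-prepared acquisition yields one complex 3D volume per preparation time
(pTE). Per voxel, three nested decay models compete:

| model | signal | parameters | box constraints |
|---|---|---|---|
| ME | `A exp(-t/T2)` | T2 | T2 ∈ [0.1, 400] ms |
| SE | `A exp(-(t/T2)^alpha)` | T2, alpha | T2 ∈ [0.1, 400] ms, alpha ∈ [0.1, 1] |
| BE | `A [f e^{-t/T2s} + (1-f) e^{-t/T2l}]` | f, T2s, T2l | f ∈ [0.01, 0.99], T2s ∈ [0.1, 10] ms, T2l ∈ [20, 300] ms |

`A` is complex; at `t = 0` every model returns exactly `A` (we define
`0^alpha = 0` so the SE model is continuous there). SE with `alpha = 1`
reproduces ME exactly; BE at the `f` box edges approaches a single
exponential. The disjoint T2s/T2l boxes reflect the physical separation of
the macromolecule-bound fast pool (~0.1–10 ms) from bulk water (~20–300 ms)
and structurally prevent label switching during fitting.

Noise is i.i.d. zero-mean Gaussian with equal SD `sigma` on the real and
imaginary channels (channel correlation is assumed zero — a choice, since
coil covariance is acquisition-specific). Under this model the Fisher
information in the real parameterization `(Re A, Im A, θ)` is
`I = sigma^{-2} Σ_t Re(∂S^H ∂S)`, computed from analytic Jacobians. CRLBs
are the diagonal of `I^{-1}`; a condition number above 1e12 is reported as a
design failure rather than silently inverted.

### Schedule design

`optimize_schedule` minimizes the sum of CRLBs normalized by squared
nominal parameter values (relative variances; both amplitude components are
normalized by `|A|^2`, making the objective phase-invariant). Nominal tissue
parameters are explicit inputs; the documented defaults are
whole-cartilage healthy bi-exponential values (f = 0.22, T2s = 5.7 ms,
T2l = 54.1 ms). The search is exhaustive over multisets when the space is
small (≤ 50 000 candidates) and otherwise a deterministic greedy exchange
from a quantile-spread start; the strategy used is recorded in the result.
Repeat acquisitions are literal duplicate pTE entries — the likelihood sees
two independent noisy samples, which is how repeated long-pTE images raise
effective SNR.

## Voxel fitting

Complex-valued fitting is realized as joint least squares on stacked
real/imaginary residuals with the amplitude free as `(Re A, Im A)`
(unbounded) and model parameters box-constrained (`scipy.optimize.
least_squares`, trust-region reflective, analytic Jacobians, tolerances
1e-10, ≤ 500 iterations per start). Deterministic multi-start grids guard
against local minima:

- coarse (default): ME/SE start T2 at {5, 20, 50, 150} ms and alpha at
  {0.4, 0.7, 1.0}; BE starts f at {0.1, 0.3, 0.5}, T2s at {2, 6} ms, T2l at
  {40, 120} ms;
- quick (for large batch simulations where signals are well-conditioned):
  two physiologically central starts per model.

The amplitude always starts at the least-decayed sample. Degenerate signals
and universally failed starts yield flagged non-converged results (never
exceptions); non-converged voxels are excluded from ROI averaging.

## ROI features

The label convention is {1: PC, 2: TrC, 3: MFC, 4: MTC, 5: LFC, 6: LTC};
region means average converged, finite voxels only. The "Global" value is
the voxel-weighted mean over all cartilage voxels pooled — not the mean of
the six region means — because region sizes differ; the identity
`Global = Σ n_r m_r / Σ n_r` is enforced by test. Feature tables are
parameter-major with fixed region order, so the multi-ROI BE table has 18
columns `f_PC … t2_long_LTC`.

## Age adjustment

Cartilage T2 drifts with age, and case-control cohorts in this area are
often not age-matched, so each feature is residualized with per-feature OLS
on `[1, age_c, group, age_c × group]` (age centered at the training mean):
`Y_adj = Y − (β_age + β_int·g)(age − mean age)`. Group intercepts — the
disease signal — are preserved. Two deliberate choices:

- The model is always fitted on training-fold subjects only and applied to
  held-out subjects with the coefficients frozen (no leakage of test data
  into the transform).
- A held-out subject's group is unknown at prediction time, so held-out
  folds are adjusted with the expected-group slope
  `β_age + β_int · prevalence(train)` rather than the subject's own label.
  This keeps held-out scores strictly independent of held-out labels — a
  property the test suite checks procedurally — at the cost of a slightly
  attenuated interaction correction.

Sex and BMI are not modeled as covariates.

## Univariate battery

Group differences per feature use the two-sided Mann–Whitney U test
(exact enumeration for small untied samples, tie-corrected normal
approximation with continuity correction otherwise) with Cliff's delta
`δ = 2U/(n1 n2) − 1` as effect size, and Benjamini–Hochberg step-up FDR
adjustment. The permutation MANOVA on discriminant scores uses
`trace(W^{-1}B)` (sum of between/within eigenvalues, reducing to SSB/SSW
for one-dimensional scores) with `p = (1 + #{perm ≥ obs})/(1 + n_perm)`;
zero within-group scatter (perfect separation) maps to an infinite
statistic.

## Classification and evaluation

The regularized LDA weight vector is
`w = [(1−λ) S_pooled + λ (tr S / p) I]^{-1} (μ1 − μ0)` with λ ∈ [0, 1]
shrinking toward a scaled identity; posteriors come from the shared-
covariance Gaussian model with empirical prevalence as prior. λ = 0 with a
singular pooled covariance raises an error that points at λ > 0.

Nested cross-validation is stratified: default 5 outer × 5 inner folds, 20
repeats with reshuffled folds, λ grid {0, 0.01, 0.1, 0.3, 0.5, 0.7, 0.9, 1}
selected by inner-CV pooled AUC with ties breaking toward the larger (more
stable) λ. Age adjustment and standardization are refit inside every outer
training fold. The headline AUC is the pooled out-of-fold AUC averaged over
repeats; per-subject scores averaged over repeats feed the ROC, bootstrap
CI (subject-level percentile, default B = 2000, class-deficient resamples
redrawn), calibration (equal-width bins; Brier = mean squared error),
decision curves (`NB(pt) = TP/N − (FP/N)·pt/(1−pt)` on a 0.05–0.95 grid vs
treat-all/treat-none), and DeLong's paired test (placement-value variance).
The permutation test permutes labels *before* the entire nested-CV run, so
its null respects the full selection procedure; `p = (1 + #{≥ obs})/(1 +
n_perm)`, one-sided for AUC > 0.5. Weight stability summarizes fold-wise
weights by `|mean|/SD` per feature, optionally calibrated against the
per-permutation maximum from label-permuted reruns (family-wise control).
AUC itself is the midrank formula, exactly the normalized Mann–Whitney U;
the equivalence to brute-force pair counting is a standing test.

## Synthetic cohorts

The generator emulates a 26 + 26 case-control cohort: group ages are
truncated Gaussians (healthy 51.5 ± 8.4 y, OA 61.8 ± 7.6 y, range 40–75),
sex and BMI follow the same demographic pattern (10/26 vs 19/26 female,
BMI ≈ 27.3/27.8 with SD 4 — the SD a modeling choice). Ground truth is
bi-exponential per region: subject-level (f, T2s, T2l) are Gaussian around
group medians typical of healthy and early-OA cartilage with spreads
converted from interquartile ranges via SD ≈ IQR/1.349 (a normal-theory
approximation), clipped to the model boxes. Voxel signals add complex
Gaussian noise at SNR = |A|/sigma = 50 at t = 0 (sigma is a config knob, not
a measured quantity); the default per-region grid is 8×8×2 voxels, and the
calibration studies use 2×2×1 so a full cohort fits in seconds. ME/SE fits
to these data are intentionally misspecified, as in vivo. Optional per-year
age slopes can inject age confounding (default 0).

The exact-null variant draws *everything* — ages, demographics, all region
parameters — from the healthy distributions for both groups, so labels are
independent of all features by construction. It calibrates the pipeline:
over 200 replicates the mean nested-CV AUC sits at 0.5 (±0.03 band checked
by test) and the permutation test rejects at the nominal 5% rate. The
`shifted_config` helper builds the complementary power scenario: OA medians
equal healthy medians except the three BE parameters of chosen regions
(default the medial compartments MFC and MTC) shifted by a configurable
number of between-subject SDs (default 1.5), with shared spreads so the
effect size is exact.

What the generator does **not** emulate: cartilage geometry and partial
voluming, spatial noise correlation, B0/B1 and magic-angle orientation
effects, registration error, and segmentation variability. Passing the
end-to-end tests therefore demonstrates the statistical machinery is
unbiased and sensitive under the assumed generative structure — not that
any particular AUC is attainable on real patients.

## Study-design utilities

The sample-size calculator inverts the exact noncentral-t power function of
the two-sided two-sample t test (the normal approximation undershoots by
about one subject at these sizes), returning the smallest n per group
reaching the target power; a Monte-Carlo t-test simulation backs it in the
tests. For the reference inputs (mean 34 ms, SD 2.6 ms, 7% detectable
effect, α = 0.05, power 0.80) it returns 20 per group (achieved power
0.805). `total_scan_time` is the trivial protocol arithmetic (7 images at
3 min 12 s → 22 min 24 s).

## Numerical choices and limitations

- All randomness flows through `numpy.random.Generator` seeds; every
  stochastic routine is reproducible bit-for-bit given a seed.
- Problem sizes in the shipped studies (2×2×1 voxels per region for
  end-to-end replicates, 200 calibration replicates, reduced 5×3 CV with a
  3-point λ grid) are chosen so the whole suite runs on a laptop in
  minutes; all are plain parameters that scale up.
- BE parameter precision at protocol SNR is CRLB-limited: at SNR 50 on the
  7-point schedule the bound for T2s is ≈ 2.6 ms (tens of percent relative)
  — a property of the design, not the optimizer. The recovery tests
  document this: ME/SE parameters and the BE fraction recover tightly,
  BE T2 values do not.
- The inner-CV λ selection is greedy per fold; no one-standard-error rule.
- DeLong's test assumes asymptotic normality of the placement means; at
  n = 52 it is indicative, which is why the permutation test is primary.
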