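# t2oa

Multi-component T2 relaxometry of knee cartilage with a regularized-LDA
classification framework for detecting early osteoarthritis (OA).

Early OA alters cartilage composition (proteoglycan depletion, collagen
disorganization) before any structural damage is radiographically visible.
Quantitative T2 mapping probes these changes, but a single whole-cartilage
mono-exponential T2 often cannot separate early-OA knees from healthy ones:
the changes are subtle, spatially heterogeneous, and voxels contain more
than one water environment. This package implements the full analysis chain
for testing whether *multi-component* decay models evaluated over
*sub-regions* of cartilage carry more diagnostic signal:

1. **Signal models** (`t2oa.signal_models`) — three competing decay models
   for a T2-prepared acquisition at preparation times *t* (pTE, ms):
   - mono-exponential (ME): `S(t) = A exp(-t/T2)`
   - bi-exponential (BE): `S(t) = A [f exp(-t/T2s) + (1-f) exp(-t/T2l)]`,
     a fast macromolecule-bound pool (fraction `f`) plus slow bulk water
   - stretched-exponential (SE): `S(t) = A exp(-(t/T2)^alpha)`, with
     heterogeneity exponent `alpha in (0, 1]`
   plus complex Gaussian noise, closed-form Fisher information, per-parameter
   Cramér–Rao lower bounds (CRLB), and CRLB-driven pTE-schedule optimization.
2. **Voxel fitting** (`t2oa.voxel_fitting`) — bounded multi-start nonlinear
   least squares on complex signals, assembled into parameter maps.
3. **ROI features** (`t2oa.roi_features`) — per-subject means over six
   standard cartilage sub-regions (PC, TrC, MFC, MTC, LFC, LTC) and a
   voxel-weighted global region; feature vectors of size 1/2/3 (global) or
   6/12/18 (multi-ROI) for ME/SE/BE.
4. **Statistics** (`t2oa.adjust_stats`) — train-fold age adjustment
   (`Y ~ Age + Group + Age x Group`), Mann–Whitney U with Cliff's delta,
   Benjamini–Hochberg FDR, permutation MANOVA.
5. **Classification & evaluation** (`t2oa.classify_eval`) — shrinkage LDA
   `w = [(1-λ) S_pooled + λ (tr S / p) I]^{-1} (μ1 - μ0)` inside stratified
   nested cross-validation (inner folds pick λ by AUC), with bootstrap AUC
   CIs, label-permutation tests, DeLong comparisons, calibration/Brier,
   decision-curve net benefit, and fold-wise weight-stability analysis.
6. **Synthetic cohorts** (`t2oa.synthetic_data`) — fully parameterized
   two-group cohort generator (bi-exponential ground truth, complex voxel
   noise, realistic demographics) including an exact-null variant for
   calibration studies.

## Worked example

Size the study, simulate a cohort in which the bi-exponential parameters of
the two medial compartments (MFC, MTC) are shifted by 1.5 between-subject
SDs in the OA group, fit voxelwise, and classify:

```python
import numpy as np
from t2oa import sample_size_two_means
from t2oa.synthetic_data import CohortConfig, shifted_config, generate_cohort
from t2oa.roi_features import extract_roi_means, build_feature_table, feature_columns
from t2oa.voxel_fitting import fit_map, FitConfig
from t2oa.classify_eval import CVConfig, nested_cv, bootstrap_auc_ci, weight_stability

print("n per group:", sample_size_two_means(mean=34.0, sd=2.6, detectable_fraction=0.07))

cfg = shifted_config(CohortConfig(roi_grid=(2, 2, 1)))
cohort = generate_cohort(cfg, seed=7)
roi_means = {
    sid: extract_roi_means(
        fit_map(series, cohort.labels > 0, "be", FitConfig(starts="quick")),
        cohort.labels,
    )
    for sid, series in cohort.images.items()
}
table = build_feature_table(cohort.subjects, roi_means, "be", "multi")
cols = feature_columns("be", "multi")
X, y = table[cols].to_numpy(), table["group"].to_numpy(int)
cv = nested_cv(X, y, CVConfig(repeats=5), seed=7, ages=table["age"].to_numpy())
ci = bootstrap_auc_ci(cv.pooled_scores, y, seed=8)
stab = weight_stability(cv.fold_weights)
top = [cols[i] for i in np.argsort(stab.stat)[::-1][:3]]
print(f"mean AUC: {cv.mean_auc:.3f}  (bootstrap 95% CI {ci[0]:.3f}-{ci[1]:.3f})")
print("most stable weights:", top)
```

Output:

```
n per group: 20
mean AUC: 0.892  (bootstrap 95% CI 0.813-0.970)
most stable weights: ['t2_long_MFC', 't2_long_MTC', 'f_MTC']
```

The power calculation says 20 subjects per group suffice to detect a 7%
shift of a 34 ms mean T2 (SD 2.6 ms) at 80% power; the nested-CV AUC of
0.89 shows the pipeline detecting the simulated regional effect, and the
weight-stability ranking correctly singles out the shifted medial-compartment
features.

A command-line interface mirrors the library:

```bash
t2oa power --mean 34 --sd 2.6 --effect 0.07
t2oa simulate --seed 7 --n-per-group 26 --out data/
t2oa fit --model be --series data/series_hs000 --mask data/labels.nii.gz --out maps/hs000
t2oa analyze --features features.csv --model be --scope multi --out results/
t2oa design --model me --n-images 3 --grid-step 5
```

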