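"""Regularized LDA with nested cross-validation and resampling-based evaluation.

The classifier projects the ROI features onto a single discriminant score
with a shrinkage-regularized linear discriminant:

    w = [(1 - lam) S_pooled + lam (tr(S)/p) I]^-1 (mu_1 - mu_0)

where ``S_pooled`` is the pooled within-class covariance, ``p`` the feature
count and ``lam`` in [0, 1] the shrinkage intensity toward a scaled identity.
With ~18 features and ~40 training subjects per fold the unregularized
covariance is near-singular; shrinkage stabilizes it.

Performance is estimated with stratified nested cross-validation: inner
folds select ``lam`` by AUC, outer folds produce out-of-fold scores, and
age adjustment and feature standardization are fitted on each outer-fold
training portion only, so no test information leaks into the model.
Inference and uncertainty come from resampling: subject-level bootstrap CI
for the AUC, a label-permutation test run through the entire nested-CV
procedure, DeLong's test for paired AUC differences, calibration/Brier,
decision-curve net benefit, and fold-wise weight stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .adjust_stats import apply_age_adjustment, fit_age_adjustment

__all__ = [
    "RldaModel",
    "CVConfig",
    "CVResult",
    "fit_rlda",
    "nested_cv",
    "roc_auc",
    "roc_curve_points",
    "bootstrap_auc_ci",
    "permutation_test_auc",
    "delong_test",
    "calibration_brier",
    "decision_curve",
    "weight_stability",
]


# ---------------------------------------------------------------------------
# regularized LDA
# ---------------------------------------------------------------------------

@dataclass
class RldaModel:
    weights: np.ndarray
    intercept: float
    shrinkage: float
    means: np.ndarray  # (2, p): class 0 and class 1 means
    covariance: np.ndarray  # pooled, shrunk

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.weights + self.intercept

    def posteriors(self, X: np.ndarray) -> np.ndarray:
        """P(class 1 | x) from the shared-covariance Gaussian model."""
        return 1.0 / (1.0 + np.exp(-np.clip(self.decision_scores(X), -500, 500)))


def fit_rlda(X: np.ndarray, y: np.ndarray, shrinkage: float, priors=None) -> RldaModel:
    """Fit the shrinkage LDA. ``shrinkage`` = 0 is plain LDA (requires a
    nonsingular pooled covariance); 1 is the scaled-identity target, whose
    weight direction is parallel to the mean difference."""
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    classes = np.unique(y)
    if classes.size != 2 or np.any(np.bincount(y) < 2):
        raise ValueError("need two classes with >= 2 samples each")
    n, p = X.shape
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    C0 = X[y == 0] - mu0
    C1 = X[y == 1] - mu1
    S = (C0.T @ C0 + C1.T @ C1) / (n - 2)
    target = (np.trace(S) / p) * np.eye(p)
    Sh = (1.0 - shrinkage) * S + shrinkage * target
    try:
        L = np.linalg.cholesky(Sh)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "pooled covariance singular at shrinkage=%g (p=%d, n=%d); "
            "use shrinkage > 0" % (shrinkage, p, n)
        )
    d = mu1 - mu0
    w = np.linalg.solve(L.T, np.linalg.solve(L, d))
    if priors is None:
        pi1 = (y == 1).mean()
    else:
        pi1 = priors[1]
    b = -0.5 * w @ (mu0 + mu1) + np.log(pi1 / (1.0 - pi1))
    return RldaModel(w, float(b), shrinkage, np.stack([mu0, mu1]), Sh)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """AUC with ties counted 1/2 — identical to the normalized Mann-Whitney
    U statistic (rank formulation, exact for ties)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = sps.rankdata(s)
    u1 = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n1 * n0))


def roc_curve_points(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fpr, tpr, thresholds) sweeping the score from high to low."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return fpr, tpr, thr


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVConfig:
    """Nested-CV settings: stratified outer/inner folds, repeats with
    reshuffled folds, the shrinkage grid searched in the inner loop
    (ties break toward the larger, more stable value), and whether the
    age adjustment is refit inside each training fold."""

    outer_folds: int = 5
    inner_folds: int = 5
    repeats: int = 20
    lambda_grid: tuple[float, ...] = (0.0, 0.01, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
    adjust_age: bool = True


@dataclass
class CVResult:
    oof_scores: np.ndarray  # (repeats, n) out-of-fold discriminant scores
    oof_posteriors: np.ndarray  # (repeats, n)
    fold_weights: np.ndarray  # (repeats * outer_folds, p), standardized space
    chosen_lambdas: np.ndarray  # (repeats, outer_folds)
    auc_per_repeat: np.ndarray  # pooled out-of-fold AUC per repeat
    y: np.ndarray

    @property
    def mean_auc(self) -> float:
        """Headline AUC: pooled out-of-fold AUC averaged over repeats."""
        return float(self.auc_per_repeat.mean())

    @property
    def pooled_scores(self) -> np.ndarray:
        """Per-subject score averaged over repeats (each subject is scored
        exactly once out-of-fold within a repeat)."""
        return self.oof_scores.mean(axis=0)

    @property
    def pooled_posteriors(self) -> np.ndarray:
        return self.oof_posteriors.mean(axis=0)

    @property
    def pooled_auc(self) -> float:
        return roc_auc(self.pooled_scores, self.y)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    """Index lists of k stratified folds, shuffled by rng."""
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(
        n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    return list(skf.split(np.zeros_like(y), y))


def _select_lambda(X, y, grid, k, rng) -> float:
    """Inner loop: pooled out-of-fold AUC per lambda; ties -> larger lambda."""
    folds = _stratified_folds(y, k, rng)
    best_lam, best_auc = None, -np.inf
    for lam in grid:
        scores = np.empty(len(y))
        ok = True
        for tr, te in folds:
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            try:
                m = fit_rlda((X[tr] - mu) / sd, y[tr], lam)
            except np.linalg.LinAlgError:
                ok = False
                break
            scores[te] = m.decision_scores((X[te] - mu) / sd)
        if not ok:
            continue
        auc = roc_auc(scores, y)
        if auc >= best_auc:  # >=: later (larger) lambda wins ties
            best_auc, best_lam = auc, lam
    if best_lam is None:
        raise np.linalg.LinAlgError("no lambda on the grid gave a usable fit")
    return best_lam


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    config: CVConfig,
    seed: int,
    ages: np.ndarray | None = None,
    outer_splits: list | None = None,
) -> CVResult:
    """Stratified nested cross-validation of the regularized LDA.

    Within each outer training fold, in order: (1) the age adjustment is
    fitted and applied (train-fold coefficients applied to the held-out
    fold), (2) features are standardized by train-fold mean/SD, (3) the
    inner CV picks the shrinkage, (4) the final model is fitted and the
    held-out fold scored. Fold weights are recorded in standardized space.
    Deterministic for a fixed seed.
    """
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    n, p = X.shape
    if config.adjust_age and ages is None:
        raise ValueError("ages required when config.adjust_age is True")
    if n < 2 * config.outer_folds:
        raise ValueError("too few subjects for the outer fold count")
    rng = np.random.default_rng(seed)

    oof_scores = np.empty((config.repeats, n))
    oof_post = np.empty((config.repeats, n))
    weights = np.empty((config.repeats * config.outer_folds, p))
    lams = np.empty((config.repeats, config.outer_folds))
    aucs = np.empty(config.repeats)

    for r in range(config.repeats):
        # explicit outer splits (mainly for procedural tests) bypass the
        # per-repeat stratified reshuffle
        folds = (
            outer_splits
            if outer_splits is not None
            else _stratified_folds(y, config.outer_folds, rng)
        )
        for fi, (tr, te) in enumerate(folds):
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 1:
                raise ValueError("a fold lost a class; reduce fold count")
            Xtr, Xte = X[tr], X[te]
            if config.adjust_age:
                adj = fit_age_adjustment(Xtr, ages[tr], y[tr])
                Xtr = apply_age_adjustment(adj, Xtr, ages[tr], y[tr])
                # held-out labels are unknown at prediction time: adjust the
                # test fold with the expected-group (training prevalence)
                # slope so test scores never depend on test labels
                Xte = apply_age_adjustment(
                    adj, Xte, ages[te], np.full(len(te), y[tr].mean())
                )
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Ztr, Zte = (Xtr - mu) / sd, (Xte - mu) / sd
            lam = _select_lambda(Ztr, y[tr], config.lambda_grid, config.inner_folds, rng)
            model = fit_rlda(Ztr, y[tr], lam)
            oof_scores[r, te] = model.decision_scores(Zte)
            oof_post[r, te] = model.posteriors(Zte)
            weights[r * config.outer_folds + fi] = model.weights
            lams[r, fi] = lam
        aucs[r] = roc_auc(oof_scores[r], y)

    return CVResult(oof_scores, oof_post, weights, lams, aucs, y.copy())


# ---------------------------------------------------------------------------
# resampling-based inference
# ---------------------------------------------------------------------------

def bootstrap_auc_ci(
    scores, labels, n_boot: int = 2000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, resampling subjects with
    replacement; resamples missing a class are redrawn."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    n = len(y)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            if 0 < y[idx].sum() < n:
                break
        vals[b] = roc_auc(s[idx], y[idx])
    lo = (1 - level) / 2
    return tuple(np.quantile(vals, [lo, 1 - lo]))


def permutation_test_auc(
    X: np.ndarray,
    y: np.ndarray,
    config: CVConfig,
    n_perm: int,
    seed: int,
    ages: np.ndarray | None = None,
    observed_auc: float | None = None,
) -> tuple[float, float, np.ndarray]:
    """One-sided permutation test of H0: AUC = 0.5 vs H1: AUC > 0.5.

    Labels are permuted before the *entire* nested-CV run, so the null
    distribution reflects the full procedure including inner selection and
    age adjustment. Returns (observed AUC, p, null AUCs) with
    p = (1 + #{AUC_perm >= AUC_obs}) / (1 + n_perm).
    """
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    if observed_auc is None:
        observed_auc = nested_cv(X, y, config, seed, ages=ages).mean_auc
    null = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        null[i] = nested_cv(
            X, yp, config, int(rng.integers(2**31 - 1)), ages=ages
        ).mean_auc
    p = (1 + int((null >= observed_auc).sum())) / (1 + n_perm)
    return observed_auc, p, null


def _placements(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n for x in pos])
    v01 = np.array([(np.sum(pos > x) + 0.5 * np.sum(pos == x)) / m for x in neg])
    return v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong's paired test for the difference between two correlated AUCs.

    Uses structural-component (placement) variance estimates; returns
    (AUC_a - AUC_b, two-sided p). Antisymmetric in (a, b)."""
    y = np.asarray(labels).astype(int)
    va10, va01 = _placements(scores_a, y)
    vb10, vb01 = _placements(scores_b, y)
    auc_a, auc_b = va10.mean(), vb10.mean()
    m, n = len(va10), len(va01)
    s10 = np.cov(np.stack([va10, vb10]))
    s01 = np.cov(np.stack([va01, vb01]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        return float(diff), 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    return float(diff), float(2 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# calibration, decision curves, weight stability
# ---------------------------------------------------------------------------

def calibration_brier(posteriors, labels, n_bins: int = 10):
    """Equal-width reliability curve and the Brier score.

    Returns (bin mean predicted, bin observed fraction, bin counts, brier).
    Empty bins are dropped from the curve."""
    p = np.asarray(posteriors, float)
    y = np.asarray(labels).astype(int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("posteriors must lie in [0, 1]")
    edges = np.linspace(0, 1, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    pred, obs, counts = [], [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            pred.append(p[sel].mean())
            obs.append(y[sel].mean())
            counts.append(int(sel.sum()))
    brier = float(np.mean((p - y) ** 2))
    return np.array(pred), np.array(obs), np.array(counts), brier


def decision_curve(
    posteriors, labels, thresholds: np.ndarray | None = None
):
    """Net benefit of the model vs treat-all and treat-none.

    NB(pt) = TP/N - (FP/N) * pt/(1-pt); treat-none is 0 everywhere and
    treat-all is prevalence - (1-prevalence) * pt/(1-pt)."""
    p = np.asarray(posteriors, float)
    y = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.05, 0.951, 0.01)
    thresholds = np.asarray(thresholds, float)
    n = len(y)
    prev = y.mean()
    nb_model = np.empty_like(thresholds)
    for i, pt in enumerate(thresholds):
        treat = p >= pt
        tp = int((treat & (y == 1)).sum())
        fp = int((treat & (y == 0)).sum())
        nb_model[i] = tp / n - (fp / n) * pt / (1 - pt)
    nb_all = prev - (1 - prev) * thresholds / (1 - thresholds)
    nb_none = np.zeros_like(thresholds)
    return thresholds, nb_model, nb_all, nb_none


@dataclass
class WeightStability:
    mean: np.ndarray
    sd: np.ndarray
    stat: np.ndarray  # |mean| / SD per feature
    p_values: np.ndarray | None = None


def weight_stability(
    fold_weights: np.ndarray,
    null_fold_weights: list[np.ndarray] | None = None,
) -> WeightStability:
    """Importance and stability of the fold-wise LDA weights.

    A feature with a large absolute mean weight across folds is important;
    a small variance means a stable estimate. The stability statistic is
    |mean|/SD. When a list of null weight matrices (from label-permuted
    nested-CV runs) is supplied, a permutation p-value per feature is
    computed against the per-permutation maximum statistic (family-wise
    calibrated)."""
    W = np.asarray(fold_weights, float)
    mean = W.mean(axis=0)
    sd = W.std(axis=0, ddof=1)
    with np.errstate(divide="ignore"):
        stat = np.where(sd > 0, np.abs(mean) / np.where(sd > 0, sd, 1.0), np.inf)
    p = None
    if null_fold_weights is not None:
        null_max = np.array(
            [
                np.max(
                    np.abs(Wn.mean(axis=0))
                    / np.maximum(Wn.std(axis=0, ddof=1), 1e-300)
                )
                for Wn in null_fold_weights
            ]
        )
        p = np.array(
            [(1 + (null_max >= s).sum()) / (1 + len(null_max)) for s in stat]
        )
    return WeightStability(mean, sd, stat, p)
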