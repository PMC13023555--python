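"""Age adjustment and the univariate statistical battery.

Age is a strong confounder for cartilage T2 when groups are not age-matched.
Each feature is residualized against age with a per-feature ordinary least
squares model ``Y ~ Age + Group + Age x Group`` fitted on training subjects
only, then the group-specific age slope (about the training age mean) is
subtracted. Group intercept differences — the disease signal — are
deliberately preserved.

Group coding is 0 = healthy (HS), 1 = osteoarthritis (OA) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AgeAdjustment",
    "fit_age_adjustment",
    "apply_age_adjustment",
    "mann_whitney_cliffs",
    "bh_fdr",
    "univariate_battery",
    "np_manova",
]


@dataclass
class AgeAdjustment:
    """Per-feature OLS coefficients on the age-centered design
    [1, age-c, group, (age-c) x group], plus the training age mean."""

    coef: np.ndarray  # (n_features, 4): intercept, b_age, b_group, b_interaction
    age_mean: float


def fit_age_adjustment(
    features: np.ndarray, ages: np.ndarray, groups: np.ndarray
) -> AgeAdjustment:
    """Fit the adjustment model on (training) subjects.

    Requires both groups present and at least 4 subjects (the design has
    4 columns). Raises on a rank-deficient design (e.g. constant age).
    """
    X = np.asarray(features, float)
    if X.ndim == 1:
        X = X[:, None]
    ages = np.asarray(ages, float)
    groups = np.asarray(groups, float)
    if X.shape[0] < 4:
        raise ValueError("need >= 4 subjects to fit the age adjustment")
    if len(np.unique(groups)) < 2:
        raise ValueError("both groups must be present")
    ac = ages - ages.mean()
    D = np.column_stack([np.ones_like(ac), ac, groups, ac * groups])
    if np.linalg.matrix_rank(D) < 4:
        raise ValueError("rank-deficient adjustment design (collinear age/group)")
    coef, *_ = np.linalg.lstsq(D, X, rcond=None)
    return AgeAdjustment(coef=coef.T, age_mean=float(ages.mean()))


def apply_age_adjustment(
    model: AgeAdjustment, features: np.ndarray, ages: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """Remove the group-specific age trend learned on the training fold:
    ``Y_adj = Y - (b_age + b_int * group) * (age - training mean age)``."""
    X = np.asarray(features, float)
    one_d = X.ndim == 1
    if one_d:
        X = X[:, None]
    ages = np.asarray(ages, float)
    groups = np.asarray(groups, float)
    slope = model.coef[:, 1][None, :] + np.outer(groups, model.coef[:, 3])
    adj = X - slope * (ages - model.age_mean)[:, None]
    return adj[:, 0] if one_d else adj


@dataclass
class UnivariateRow:
    u_stat: float
    p_value: float
    cliffs_delta: float


def mann_whitney_cliffs(x, y) -> UnivariateRow:
    """Two-sided Mann-Whitney U test plus Cliff's delta.

    U counts x-over-y wins with ties as 1/2; delta = 2U/(n1 n2) - 1, the
    probability-of-superiority difference in [-1, 1]. Exact enumeration for
    small untied samples, otherwise the tie-corrected normal approximation
    with continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "asymptotic" if (max(x.size, y.size) > 20 or has_ties) else "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    delta = 2.0 * res.statistic / (x.size * y.size) - 1.0
    return UnivariateRow(float(res.statistic), float(res.pvalue), float(delta))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def univariate_battery(
    features: pd.DataFrame,
    group_col: str = "group",
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature Mann-Whitney U, Cliff's delta and BH-adjusted p across groups."""
    if feature_cols is None:
        from .roi_features import COVARIATE_COLUMNS

        feature_cols = [
            c for c in features.columns if c not in ("id",) + COVARIATE_COLUMNS
        ]
    g = features[group_col].to_numpy()
    rows = []
    for c in feature_cols:
        v = features[c].to_numpy(float)
        r = mann_whitney_cliffs(v[g == 1], v[g == 0])
        rows.append({"feature": c, "U": r.u_stat, "p": r.p_value, "delta": r.cliffs_delta})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_fdr(out["p"].to_numpy())
    return out


def _between_within_trace(scores: np.ndarray, labels: np.ndarray) -> float:
    """trace(W^-1 B): sum of eigenvalues of the between/within scatter
    pencil. For one-dimensional scores this is SSB/SSW."""
    X = scores if scores.ndim == 2 else scores[:, None]
    mu = X.mean(axis=0)
    B = np.zeros((X.shape[1],) * 2)
    W = np.zeros_like(B)
    for g in np.unique(labels):
        Xg = X[labels == g]
        d = (Xg.mean(axis=0) - mu)[:, None]
        B += Xg.shape[0] * (d @ d.T)
        C = Xg - Xg.mean(axis=0)
        W += C.T @ C
    try:
        return float(np.trace(np.linalg.solve(W, B)))
    except np.linalg.LinAlgError:
        return np.inf  # zero within-group scatter: perfect separation


def np_manova(
    scores: np.ndarray, labels: np.ndarray, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Nonparametric (permutation) MANOVA on discriminant scores.

    The statistic is the sum of eigenvalues of W^-1 B (between/within scatter);
    labels are permuted to build the null. Returns (statistic, p) with
    p = (1 + #{perm >= obs}) / (1 + n_perm). Invariant to affine rescaling of
    the scores.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for a meaningful permutation p")
    X = scores if scores.ndim == 2 else scores[:, None]
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("constant scores: statistic undefined")
    obs = _between_within_trace(scores, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _between_within_trace(scores, rng.permutation(labels)) >= obs:
            count += 1
    return obs, (1 + count) / (1 + n_perm)
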