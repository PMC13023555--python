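"""Sub-regional cartilage feature extraction.

Parameter maps are reduced to per-subject features over six standard knee
cartilage sub-regions — patellar (PC), trochlear (TrC), medial/lateral
femoral (MFC/LFC) and medial/lateral tibial (MTC/LTC) — plus a voxel-weighted
"Global" region covering all cartilage. Feature tables are parameter-major
with a fixed ROI order, giving 1/2/3 global and 6/12/18 multi-ROI features
for the mono-, stretched- and bi-exponential models respectively.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .signal_models import MODEL_PARAM_NAMES
from .voxel_fitting import ParameterMap

__all__ = [
    "ROI_LEGEND",
    "ROI_ORDER",
    "feature_columns",
    "extract_roi_means",
    "build_feature_table",
    "group_summaries",
]

log = logging.getLogger(__name__)

#: integer encoding of the six cartilage sub-regions (0 = background)
ROI_LEGEND = {1: "PC", 2: "TrC", 3: "MFC", 4: "MTC", 5: "LFC", 6: "LTC"}
ROI_ORDER = ("PC", "TrC", "MFC", "MTC", "LFC", "LTC")
_NAME_TO_LABEL = {v: k for k, v in ROI_LEGEND.items()}

COVARIATE_COLUMNS = ("group", "age", "sex", "bmi")


def feature_columns(model_id: str, scope: str) -> list[str]:
    """Canonical feature column names: parameter-major, ROI order PC..LTC."""
    params = MODEL_PARAM_NAMES[model_id]
    if scope == "global":
        return [f"{p}_Global" for p in params]
    if scope == "multi":
        return [f"{p}_{roi}" for p in params for roi in ROI_ORDER]
    raise ValueError(f"scope must be 'global' or 'multi', got {scope!r}")


def extract_roi_means(maps: ParameterMap, labels: np.ndarray) -> dict[str, float]:
    """Mean of valid voxels per ROI and over the whole cartilage.

    Only converged, finite voxels contribute. "Global" is the voxel-weighted
    mean over the union of labels 1-6 (i.e. all cartilage voxels pooled),
    not the mean of the six ROI means. Empty ROIs yield NaN with a warning.
    """
    labels = np.asarray(labels)
    names = maps.param_names
    first = maps.params[names[0]]
    if labels.shape != first.shape:
        raise ValueError(f"label grid {labels.shape} != map grid {first.shape}")
    bad = set(np.unique(labels)) - set(range(7))
    if bad:
        raise ValueError(f"unexpected label values {sorted(bad)}; legend is 0..6")

    out: dict[str, float] = {}
    for param in names:
        vol = maps.params[param]
        valid = maps.converged & np.isfinite(vol)
        for label, roi in ROI_LEGEND.items():
            sel = (labels == label) & valid
            if not (labels == label).any():
                warnings.warn(f"label {label} ({roi}) empty; mean set to NaN")
                out[f"{param}_{roi}"] = np.nan
            elif not sel.any():
                warnings.warn(f"no valid voxels in {roi}; mean set to NaN")
                out[f"{param}_{roi}"] = np.nan
            else:
                out[f"{param}_{roi}"] = float(vol[sel].mean())
        sel = (labels > 0) & valid
        out[f"{param}_Global"] = float(vol[sel].mean()) if sel.any() else np.nan
    return out


def build_feature_table(
    subjects: pd.DataFrame,
    roi_means: dict[str, dict[str, float]],
    model_id: str,
    scope: str,
) -> pd.DataFrame:
    """Assemble the subjects x features table used by the classifier.

    Parameters
    ----------
    subjects : covariate table with columns id, group, age, sex, bmi.
    roi_means : mapping subject id -> output of :func:`extract_roi_means`.
    model_id, scope : decay model and 'global' or 'multi'.

    Subjects with any missing core feature are dropped (logged); the result
    keeps the covariates alongside the features.
    """
    cols = feature_columns(model_id, scope)
    rows, kept = [], []
    for _, subj in subjects.iterrows():
        sid = subj["id"]
        means = roi_means.get(sid)
        if means is None:
            log.warning("subject %s has no ROI means; dropped", sid)
            continue
        vals = [means.get(c, np.nan) for c in cols]
        if any(not np.isfinite(v) for v in vals):
            log.warning("subject %s missing core features; dropped", sid)
            continue
        rows.append(vals)
        kept.append(subj)
    if not rows:
        raise ValueError("no subject has a complete feature vector")
    cov = pd.DataFrame(kept).reset_index(drop=True)
    keep_cov = [c for c in ("id",) + COVARIATE_COLUMNS if c in cov.columns]
    return pd.concat([cov[keep_cov], pd.DataFrame(rows, columns=cols)], axis=1)


def group_summaries(features: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Median and interquartile range per feature per group, for reporting."""
    feat_cols = [
        c for c in features.columns if c not in ("id",) + COVARIATE_COLUMNS
    ]
    recs = []
    for g, sub in features.groupby(group_col):
        for c in feat_cols:
            v = sub[c].to_numpy(float)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            recs.append(
                {"group": g, "feature": c, "median": med, "q1": q1, "q3": q3}
            )
    return pd.DataFrame(recs)
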