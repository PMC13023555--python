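"""Synthetic two-group knee-cartilage cohorts for end-to-end pipeline testing.

No patient data ship with this package; instead the generator emulates the
statistical structure the analysis assumes. Ground truth is bi-exponential
(the richest of the three decay models): each subject carries per-ROI true
(f, T2_short, T2_long) drawn around group-level medians typical of healthy
and early-OA cartilage, voxel signals are the bi-exponential forward model
plus complex Gaussian noise on a small grid, and demographics mimic a
26 + 26 case-control cohort (healthy mean age 51.5 +/- 8.4 y, OA
61.8 +/- 7.6 y, truncated to 40-75 y). Mono- and stretched-exponential fits
to these data are intentionally misspecified, as they are in vivo.

Group-level spreads are Gaussian with SD approximated as IQR/1.349 from the
reported interquartile ranges. An exact-null variant draws both groups from
the healthy distributions with labels assigned independently, for
calibration of the permutation/CV machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .roi_features import ROI_ORDER, feature_columns
from .signal_models import BEParams, EchoSchedule, MODEL_BOUNDS, NoiseModel, add_complex_noise, be_signal
from .voxel_fitting import ImageSeries

__all__ = [
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "generate_null_cohort",
    "shifted_config",
    "feature_table_from_truth",
]

log = logging.getLogger(__name__)

_IQR_TO_SD = 1.349  # normal-distribution IQR -> SD conversion

# per-ROI bi-exponential medians and IQR widths typical of healthy (hs) and
# early-OA (oa) cartilage; ROI order PC, TrC, MFC, MTC, LFC, LTC
_BE_MEDIANS = {
    "hs": {
        "f": (0.14, 0.17, 0.24, 0.27, 0.24, 0.26),
        "t2_short": (6.0, 5.9, 5.7, 5.6, 5.4, 5.7),
        "t2_long": (58.1, 58.5, 55.3, 49.4, 65.4, 47.3),
    },
    "oa": {
        "f": (0.16, 0.19, 0.26, 0.25, 0.26, 0.20),
        "t2_short": (5.8, 5.6, 5.2, 5.4, 5.2, 5.4),
        "t2_long": (55.0, 56.0, 57.0, 55.2, 47.2, 39.8),
    },
}
_BE_IQRS = {
    "hs": {
        "f": (0.11, 0.06, 0.12, 0.08, 0.19, 0.09),
        "t2_short": (0.8, 0.9, 0.9, 1.0, 1.3, 1.1),
        "t2_long": (31.1, 37.3, 41.6, 11.2, 40.2, 12.3),
    },
    "oa": {
        "f": (0.08, 0.07, 0.11, 0.12, 0.12, 0.14),
        "t2_short": (0.6, 0.8, 1.1, 0.8, 0.7, 0.8),
        "t2_long": (20.0, 26.5, 31.9, 26.8, 22.9, 16.4),
    },
}

BE_PARAM_NAMES = ("f", "t2_short", "t2_long")


def _default_medians():
    return {g: {p: tuple(v) for p, v in d.items()} for g, d in _BE_MEDIANS.items()}


def _default_sds():
    return {
        g: {p: tuple(x / _IQR_TO_SD for x in v) for p, v in d.items()}
        for g, d in _BE_IQRS.items()
    }


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generative settings.

    ``roi_medians``/``roi_sds`` map group -> parameter -> 6-tuple (ROI order
    PC, TrC, MFC, MTC, LFC, LTC). ``sigma`` is the per-channel voxel noise
    SD; the default gives SNR = |A|/sigma = 50 at t = 0. ``age_slope`` adds
    an optional per-year linear trend to each parameter (same in both
    groups), to emulate age confounding.
    """

    n_hs: int = 26
    n_oa: int = 26
    age_mean_hs: float = 51.5
    age_sd_hs: float = 8.4
    age_mean_oa: float = 61.8
    age_sd_oa: float = 7.6
    age_range: tuple[float, float] = (40.0, 75.0)
    female_frac_hs: float = 10 / 26
    female_frac_oa: float = 19 / 26
    bmi_mean_hs: float = 27.3
    bmi_mean_oa: float = 27.8
    bmi_sd: float = 4.0
    roi_medians: dict = field(default_factory=_default_medians)
    roi_sds: dict = field(default_factory=_default_sds)
    age_slope: dict = field(default_factory=dict)  # param -> per-year slope
    amplitude: float = 100.0
    sigma: float = 2.0
    roi_grid: tuple[int, int, int] = (8, 8, 2)
    schedule: EchoSchedule = field(default_factory=EchoSchedule.default_seven)


@dataclass
class Cohort:
    """A generated cohort: covariates, optional images, labels, and the
    latent truth used for recovery tests."""

    subjects: pd.DataFrame  # id, group, age, sex, bmi
    labels: np.ndarray | None  # shared integer label volume
    images: dict[str, ImageSeries] | None  # subject id -> series
    truth: dict[str, dict[str, dict[str, float]]]  # id -> roi -> param -> value
    config: CohortConfig


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    """Rejection-free truncated normal via inverse CDF."""
    from scipy import stats

    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_subject_params(rng, config, group_key, age, age_ref):
    """Per-ROI true BE parameters for one subject, clipped to model boxes."""
    out = {}
    for ri, roi in enumerate(ROI_ORDER):
        rec = {}
        for p in BE_PARAM_NAMES:
            loc = config.roi_medians[group_key][p][ri]
            loc += config.age_slope.get(p, 0.0) * (age - age_ref)
            sd = config.roi_sds[group_key][p][ri]
            v = rng.normal(loc, sd)
            lo, hi = MODEL_BOUNDS["be"][p]
            clipped = float(np.clip(v, lo, hi))
            if clipped != v:
                log.debug("clipped %s/%s from %g to %g", roi, p, v, clipped)
            rec[p] = clipped
        # keep the two pools separated even after clipping
        if rec["t2_short"] >= rec["t2_long"]:
            rec["t2_long"] = rec["t2_short"] + 10.0
        out[roi] = rec
    return out


def _build_label_volume(roi_grid):
    gx, gy, gz = roi_grid
    vol = np.zeros((6 * gx, gy, gz), dtype=np.int16)
    for r in range(6):
        vol[r * gx : (r + 1) * gx] = r + 1
    return vol


def _render_images(rng, config, params_by_roi) -> ImageSeries:
    gx, gy, gz = config.roi_grid
    n_echo = len(config.schedule)
    vox = np.zeros((6 * gx, gy, gz, n_echo), dtype=complex)
    noise = NoiseModel(config.sigma)
    for ri, roi in enumerate(ROI_ORDER):
        p = params_by_roi[roi]
        clean = be_signal(
            BEParams(amplitude=config.amplitude, **p), config.schedule
        )
        block = np.broadcast_to(clean, (gx, gy, gz, n_echo))
        vox[ri * gx : (ri + 1) * gx] = add_complex_noise(block, noise, rng)
    return ImageSeries(vox, config.schedule)


def generate_cohort(
    config: CohortConfig, seed: int, with_images: bool = True
) -> Cohort:
    """Generate a full two-group cohort.

    Ages are group-specific truncated Gaussians; per-ROI true bi-exponential
    parameters are drawn around the group medians; voxel signals (if
    requested) are the forward model plus complex noise on a small per-ROI
    grid. All latent parameters are returned in ``truth``. Byte-identical
    under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    age_ref = (config.age_mean_hs + config.age_mean_oa) / 2.0
    rows, truth, images = [], {}, {} if with_images else None
    specs = [("hs", 0, config.n_hs), ("oa", 1, config.n_oa)]
    for group_key, group, n in specs:
        mean_age = config.age_mean_hs if group == 0 else config.age_mean_oa
        sd_age = config.age_sd_hs if group == 0 else config.age_sd_oa
        ffrac = config.female_frac_hs if group == 0 else config.female_frac_oa
        bmi_mean = config.bmi_mean_hs if group == 0 else config.bmi_mean_oa
        for i in range(n):
            sid = f"{group_key}{i:03d}"
            age = float(_truncnorm(rng, mean_age, sd_age, *config.age_range))
            sex = "F" if rng.random() < ffrac else "M"
            bmi = float(rng.normal(bmi_mean, config.bmi_sd))
            rows.append(
                {"id": sid, "group": group, "age": age, "sex": sex, "bmi": bmi}
            )
            truth[sid] = _draw_subject_params(rng, config, group_key, age, age_ref)
            if with_images:
                images[sid] = _render_images(rng, config, truth[sid])
    subjects = pd.DataFrame(rows)
    labels = _build_label_volume(config.roi_grid) if with_images else None
    return Cohort(subjects, labels, images, truth, config)


def generate_null_cohort(
    config: CohortConfig, seed: int, with_images: bool = True
) -> Cohort:
    """Exact-null cohort: every subject (regardless of label) is drawn from
    the healthy-group distributions — ages, demographics and all ROI
    parameters — so group labels carry no information. Per-group sample
    counts follow the config."""
    null_cfg = replace(
        config,
        age_mean_oa=config.age_mean_hs,
        age_sd_oa=config.age_sd_hs,
        female_frac_oa=config.female_frac_hs,
        bmi_mean_oa=config.bmi_mean_hs,
        roi_medians={
            "hs": config.roi_medians["hs"],
            "oa": config.roi_medians["hs"],
        },
        roi_sds={"hs": config.roi_sds["hs"], "oa": config.roi_sds["hs"]},
    )
    return generate_cohort(null_cfg, seed, with_images=with_images)


def shifted_config(
    base: CohortConfig | None = None,
    rois: tuple[str, ...] = ("MFC", "MTC"),
    params: tuple[str, ...] = BE_PARAM_NAMES,
    shift_sds: float = 1.5,
) -> CohortConfig:
    """A config with a controlled disease effect: OA medians equal the
    healthy medians except in the named ROIs/parameters, which are shifted
    by ``shift_sds`` between-subject SDs. Both groups share the healthy
    spreads, so the configured effect size is exact."""
    base = base or CohortConfig()
    hs_med = base.roi_medians["hs"]
    hs_sd = base.roi_sds["hs"]
    oa_med = {p: list(v) for p, v in hs_med.items()}
    for roi in rois:
        ri = ROI_ORDER.index(roi)
        for p in params:
            oa_med[p][ri] = hs_med[p][ri] + shift_sds * hs_sd[p][ri]
    return replace(
        base,
        roi_medians={"hs": hs_med, "oa": {p: tuple(v) for p, v in oa_med.items()}},
        roi_sds={"hs": hs_sd, "oa": hs_sd},
    )


def feature_table_from_truth(cohort: Cohort) -> pd.DataFrame:
    """Ready-made multi-ROI bi-exponential feature table straight from the
    latent truth (no imaging or fitting) — the fast path for large
    calibration simulations."""
    cols = feature_columns("be", "multi")
    rows = []
    for _, subj in cohort.subjects.iterrows():
        rec = cohort.truth[subj["id"]]
        rows.append([rec[roi][p] for p in BE_PARAM_NAMES for roi in ROI_ORDER])
    feats = pd.DataFrame(rows, columns=cols)
    return pd.concat([cohort.subjects.reset_index(drop=True), feats], axis=1)
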