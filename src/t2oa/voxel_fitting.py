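"""Bounded nonlinear least-squares fitting of decay models to complex voxel signals.

Fitting is complex-valued: the objective stacks real and imaginary residuals
and the amplitude is free as (Re A, Im A). Model parameters are constrained
to fixed physiological boxes (T2 in [0.1, 400] ms, alpha in [0.1, 1],
f in [0.01, 0.99], short T2 in [0.1, 10] ms, long T2 in [20, 300] ms).
The disjoint short/long boxes rule out label switching structurally.

A deterministic multi-start grid guards against local minima; repeated pTEs
enter the objective as independent residual terms (no pre-averaging).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.optimize import least_squares

from .signal_models import (
    MODEL_BOUNDS,
    MODEL_PARAM_NAMES,
    BEParams,
    EchoSchedule,
    MEParams,
    SEParams,
    decay_envelope,
    signal_jacobian,
)

__all__ = ["FitConfig", "FitResult", "ImageSeries", "ParameterMap", "fit_voxel", "fit_map"]

_PARAM_CLASSES = {"me": MEParams, "be": BEParams, "se": SEParams}

# deterministic coarse multi-start grids over the parameter boxes
_COARSE_STARTS = {
    "me": [(t2,) for t2 in (5.0, 20.0, 50.0, 150.0)],
    "se": [
        (t2, a)
        for t2 in (5.0, 20.0, 50.0, 150.0)
        for a in (0.4, 0.7, 1.0)
    ],
    "be": [
        (f, s, l)
        for f in (0.1, 0.3, 0.5)
        for s in (2.0, 6.0)
        for l in (40.0, 120.0)
    ],
}

# reduced grids for large batch jobs where signals are well conditioned
_QUICK_STARTS = {
    "me": [(40.0,)],
    "se": [(30.0, 0.6), (60.0, 1.0)],
    "be": [(0.2, 5.0, 50.0), (0.4, 6.0, 90.0)],
}


@dataclass(frozen=True)
class FitConfig:
    """Solver settings: tolerance 1e-10, <=500 iterations per start, and the
    multi-start policy ('coarse' spans the boxes; 'quick' uses two
    physiologically central starts for batch work)."""

    starts: str = "coarse"
    tol: float = 1e-10
    max_nfev: int = 500

    def start_grid(self, model_id: str) -> list[tuple[float, ...]]:
        table = _COARSE_STARTS if self.starts == "coarse" else _QUICK_STARTS
        return table[model_id]


@dataclass
class FitResult:
    model_id: str
    params: MEParams | BEParams | SEParams | None
    residual_norm: float
    converged: bool
    n_starts_used: int

    @property
    def theta(self) -> np.ndarray | None:
        return None if self.params is None else self.params.theta


@dataclass
class ImageSeries:
    """A 4D complex acquisition: one 3D volume per preparation time."""

    voxels: np.ndarray  # (x, y, z, echo) complex
    schedule: EchoSchedule
    voxel_size: tuple[float, float, float] = (0.8, 0.8, 2.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=complex)
        if self.voxels.ndim != 4:
            raise ValueError(f"expected 4D (x,y,z,echo), got shape {self.voxels.shape}")
        if self.voxels.shape[3] != len(self.schedule):
            raise ValueError(
                f"echo dimension {self.voxels.shape[3]} != schedule length "
                f"{len(self.schedule)}"
            )


@dataclass
class ParameterMap:
    """Per-parameter 3D volumes from voxelwise fitting (NaN outside the mask)."""

    model_id: str
    params: dict[str, np.ndarray]
    residual: np.ndarray
    converged: np.ndarray  # bool volume, False outside mask
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def param_names(self) -> tuple[str, ...]:
        return MODEL_PARAM_NAMES[self.model_id]


def _residual_and_jac(model_id, t, y):
    """Factory for the stacked real/imag residual and its Jacobian in the
    free vector x = (Re A, Im A, theta)."""

    def resid(x):
        a = x[0] + 1j * x[1]
        s = a * decay_envelope(model_id, x[2:], t)
        d = s - y
        return np.concatenate([d.real, d.imag])

    def jac(x):
        a = x[0] + 1j * x[1]
        J = signal_jacobian(model_id, a, x[2:], t)
        return np.concatenate([J.real, J.imag], axis=0)

    return resid, jac


def fit_voxel(
    signal: np.ndarray,
    schedule: EchoSchedule,
    model_id: str,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit one model to one voxel's complex signal by bounded least squares.

    Multi-start: the solver is run from each initialization on a deterministic
    grid (amplitude always started at the earliest-pTE sample) and the start
    with the smallest residual wins. Degenerate (all-zero/non-finite) signals
    and universally failed starts return a flagged, non-converged result.
    """
    config = config or FitConfig()
    t = schedule.times
    y = np.asarray(signal, dtype=complex)
    if y.shape != t.shape:
        raise ValueError(f"signal length {y.size} != schedule length {t.size}")
    names = MODEL_PARAM_NAMES[model_id]
    n_free = 2 + len(names)
    if t.size < n_free:
        raise ValueError(f"{t.size} echoes < {n_free} free parameters")
    if not np.all(np.isfinite(y.view(float))) or np.all(y == 0):
        return FitResult(model_id, None, np.inf, False, 0)

    lo = np.array([-np.inf, -np.inf] + [MODEL_BOUNDS[model_id][n][0] for n in names])
    hi = np.array([np.inf, np.inf] + [MODEL_BOUNDS[model_id][n][1] for n in names])
    a0 = y[np.argmin(t)]  # amplitude guess: least-decayed sample

    resid, jac = _residual_and_jac(model_id, t, y)
    best_x, best_cost, n_used = None, np.inf, 0
    for theta0 in config.start_grid(model_id):
        x0 = np.clip(np.array([a0.real, a0.imag, *theta0]), lo, hi)
        try:
            sol = least_squares(
                resid,
                x0,
                jac=jac,
                bounds=(lo, hi),
                xtol=config.tol,
                ftol=config.tol,
                gtol=config.tol,
                max_nfev=config.max_nfev,
            )
        except Exception:
            continue
        n_used += 1
        if sol.cost < best_cost:
            best_cost, best_x = sol.cost, sol.x

    if best_x is None:
        return FitResult(model_id, None, np.inf, False, n_used)

    a = complex(best_x[0], best_x[1])
    if a == 0:  # amplitude collapsed: parameter record would be invalid
        return FitResult(model_id, None, float(np.sqrt(2 * best_cost)), False, n_used)
    kwargs = dict(zip(names, best_x[2:]))
    if model_id == "be" and not kwargs["t2_short"] < kwargs["t2_long"]:
        return FitResult(model_id, None, float(np.sqrt(2 * best_cost)), False, n_used)
    params = _PARAM_CLASSES[model_id](amplitude=a, **kwargs)
    return FitResult(model_id, params, float(np.sqrt(2 * best_cost)), True, n_used)


def fit_map(
    series: ImageSeries,
    mask: np.ndarray,
    model_id: str,
    config: FitConfig | None = None,
) -> ParameterMap:
    """Apply :func:`fit_voxel` to every voxel inside a boolean mask.

    Voxel order has no effect on results. Non-converged voxels keep NaN
    parameters and ``converged=False`` so that downstream ROI averaging can
    exclude them.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.voxels.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} != series grid {series.voxels.shape[:3]}"
        )
    if not mask.any():
        raise ValueError("empty mask")

    names = MODEL_PARAM_NAMES[model_id]
    shape = mask.shape
    vols = {n: np.full(shape, np.nan) for n in names}
    residual = np.full(shape, np.nan)
    converged = np.zeros(shape, dtype=bool)

    for idx in np.argwhere(mask):
        i, j, k = idx
        res = fit_voxel(series.voxels[i, j, k, :], series.schedule, model_id, config)
        residual[i, j, k] = res.residual_norm
        converged[i, j, k] = res.converged
        if res.converged:
            for n, v in zip(names, res.theta):
                vols[n][i, j, k] = v
    return ParameterMap(model_id, vols, residual, converged, series.affine.copy())
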