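"""Forward T2 relaxation models, complex noise, Fisher information and schedule design.

The three competing voxel decay models for T2-prepared cartilage imaging:

* mono-exponential (ME): ``S(t) = A exp(-t/T2)``
* bi-exponential (BE):   ``S(t) = A [f exp(-t/T2s) + (1-f) exp(-t/T2l)]``
* stretched-exponential (SE): ``S(t) = A exp(-(t/T2)^alpha)``

``A`` is the complex signal amplitude, ``t`` the preparation time (pTE, ms).
Measurement noise is i.i.d. zero-mean Gaussian on the real and imaginary
channels. Under that noise model the Fisher information is available in
closed form, which drives the Cramer-Rao lower-bound (CRLB) evaluation and
the preparation-time schedule optimization.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EchoSchedule",
    "MEParams",
    "BEParams",
    "SEParams",
    "NoiseModel",
    "DesignError",
    "MODEL_PARAM_NAMES",
    "MODEL_BOUNDS",
    "me_signal",
    "be_signal",
    "se_signal",
    "decay_envelope",
    "signal_jacobian",
    "add_complex_noise",
    "fisher_information",
    "crlb",
    "optimize_schedule",
]

# design-search grid limits (ms)
GRID_MIN = 0.1
GRID_MAX = 55.0
GRID_STEP = 0.1

#: model parameter names in canonical order (excluding the complex amplitude)
MODEL_PARAM_NAMES = {
    "me": ("t2",),
    "se": ("t2", "alpha"),
    "be": ("f", "t2_short", "t2_long"),
}

#: box constraints used both for validation and for bounded fitting
MODEL_BOUNDS = {
    "me": {"t2": (0.1, 400.0)},
    "se": {"t2": (0.1, 400.0), "alpha": (0.1, 1.0)},
    "be": {"f": (0.01, 0.99), "t2_short": (0.1, 10.0), "t2_long": (20.0, 300.0)},
}


class DesignError(ValueError):
    """A pTE schedule cannot identify the model (singular Fisher information)."""


@dataclass(frozen=True)
class EchoSchedule:
    """A preparation-time (pTE) schedule in ms. Duplicates encode repeat acquisitions."""

    ptes: tuple[float, ...]
    grid_step: float = GRID_STEP

    def __post_init__(self) -> None:
        ptes = tuple(float(t) for t in self.ptes)
        if len(ptes) == 0:
            raise ValueError("schedule must contain at least one pTE")
        if any(not math.isfinite(t) or t < 0 for t in ptes):
            raise ValueError(f"pTEs must be finite and >= 0, got {ptes}")
        object.__setattr__(self, "ptes", ptes)

    def __len__(self) -> int:
        return len(self.ptes)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.ptes, dtype=float)

    @classmethod
    def default_seven(cls) -> "EchoSchedule":
        """The 7-image CRLB-optimized protocol schedule (ms), with repeated
        33 and 55 ms preparations that raise the effective SNR at long pTE."""
        return cls(ptes=(0.0, 4.3, 9.0, 33.0, 33.0, 55.0, 55.0))


def _check_finite(name: str, value: complex | float) -> None:
    if not np.all(np.isfinite([np.real(value), np.imag(value)])):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class MEParams:
    """Mono-exponential parameters: complex amplitude and a single T2 (ms)."""

    amplitude: complex
    t2: float

    model_id = "me"

    def __post_init__(self) -> None:
        _check_finite("amplitude", self.amplitude)
        _check_finite("t2", self.t2)
        if abs(self.amplitude) <= 0:
            raise ValueError("amplitude must be nonzero")
        lo, hi = MODEL_BOUNDS["me"]["t2"]
        if not lo <= self.t2 <= hi:
            raise ValueError(f"t2={self.t2} outside [{lo}, {hi}] ms")

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.t2])


@dataclass(frozen=True)
class BEParams:
    """Bi-exponential parameters: two water pools with short/long T2 and a
    short-pool signal fraction f."""

    amplitude: complex
    f: float
    t2_short: float
    t2_long: float

    model_id = "be"

    def __post_init__(self) -> None:
        for name in ("amplitude", "f", "t2_short", "t2_long"):
            _check_finite(name, getattr(self, name))
        if abs(self.amplitude) <= 0:
            raise ValueError("amplitude must be nonzero")
        for name in ("f", "t2_short", "t2_long"):
            lo, hi = MODEL_BOUNDS["be"][name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if not self.t2_short < self.t2_long:
            raise ValueError("t2_short must be < t2_long")

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.f, self.t2_short, self.t2_long])


@dataclass(frozen=True)
class SEParams:
    """Stretched-exponential parameters: T2 (ms) and heterogeneity exponent
    alpha in (0, 1]; alpha = 1 recovers the mono-exponential model."""

    amplitude: complex
    t2: float
    alpha: float

    model_id = "se"

    def __post_init__(self) -> None:
        for name in ("amplitude", "t2", "alpha"):
            _check_finite(name, getattr(self, name))
        if abs(self.amplitude) <= 0:
            raise ValueError("amplitude must be nonzero")
        for name in ("t2", "alpha"):
            lo, hi = MODEL_BOUNDS["se"][name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.t2, self.alpha])


@dataclass(frozen=True)
class NoiseModel:
    """Complex Gaussian noise: i.i.d. N(0, sigma^2) per real/imaginary channel."""

    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.sigma) or self.sigma < 0:
            raise ValueError(f"sigma must be finite and >= 0, got {self.sigma}")


# ---------------------------------------------------------------------------
# forward envelopes (real, amplitude-free) and their gradients
# ---------------------------------------------------------------------------

def _me_envelope(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    (t2,) = theta
    return np.exp(-t / t2)


def _me_grad(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    (t2,) = theta
    g = np.exp(-t / t2)
    return (g * t / t2**2)[:, None]


def _be_envelope(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    f, t2s, t2l = theta
    return f * np.exp(-t / t2s) + (1.0 - f) * np.exp(-t / t2l)


def _be_grad(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    f, t2s, t2l = theta
    es = np.exp(-t / t2s)
    el = np.exp(-t / t2l)
    return np.stack(
        [es - el, f * es * t / t2s**2, (1.0 - f) * el * t / t2l**2], axis=1
    )


def _se_envelope(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    t2, alpha = theta
    u = np.where(t > 0, (t / t2) ** alpha, 0.0)  # 0^alpha := 0 so S(0) = A
    return np.exp(-u)


def _se_grad(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    t2, alpha = theta
    pos = t > 0
    u = np.where(pos, (t / t2) ** alpha, 0.0)
    g = np.exp(-u)
    # u * log(t/t2) -> 0 as t -> 0+ for alpha > 0
    logr = np.where(pos, np.log(np.where(pos, t, 1.0) / t2), 0.0)
    d_t2 = g * alpha * u / t2
    d_alpha = -g * u * logr
    return np.stack([d_t2, d_alpha], axis=1)


_ENVELOPES = {"me": _me_envelope, "be": _be_envelope, "se": _se_envelope}
_GRADS = {"me": _me_grad, "be": _be_grad, "se": _se_grad}


def decay_envelope(model_id: str, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Amplitude-free decay envelope g(t; theta), real-valued, g(0) = 1."""
    return _ENVELOPES[model_id](np.asarray(theta, float), np.asarray(t, float))


def me_signal(params: MEParams, schedule: EchoSchedule) -> np.ndarray:
    """Noise-free mono-exponential signal ``A exp(-t/T2)`` at each pTE."""
    return params.amplitude * _me_envelope(params.theta, schedule.times)


def be_signal(params: BEParams, schedule: EchoSchedule) -> np.ndarray:
    """Noise-free bi-exponential signal; returns exactly A at t = 0."""
    return params.amplitude * _be_envelope(params.theta, schedule.times)


def se_signal(params: SEParams, schedule: EchoSchedule) -> np.ndarray:
    """Noise-free stretched-exponential signal; S(0) = A even for alpha < 1."""
    return params.amplitude * _se_envelope(params.theta, schedule.times)


def add_complex_noise(
    signal: np.ndarray, noise: NoiseModel, seed: int | np.random.Generator
) -> np.ndarray:
    """Add independent Gaussian noise to the real and imaginary channels."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    signal = np.asarray(signal, dtype=complex)
    if noise.sigma == 0:
        return signal.copy()
    eta = rng.normal(0.0, noise.sigma, signal.shape) + 1j * rng.normal(
        0.0, noise.sigma, signal.shape
    )
    return signal + eta


# ---------------------------------------------------------------------------
# Fisher information / CRLB
# ---------------------------------------------------------------------------

def signal_jacobian(
    model_id: str, amplitude: complex, theta: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Complex Jacobian of S(t) w.r.t. the real parameterization
    (Re A, Im A, theta); shape (len(t), 2 + len(theta))."""
    theta = np.asarray(theta, float)
    t = np.asarray(t, float)
    g = _ENVELOPES[model_id](theta, t)
    dg = _GRADS[model_id](theta, t)
    cols = [g.astype(complex), 1j * g]
    for k in range(dg.shape[1]):
        cols.append(amplitude * dg[:, k])
    return np.stack(cols, axis=1)


def fisher_information(
    model_id: str,
    params: MEParams | BEParams | SEParams,
    schedule: EchoSchedule,
    noise: NoiseModel,
) -> np.ndarray:
    """Fisher information matrix under the complex Gaussian noise model.

    With independent N(0, sigma^2) noise on both channels,
    ``I_jk = sigma^-2 sum_t Re(conj(dS/dp_j) dS/dp_k)`` for the real
    parameterization p = (Re A, Im A, theta).
    """
    if noise.sigma <= 0:
        raise ValueError("Fisher information requires sigma > 0")
    J = signal_jacobian(model_id, params.amplitude, params.theta, schedule.times)
    return np.real(J.conj().T @ J) / noise.sigma**2


def crlb(
    model_id: str,
    params: MEParams | BEParams | SEParams,
    schedule: EchoSchedule,
    noise: NoiseModel,
) -> np.ndarray:
    """Per-parameter Cramer-Rao variance lower bounds.

    Returns the diagonal of the inverse Fisher information, ordered as
    (Re A, Im A, *model parameters*). Bounds scale as sigma^2.

    Raises
    ------
    DesignError
        If the information matrix is singular — e.g. all pTEs identical —
        meaning the schedule cannot identify the model.
    """
    info = fisher_information(model_id, params, schedule, noise)
    n = info.shape[0]
    if 2 * len(schedule) < n:  # each complex echo yields two real measurements
        raise DesignError(
            f"{len(schedule)} pTEs cannot identify {n} real parameters of '{model_id}'"
        )
    # relative conditioning guard: inversion of a numerically singular design
    # would silently return garbage bounds
    if np.linalg.cond(info) > 1e12:
        raise DesignError(
            f"singular/ill-conditioned information matrix for schedule {schedule.ptes}"
        )
    return np.diag(np.linalg.inv(info))


def _normalized_crlb_objective(
    model_id, params, times: np.ndarray, noise: NoiseModel
) -> float:
    """Sum of CRLBs normalized by squared nominal parameter values.

    Amplitude bounds (Re A, Im A) are both normalized by |A|^2 so the
    objective is invariant to the amplitude's phase; model-parameter bounds
    are normalized by the nominal value squared (relative variances).
    """
    try:
        bounds = crlb(model_id, params, EchoSchedule(tuple(times)), noise)
    except DesignError:
        return np.inf
    a2 = abs(params.amplitude) ** 2
    scales = np.concatenate([[a2, a2], params.theta**2])
    return float(np.sum(bounds / scales))


@dataclass
class OptimizedSchedule:
    """Result of a schedule search: the schedule plus search metadata."""

    schedule: EchoSchedule
    objective: float
    strategy: str
    n_evaluated: int


def optimize_schedule(
    model_id: str,
    nominal_params: MEParams | BEParams | SEParams,
    n_images: int,
    grid: Sequence[float],
    noise: NoiseModel,
    exhaustive_limit: int = 50_000,
    max_passes: int = 50,
) -> OptimizedSchedule:
    """Choose the n_images pTEs (repeats allowed) minimizing the normalized
    sum of parameter CRLBs at the nominal parameters.

    Exhaustive multiset enumeration when the search space is small, else a
    deterministic greedy exchange (quantile-spread start, coordinate-wise
    replacement passes until no improvement).
    """
    grid = np.asarray(sorted(set(float(g) for g in grid)))
    if grid.size == 0:
        raise ValueError("empty design grid")
    n_free = 2 + len(nominal_params.theta)
    if n_images < n_free:
        raise DesignError(
            f"n_images={n_images} < {n_free} free real parameters of '{model_id}'"
        )

    n_multisets = math.comb(len(grid) + n_images - 1, n_images)
    if n_multisets <= exhaustive_limit:
        best, best_obj, n_eval = None, np.inf, 0
        for combo in itertools.combinations_with_replacement(grid, n_images):
            obj = _normalized_crlb_objective(
                model_id, nominal_params, np.asarray(combo), noise
            )
            n_eval += 1
            if obj < best_obj:
                best, best_obj = combo, obj
        if best is None or not np.isfinite(best_obj):
            raise DesignError("no feasible schedule on the given grid")
        return OptimizedSchedule(
            EchoSchedule(tuple(best)), best_obj, "exhaustive", n_eval
        )

    # greedy exchange on fine grids
    qs = np.linspace(0.0, 1.0, n_images)
    current = np.array([grid[int(round(q * (len(grid) - 1)))] for q in qs])
    current_obj = _normalized_crlb_objective(model_id, nominal_params, current, noise)
    n_eval = 1
    for _ in range(max_passes):
        improved = False
        for i in range(n_images):
            trial = current.copy()
            best_v, best_obj = current[i], current_obj
            for v in grid:
                trial[i] = v
                obj = _normalized_crlb_objective(model_id, nominal_params, trial, noise)
                n_eval += 1
                if obj < best_obj - 1e-15:
                    best_v, best_obj = v, obj
            if best_v != current[i]:
                current[i] = best_v
                current_obj = best_obj
                improved = True
        if not improved:
            break
    if not np.isfinite(current_obj):
        raise DesignError("greedy search found no feasible schedule")
    return OptimizedSchedule(
        EchoSchedule(tuple(sorted(current))), current_obj, "greedy", n_eval
    )
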