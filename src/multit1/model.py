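"""Magnitude inversion-recovery signal model for multi-component T1 relaxometry.

A voxel containing up to seven sub-voxel compartments (cortical layers plus
bordering white matter and CSF) produces a magnitude inversion-recovery signal

    M(TI) = sum_j  M0_j * |1 - 2 exp(-TI / T1_j)|,

where ``M0_j`` is the equilibrium magnetization of compartment ``j``
(proportional to its volume fraction within the voxel) and ``T1_j`` its
spin-lattice relaxation time in milliseconds.  Because only magnitude images
are available the kernel carries an absolute value; no polarity restoration is
attempted.  This module provides the forward model, residuals, sum-of-squares
objective and the analytic Jacobian consumed by the solver.

Parameter vectors are laid out as ``x = [M0_1..M0_n, T1_1..T1_n]`` (length 2n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MAX_COMPONENTS",
    "InversionRecoverySeries",
    "ComponentParameters",
    "ParameterBounds",
    "component_signal",
    "forward_signal",
    "residuals",
    "objective",
    "jacobian",
    "gradient",
    "gauss_newton_hessian",
]

#: Up to seven unique compartments per voxel are assumed (six cortical layers
#: are bordered by CSF and white matter at 3 mm resolution).
MAX_COMPONENTS = 7


def _as_1d_float(values, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class InversionRecoverySeries:
    """One voxel's magnitude samples over a schedule of inversion times.

    ``magnitude`` is real-valued: synthetic Gaussian noise is added directly to
    the magnitudes and may push samples below zero, which the model accepts.
    """

    ti_ms: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self):
        ti = _as_1d_float(self.ti_ms, "ti_ms")
        mag = _as_1d_float(self.magnitude, "magnitude")
        if ti.size != mag.size:
            raise ValueError(
                f"schedule and magnitude lengths differ: {ti.size} != {mag.size}"
            )
        if ti.size < 2:
            raise ValueError("a series needs at least two inversion times")
        if np.any(ti < 0):
            raise ValueError("inversion times must be non-negative")
        if np.any(np.diff(ti) <= 0):
            raise ValueError("inversion times must be strictly increasing")
        if not (np.all(np.isfinite(ti)) and np.all(np.isfinite(mag))):
            raise ValueError("series contains non-finite values")
        object.__setattr__(self, "ti_ms", ti)
        object.__setattr__(self, "magnitude", mag)

    def __len__(self) -> int:
        return self.ti_ms.size


@dataclass(frozen=True)
class ComponentParameters:
    """Per-component (M0_j, T1_j) pairs — the quantity being estimated."""

    m0: np.ndarray
    t1_ms: np.ndarray

    def __post_init__(self):
        m0 = _as_1d_float(self.m0, "m0")
        t1 = _as_1d_float(self.t1_ms, "t1_ms")
        if m0.size != t1.size:
            raise ValueError("m0 and t1_ms must have equal length")
        if not 1 <= m0.size <= MAX_COMPONENTS:
            raise ValueError(
                f"number of components must be in [1, {MAX_COMPONENTS}], got {m0.size}"
            )
        if np.any(m0 < 0):
            raise ValueError("M0 must be non-negative")
        if np.any(t1 <= 0):
            raise ValueError("T1 must be strictly positive")
        object.__setattr__(self, "m0", m0)
        object.__setattr__(self, "t1_ms", t1)

    @property
    def n_components(self) -> int:
        return self.m0.size

    def as_vector(self) -> np.ndarray:
        """Stacked layout [M0_1..M0_n, T1_1..T1_n]."""
        return np.concatenate([self.m0, self.t1_ms])

    @classmethod
    def from_vector(cls, x) -> "ComponentParameters":
        x = _as_1d_float(x, "x")
        if x.size % 2:
            raise ValueError("parameter vector length must be even")
        n = x.size // 2
        return cls(m0=x[:n], t1_ms=x[n:])

    def permuted(self, order) -> "ComponentParameters":
        order = np.asarray(order, dtype=int)
        return ComponentParameters(m0=self.m0[order], t1_ms=self.t1_ms[order])


@dataclass(frozen=True)
class ParameterBounds:
    """Box constraints on every M0_j and T1_j.

    Scalars broadcast to all components.  Typical choice: M0 bounded by the
    maximum magnitude observed in the data, T1 by literature values for the
    fastest (fat, 250 ms) and slowest (CSF, 4000 ms) relaxing tissue.
    """

    m0_lower: np.ndarray | float = 0.0
    m0_upper: np.ndarray | float = field(default=np.inf)
    t1_lower_ms: np.ndarray | float = 250.0
    t1_upper_ms: np.ndarray | float = 4000.0

    def __post_init__(self):
        for lo_name, hi_name in (("m0_lower", "m0_upper"), ("t1_lower_ms", "t1_upper_ms")):
            lo = np.asarray(getattr(self, lo_name), dtype=float)
            hi = np.asarray(getattr(self, hi_name), dtype=float)
            if np.any(lo >= hi):
                raise ValueError(f"{lo_name} must be < {hi_name} elementwise")
        if np.any(np.asarray(self.t1_lower_ms, dtype=float) <= 0):
            raise ValueError("t1_lower_ms must be positive")

    def as_vectors(self, n_components: int) -> tuple[np.ndarray, np.ndarray]:
        """Lower/upper bound vectors in the stacked [M0, T1] layout."""
        lb = np.concatenate(
            [
                np.broadcast_to(np.asarray(self.m0_lower, float), n_components),
                np.broadcast_to(np.asarray(self.t1_lower_ms, float), n_components),
            ]
        )
        ub = np.concatenate(
            [
                np.broadcast_to(np.asarray(self.m0_upper, float), n_components),
                np.broadcast_to(np.asarray(self.t1_upper_ms, float), n_components),
            ]
        )
        return lb.astype(float), ub.astype(float)

    def contains(self, params: ComponentParameters, atol: float = 0.0) -> bool:
        lb, ub = self.as_vectors(params.n_components)
        x = params.as_vector()
        return bool(np.all(x >= lb - atol) and np.all(x <= ub + atol))


def component_signal(m0: float, t1_ms: float, ti_ms):
    """Magnitude IR signal of a single compartment: ``m0 * |1 - 2 exp(-TI/T1)|``.

    The kernel is bounded in [0, 1] for TI >= 0 and has a single null point at
    TI = T1 * ln 2.
    """
    if t1_ms <= 0:
        raise ValueError("t1_ms must be positive")
    if m0 < 0:
        raise ValueError("m0 must be non-negative")
    ti = np.asarray(ti_ms, dtype=float)
    return m0 * np.abs(1.0 - 2.0 * np.exp(-ti / t1_ms))


def forward_signal(params: ComponentParameters, ti_ms):
    """Sum of compartment magnitudes at the requested inversion time(s)."""
    ti = np.atleast_1d(np.asarray(ti_ms, dtype=float))
    kernels = np.abs(1.0 - 2.0 * np.exp(-ti[:, None] / params.t1_ms[None, :]))
    out = kernels @ params.m0
    return out if np.ndim(ti_ms) else float(out[0])


def residuals(params: ComponentParameters, series: InversionRecoverySeries) -> np.ndarray:
    """r_i = magnitude_i - M(TI_i)."""
    return series.magnitude - forward_signal(params, series.ti_ms)


def objective(params: ComponentParameters, series: InversionRecoverySeries) -> float:
    """Sum of squared residuals; zero iff the model interpolates the data."""
    r = residuals(params, series)
    return float(r @ r)


def jacobian(params: ComponentParameters, series: InversionRecoverySeries) -> np.ndarray:
    """Analytic Jacobian of the *model* M(TI) w.r.t. [M0, T1] (len(series) x 2n).

    dM/dM0_j = |1 - 2 e^(-TI/T1_j)|
    dM/dT1_j = M0_j * sign(1 - 2 e^(-TI/T1_j)) * (-2 e^(-TI/T1_j) TI / T1_j^2)

    At the kernel's null point the absolute value is non-differentiable; the
    convention sign(0) = 0 selects a valid subgradient there (a measure-zero
    event on any continuous schedule).
    """
    ti = series.ti_ms
    m0, t1 = params.m0, params.t1_ms
    e = np.exp(-ti[:, None] / t1[None, :])
    u = 1.0 - 2.0 * e
    n = m0.size
    jac = np.empty((ti.size, 2 * n))
    jac[:, :n] = np.abs(u)
    jac[:, n:] = m0[None, :] * np.sign(u) * (-2.0 * e * ti[:, None] / t1[None, :] ** 2)
    return jac


def gradient(params: ComponentParameters, series: InversionRecoverySeries) -> np.ndarray:
    """Gradient of the objective: -2 J^T r."""
    return -2.0 * jacobian(params, series).T @ residuals(params, series)


def gauss_newton_hessian(
    params: ComponentParameters, series: InversionRecoverySeries
) -> np.ndarray:
    """Gauss-Newton Hessian approximation 2 J^T J (positive semi-definite)."""
    jac = jacobian(params, series)
    return 2.0 * jac.T @ jac
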