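"""Bound-constrained trust-region least squares with multi-start initialization.

The fitting problem min_x ||y - M(x)||^2 subject to box constraints is solved
by a trust-region iteration whose local quadratic model

    m_k(s) = f(x_k) + g_k^T s + 1/2 s^T H_k s,      H_k = 2 J^T J  (Gauss-Newton)

is minimized over the two-dimensional subspace spanned by the (scaled) steepest
descent direction and the Newton direction H v = -g, intersected with the ball
||s|| <= Delta_k.  Because the multi-exponential objective is riddled with
non-optimal local minima, a single descent run is unreliable; the solver is
therefore restarted from many starting points drawn uniformly inside the bounds
and the best local solution is kept.

All trust-region arithmetic happens in affine-scaled coordinates
z = (x - lb) / (ub - lb) in [0, 1]^{2n}: M0 (signal units) and T1 (hundreds to
thousands of ms) live on very different scales, and an unscaled radius would be
meaningless across coordinates.  Steps that would cross a bound are truncated
to 99.5% of the distance to the bound, keeping all iterates strictly interior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    ComponentParameters,
    InversionRecoverySeries,
    ParameterBounds,
)

__all__ = [
    "SolverConfig",
    "MultiStartConfig",
    "SingleStartResult",
    "FitResult",
    "MultiStartError",
    "QuadraticModel",
    "build_quadratic_model",
    "solve_subproblem_2d",
    "step_quality",
    "update_radius",
    "minimize_least_squares",
    "solve_bounded",
    "sample_starting_points",
    "multistart_fit",
]

_INTERIOR_MARGIN = 1e-10  # starting points on a bound are nudged inward by this
_STEP_BACK = 0.995  # fraction of the distance to a violated bound that is taken
_MIN_RADIUS = 1e-13


@dataclass(frozen=True)
class SolverConfig:
    """Trust-region controls.

    Defaults follow standard trust-region-reflective practice: the radius is
    quartered after a poor step (predicted/actual agreement rho below 0.25),
    doubled after a very good boundary step (rho above 0.75), and unchanged
    otherwise.  Radii are expressed in the affine-scaled unit box.
    """

    max_iterations: int = 400
    gradient_tolerance: float = 1e-8
    step_tolerance: float = 1e-10
    objective_tolerance: float = 1e-10  # relative decrease per accepted step
    initial_radius: float = 1.0
    radius_shrink: float = 0.25
    radius_grow: float = 2.0
    accept_threshold_low: float = 0.25
    accept_threshold_high: float = 0.75

    def __post_init__(self):
        if not 0 < self.radius_shrink < 1:
            raise ValueError("radius_shrink must be in (0, 1)")
        if self.radius_grow <= 1:
            raise ValueError("radius_grow must exceed 1")
        if not 0 < self.accept_threshold_low < self.accept_threshold_high < 1:
            raise ValueError("need 0 < accept_threshold_low < accept_threshold_high < 1")
        for name in ("gradient_tolerance", "step_tolerance", "initial_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class MultiStartConfig:
    """How many random restarts, from where, and under which seed."""

    n_starts: int
    seed: int
    bounds: ParameterBounds

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class SingleStartResult:
    x: np.ndarray
    objective: float
    n_iterations: int
    converged: bool
    status: str
    objective_history: np.ndarray  # objective at every accepted iterate


@dataclass
class FitResult:
    """Best local solution over all starts plus per-start diagnostics."""

    best_params: ComponentParameters
    best_objective: float
    best_start_index: int
    per_start_objectives: np.ndarray
    converged_flags: np.ndarray
    n_iterations: np.ndarray

    @property
    def n_starts(self) -> int:
        return self.per_start_objectives.size


class MultiStartError(RuntimeError):
    """Raised when every start fails; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class QuadraticModel:
    """m(s) = f0 + g.s + 1/2 s.H.s — the local model of the objective."""

    f0: float
    g: np.ndarray
    hess: np.ndarray

    def __call__(self, s) -> float:
        s = np.asarray(s, dtype=float)
        return float(self.f0 + self.g @ s + 0.5 * s @ self.hess @ s)

    def decrease(self, s) -> float:
        """Predicted reduction m(0) - m(s)."""
        s = np.asarray(s, dtype=float)
        return float(-(self.g @ s + 0.5 * s @ self.hess @ s))


def build_quadratic_model(f0: float, g: np.ndarray, hess: np.ndarray) -> QuadraticModel:
    g = np.asarray(g, dtype=float)
    hess = np.asarray(hess, dtype=float)
    if not (np.isfinite(f0) and np.all(np.isfinite(g)) and np.all(np.isfinite(hess))):
        raise FloatingPointError("non-finite gradient or Hessian; solver aborted")
    return QuadraticModel(float(f0), g, hess)


# ---------------------------------------------------------------------------
# exact trust-region subproblem in <= 2 dimensions
# ---------------------------------------------------------------------------


def _eigh2(b00: float, b01: float, b11: float):
    """Eigen-decomposition of a symmetric 2x2 matrix, ascending eigenvalues."""
    half_tr = 0.5 * (b00 + b11)
    disc = math.hypot(0.5 * (b00 - b11), b01)
    w0, w1 = half_tr - disc, half_tr + disc
    if disc <= 1e-18 * max(1.0, abs(half_tr)):
        return (w0, w1), ((1.0, 0.0), (0.0, 1.0))
    # eigenvector for w0: (B - w0 I) v = 0
    if abs(b01) > abs(b00 - w0):
        v0 = (b01, w0 - b00)
    else:
        v0 = (w0 - b11, b01)
    norm = math.hypot(*v0)
    v0 = (v0[0] / norm, v0[1] / norm)
    v1 = (-v0[1], v0[0])
    return (w0, w1), (v0, v1)


def _tr_exact_diag(w, gq, delta):
    """min gq.p + 1/2 sum w_i p_i^2 s.t. ||p|| <= delta, diagonalized coords."""
    w = [float(v) for v in w]
    gq = [float(v) for v in gq]
    k = len(w)
    # interior Newton point when the model is strictly convex
    if w[0] > 0:
        p = [-gq[i] / w[i] for i in range(k)]
        if sum(v * v for v in p) <= delta * delta:
            return p
    lam0 = max(0.0, -w[0])

    def norm2(lam):
        return sum((gq[i] / (w[i] + lam)) ** 2 for i in range(k) if w[i] + lam > 0.0)

    scale = max(1.0, max(abs(v) for v in w))
    eps = 1e-14 * scale
    if norm2(lam0 + eps) < delta * delta:
        # hard case: gradient (numerically) orthogonal to the lowest mode;
        # fill the remaining norm along that eigenvector
        lam = lam0 + eps
        p = [(-gq[i] / (w[i] + lam)) if w[i] + lam > eps else 0.0 for i in range(k)]
        extra = delta * delta - sum(v * v for v in p)
        p[0] += math.sqrt(max(extra, 0.0))
        return p
    # secular equation: ||p(lam)|| = delta has a unique root in (lam0, hi]
    gnorm = math.sqrt(sum(v * v for v in gq))
    lo, hi = lam0 + eps, max(lam0 + eps, gnorm / delta - w[0])
    lam = 0.5 * (lo + hi)
    for _ in range(80):
        n2 = norm2(lam)
        pn = math.sqrt(n2)
        phi = 1.0 / pn - 1.0 / delta
        if abs(phi) < 1e-12 / delta:
            break
        if phi > 0.0:  # ||p|| < delta -> lambda too large
            hi = lam
        else:
            lo = lam
        # Newton step on phi(lam) = 1/||p|| - 1/delta
        dn2 = -2.0 * sum(
            gq[i] ** 2 / (w[i] + lam) ** 3 for i in range(k) if w[i] + lam > 0.0
        )
        dphi = -0.5 * dn2 / (n2 * pn)
        lam_new = lam - phi / dphi if dphi != 0.0 else 0.5 * (lo + hi)
        lam = lam_new if lo < lam_new < hi else 0.5 * (lo + hi)
    return [-gq[i] / (w[i] + lam) for i in range(k)]


def _tr_step_subspace(basis: np.ndarray, model: QuadraticModel, radius: float) -> np.ndarray:
    """Exact TR step within span(basis columns), basis orthonormal."""
    gs = basis.T @ model.g
    bs = basis.T @ model.hess @ basis
    if basis.shape[1] == 1:
        w = (float(bs[0, 0]),)
        p = _tr_exact_diag(w, (float(gs[0]),), radius)
        return basis[:, 0] * p[0]
    (w0, w1), (v0, v1) = _eigh2(bs[0, 0], bs[0, 1], bs[1, 1])
    q = np.array([[v0[0], v1[0]], [v0[1], v1[1]]])
    gq = (
        v0[0] * gs[0] + v0[1] * gs[1],
        v1[0] * gs[0] + v1[1] * gs[1],
    )
    p = _tr_exact_diag((w0, w1), gq, radius)
    return basis @ (q @ np.asarray(p))


def _orthonormal_2d_basis(g: np.ndarray, hess: np.ndarray) -> np.ndarray:
    """Columns spanning {-g, Newton direction}; falls back to 1D on degeneracy.

    The Gauss-Newton Hessian is positive semi-definite, so true negative
    curvature cannot arise; rank deficiency degrades gracefully to the
    steepest-descent subspace.
    """
    gnorm = float(np.linalg.norm(g))
    q1 = -g / gnorm
    try:
        v = np.linalg.solve(hess, -g)
        if not np.all(np.isfinite(v)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        v = None
    if v is not None:
        v_orth = v - (v @ q1) * q1
        vnorm = float(np.linalg.norm(v_orth))
        if vnorm > 1e-10 * max(float(np.linalg.norm(v)), 1e-300):
            return np.column_stack([q1, v_orth / vnorm])
    return q1[:, None]


def _rescale_truncated(z: np.ndarray, scale: np.ndarray, s_hat: np.ndarray) -> np.ndarray:
    """Truncate a scaled-space step so z + scale * s_hat stays inside the box."""
    s_z = scale * s_hat
    alpha = 1.0
    for zi, si in zip(z, s_z):
        if si > 0.0 and zi + si > 1.0:
            alpha = min(alpha, (1.0 - zi) / si)
        elif si < 0.0 and zi + si < 0.0:
            alpha = min(alpha, -zi / si)
    if alpha >= 1.0:
        return s_hat
    return (_STEP_BACK * alpha) * s_hat


def _truncate_to_box(z: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Scale the step so z + s stays strictly inside [0, 1]^d."""
    alpha = 1.0
    for zi, si in zip(z, s):
        if si > 0.0 and zi + si > 1.0:
            alpha = min(alpha, (1.0 - zi) / si)
        elif si < 0.0 and zi + si < 0.0:
            alpha = min(alpha, -zi / si)
    if alpha >= 1.0:
        return s
    return (_STEP_BACK * alpha) * s


def solve_subproblem_2d(
    model: QuadraticModel,
    radius: float,
    position: np.ndarray | None = None,
) -> np.ndarray:
    """Trial step minimizing the model over the 2D subspace within the ball.

    When ``position`` (the current point in unit-box coordinates) is given,
    candidate steps are truncated to remain strictly inside the box and the
    bound-truncated Cauchy step is considered as well; the candidate with the
    lowest model value wins.  A zero gradient returns the zero step (first-order
    stationary point).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    g = model.g
    if not np.any(g):
        return np.zeros_like(g)
    basis = _orthonormal_2d_basis(g, model.hess)
    s = _tr_step_subspace(basis, model, radius)
    if position is None:
        return s
    best = _truncate_to_box(position, s)
    best_val = model(best)
    cauchy = _truncate_to_box(position, _cauchy_step(model, radius))
    cauchy_val = model(cauchy)
    if cauchy_val < best_val:
        return cauchy
    return best


def _cauchy_step(model: QuadraticModel, radius: float) -> np.ndarray:
    """Optimal step along the steepest-descent direction within the ball."""
    g = model.g
    gnorm = float(np.linalg.norm(g))
    ghg = float(g @ model.hess @ g)
    tau = radius / gnorm
    if ghg > 0.0:
        tau = min(tau, gnorm * gnorm / ghg)
    return -tau * g


def step_quality(model: QuadraticModel, f_trial: float, s: np.ndarray) -> float:
    """rho = actual reduction / predicted reduction for the trial step."""
    predicted = model.decrease(s)
    if predicted <= 0.0:
        return -np.inf  # model predicts no progress: reject outright
    return (model.f0 - f_trial) / predicted


def update_radius(
    config: SolverConfig, rho: float, step_norm: float, radius: float
) -> tuple[float, bool]:
    """Radius policy: poor agreement shrinks, strong agreement on a boundary
    step grows, anything in between keeps the radius.  Returns (new radius,
    step accepted)."""
    if not np.isfinite(rho) or rho < config.accept_threshold_low:
        return radius * config.radius_shrink, False
    if rho > config.accept_threshold_high and step_norm >= 0.95 * radius:
        return radius * config.radius_grow, True
    return radius, True


# ---------------------------------------------------------------------------
# single-start bounded minimization
# ---------------------------------------------------------------------------


def minimize_least_squares(
    res_jac,
    x0: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    config: SolverConfig | None = None,
) -> SingleStartResult:
    """Trust-region minimization of ||r(x)||^2 over a box.

    ``res_jac(x)`` must return the residual vector and its Jacobian dr/dx.
    Works in unit-box scaled coordinates internally; every accepted iterate is
    strictly interior and never increases the objective.
    """
    cfg = config or SolverConfig()
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    d = upper - lower
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValueError("bounds must be finite with lower < upper")
    z = np.clip((np.asarray(x0, dtype=float) - lower) / d, _INTERIOR_MARGIN, 1.0 - _INTERIOR_MARGIN)

    def eval_point(zv):
        r, jac = res_jac(lower + d * zv)
        return r, jac * d  # column scaling: d r / d z

    r, jac = eval_point(z)
    f = float(r @ r)
    if not np.isfinite(f):
        raise ValueError("objective is non-finite at the starting point")
    radius = cfg.initial_radius
    history = [f]
    status = "maxiter"
    it = 0
    model = None
    scale = None
    while it < cfg.max_iterations:
        it += 1
        if model is None:
            g = 2.0 * (jac.T @ r)
            # Coleman-Li distance-to-bound vector: the bound each gradient
            # component pushes toward.  Its product with g is the optimality
            # measure (zero at a constrained stationary point), and its square
            # root scales the step space so that directions into a nearby
            # bound are shortened without freezing the other coordinates.
            v = np.where(g > 0.0, z, 1.0 - z)
            if float(np.max(np.abs(v * g))) < cfg.gradient_tolerance:
                status = "gtol"
                break
            scale = np.sqrt(v)
            g_hat = scale * g
            hess = 2.0 * (jac.T @ jac)
            hess_hat = scale[:, None] * hess * scale[None, :]
            hess_hat[np.diag_indices_from(hess_hat)] += np.abs(g)
            model = build_quadratic_model(f, g_hat, hess_hat)
        s_hat = solve_subproblem_2d(model, radius)
        cauchy_hat = _cauchy_step(model, radius)
        # candidates mapped back to the unit box and truncated to stay interior
        s_hat = min(
            (_rescale_truncated(z, scale, c) for c in (s_hat, cauchy_hat)),
            key=model,
        )
        step_norm = float(np.linalg.norm(s_hat))
        if step_norm == 0.0:
            status = "gtol"
            break
        predicted = model.decrease(s_hat)
        if predicted <= 0.0:
            radius *= cfg.radius_shrink
            if radius < _MIN_RADIUS:
                status = "xtol"
                break
            continue
        z_new = z + scale * s_hat
        r_new, jac_new = eval_point(z_new)
        f_new = float(r_new @ r_new)
        rho = (f - f_new) / predicted if np.isfinite(f_new) else -np.inf
        radius, accepted = update_radius(cfg, rho, step_norm, radius)
        if accepted:
            df = f - f_new
            z, r, jac, f = z_new, r_new, jac_new, f_new
            model = None
            history.append(f)
            if step_norm < cfg.step_tolerance:
                status = "xtol"
                break
            if df <= cfg.objective_tolerance * max(f, 1e-300):
                status = "ftol"
                break
        elif radius < _MIN_RADIUS:
            status = "xtol"
            break
    return SingleStartResult(
        x=lower + d * z,
        objective=f,
        n_iterations=it,
        converged=status != "maxiter",
        status=status,
        objective_history=np.asarray(history),
    )


def _series_res_jac(series: InversionRecoverySeries, n_components: int):
    ti = series.ti_ms
    y = series.magnitude
    m = ti.size
    n = n_components
    ti_col = ti[:, None]

    def res_jac(x):
        m0 = x[:n]
        t1 = x[n:]
        e = np.exp(ti_col / (-t1[None, :]))
        u = 1.0 - 2.0 * e
        k = np.abs(u)
        r = y - k @ m0
        jac = np.empty((m, 2 * n))
        jac[:, :n] = -k
        jac[:, n:] = m0[None, :] * np.sign(u) * (2.0 * e * ti_col / (t1[None, :] ** 2))
        return r, jac

    return res_jac


def solve_bounded(
    series: InversionRecoverySeries,
    x0: np.ndarray,
    bounds: ParameterBounds,
    config: SolverConfig | None = None,
) -> SingleStartResult:
    """Single-start bounded fit of the multi-component IR model to one series."""
    x0 = np.asarray(x0, dtype=float)
    if x0.size % 2:
        raise ValueError("parameter vector length must be even")
    n = x0.size // 2
    if len(series) < 2 * n:
        raise ValueError(
            f"series of length {len(series)} cannot identify {n} components "
            f"(need at least {2 * n} samples)"
        )
    lb, ub = bounds.as_vectors(n)
    return minimize_least_squares(_series_res_jac(series, n), x0, lb, ub, config)


# ---------------------------------------------------------------------------
# multi-start
# ---------------------------------------------------------------------------


def sample_starting_points(
    mconfig: MultiStartConfig,
    n_params: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Uniform starting points inside the bounds, one row per start.

    Points are drawn sequentially so that the first k points of an n-start set
    equal the k-start set under the same seed (nested prefixes).
    """
    if n_params % 2:
        raise ValueError("n_params must be even (M0 and T1 per component)")
    lb, ub = mconfig.bounds.as_vectors(n_params // 2)
    rng = rng if rng is not None else np.random.default_rng(mconfig.seed)
    return np.vstack([rng.uniform(lb, ub) for _ in range(mconfig.n_starts)])


def multistart_fit(
    series: InversionRecoverySeries,
    bounds: ParameterBounds,
    mconfig: MultiStartConfig,
    config: SolverConfig | None = None,
    n_components: int | None = None,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Run the bounded solver from every start; keep the lowest objective.

    Repeated initialization from random points prevents termination in the
    local non-optimality traps that a single multi-exponential descent run
    routinely falls into.  Ties are broken by start index.
    """
    n = n_components if n_components is not None else _infer_n_components(bounds)
    starts = sample_starting_points(mconfig, 2 * n, rng=rng)
    objectives = np.full(mconfig.n_starts, np.inf)
    flags = np.zeros(mconfig.n_starts, dtype=bool)
    iters = np.zeros(mconfig.n_starts, dtype=int)
    best: SingleStartResult | None = None
    best_idx = -1
    failures: list[tuple[int, Exception]] = []
    for i, x0 in enumerate(starts):
        try:
            result = solve_bounded(series, x0, bounds, config)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError) as exc:
            if isinstance(exc, ValueError) and "identify" in str(exc):
                raise  # too-short series is a caller error, not a bad start
            failures.append((i, exc))
            continue
        objectives[i] = result.objective
        flags[i] = result.converged
        iters[i] = result.n_iterations
        if best is None or result.objective < best.objective:
            best = result
            best_idx = i
    if best is None:
        raise MultiStartError(
            f"all {mconfig.n_starts} starts failed", diagnostics=failures
        )
    return FitResult(
        best_params=ComponentParameters.from_vector(best.x),
        best_objective=best.objective,
        best_start_index=best_idx,
        per_start_objectives=objectives,
        converged_flags=flags,
        n_iterations=iters,
    )


def _infer_n_components(bounds: ParameterBounds) -> int:
    sizes = {
        np.asarray(getattr(bounds, name)).size
        for name in ("m0_lower", "m0_upper", "t1_lower_ms", "t1_upper_ms")
    }
    sizes.discard(1)
    if len(sizes) == 1:
        return sizes.pop()
    raise ValueError(
        "n_components cannot be inferred from scalar bounds; pass n_components"
    )
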