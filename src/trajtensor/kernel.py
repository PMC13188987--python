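"""Rescaled Bernoulli-polynomial kernel and penalized temporal smoothing.

The temporal loading of each component lives in the reproducing-kernel
Hilbert space (RKHS) of the rescaled Bernoulli polynomial kernel on [0, 1],

    K(s, t) = 1 + k1(s) k1(t) + k2(s) k2(t) - k4(|s - t|),

with k1(s) = s - 1/2, k2(s) = (k1^2 - 1/12) / 2 and
k4(s) = (k1^4 - k1^2/2 + 7/240) / 24.  The associated squared norm

    ||xi||_H^2 = int (xi'')^2 dt + (int xi dt)^2
               + (int xi k1 dt)^2 + (int xi k2 dt)^2

penalizes curvature together with the projections on the polynomial basis
up to order two, so penalized fits favour smooth, slowly varying loadings.
Temporal-loading updates are weighted kernel ridge regressions solved in the
span of K(., t_u) over the observed time points (representer theorem).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson

__all__ = [
    "bernoulli_kernel",
    "gram_matrix",
    "rkhs_norm_sq",
    "SmoothFunction",
    "PenaltyConfig",
    "fit_smooth_function",
]


def _k1(s: np.ndarray) -> np.ndarray:
    return s - 0.5


def _k2(s: np.ndarray) -> np.ndarray:
    k1 = s - 0.5
    return (k1 * k1 - 1.0 / 12.0) / 2.0


def _k4(s: np.ndarray) -> np.ndarray:
    k1 = s - 0.5
    k1sq = k1 * k1
    return (k1sq * k1sq - k1sq / 2.0 + 7.0 / 240.0) / 24.0


def bernoulli_kernel(s, t):
    """Evaluate K(s, t) elementwise; both arguments must lie in [0, 1]."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    for name, x in (("s", s), ("t", t)):
        if np.any(x < 0.0) or np.any(x > 1.0):
            raise ValueError(f"{name} outside [0, 1]")
    out = 1.0 + _k1(s) * _k1(t) + _k2(s) * _k2(t) - _k4(np.abs(s - t))
    return out if out.ndim else float(out)


def gram_matrix(points: np.ndarray) -> np.ndarray:
    """Kernel Gram matrix on a vector of distinct points in [0, 1]."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 1:
        raise ValueError("points must be a 1-D vector")
    if np.unique(points).size != points.size:
        raise ValueError("duplicate points in Gram matrix")
    return bernoulli_kernel(points[:, None], points[None, :])


@dataclass
class PenaltyConfig:
    """Smoothness penalty for temporal-loading fits.

    ``c_k`` is the weight on the squared RKHS norm.  With
    ``scale_by_observations`` (the default) the effective penalty is
    ``c_k * n_triples`` for the component being fitted, which keeps the
    balance between the data term (which grows with the number of observed
    entries) and the penalty roughly constant across dataset sizes; set it
    to False to use ``c_k`` verbatim.
    """

    c_k: float = 1e-4
    scale_by_observations: bool = True
    quadrature_points: int = 101

    def __post_init__(self) -> None:
        if self.c_k < 0:
            raise ValueError("c_k must be nonnegative")
        if self.quadrature_points < 21:
            raise ValueError("quadrature_points must be >= 21")

    def effective(self, n_triples: int) -> float:
        return self.c_k * n_triples if self.scale_by_observations else self.c_k


@dataclass
class SmoothFunction:
    """A function in the kernel span, xi(t) = sum_u c_u K(t, anchor_u)."""

    anchor_times: np.ndarray
    coefficients: np.ndarray
    n_grid: int = 101
    _grid_cache: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.anchor_times = np.asarray(self.anchor_times, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.anchor_times.shape != self.coefficients.shape:
            raise ValueError("anchors and coefficients must align")

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        vals = bernoulli_kernel(t[:, None], self.anchor_times[None, :]) @ self.coefficients
        return vals

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached values on the uniform evaluation grid."""
        if self._grid_cache is None:
            t = np.linspace(0.0, 1.0, self.n_grid)
            self._grid_cache = (t, self(t))
        return self._grid_cache

    def l2_norm_sq(self) -> float:
        """Quadrature estimate of int_0^1 xi(t)^2 dt."""
        t, y = self.grid()
        return float(simpson(y * y, x=t))

    def mean_integral(self) -> float:
        t, y = self.grid()
        return float(simpson(y, x=t))

    def scaled(self, factor: float) -> "SmoothFunction":
        return SmoothFunction(self.anchor_times, self.coefficients * factor,
                              n_grid=self.n_grid)


def _second_derivative(y: np.ndarray, h: float) -> np.ndarray:
    """Finite-difference second derivative; second-order one-sided at ends."""
    d2 = np.empty_like(y)
    d2[1:-1] = (y[:-2] - 2.0 * y[1:-1] + y[2:]) / (h * h)
    d2[0] = (2.0 * y[0] - 5.0 * y[1] + 4.0 * y[2] - y[3]) / (h * h)
    d2[-1] = (2.0 * y[-1] - 5.0 * y[-2] + 4.0 * y[-3] - y[-4]) / (h * h)
    return d2


def rkhs_norm_sq(f, n_grid: int = 101) -> float:
    """Squared RKHS norm of a function on [0, 1].

    ``f`` may be a :class:`SmoothFunction`, any callable, or an array of
    values sampled on the uniform ``n_grid``-point grid.  Integrals use
    composite Simpson quadrature; the second derivative is approximated by
    central finite differences (one-sided at the endpoints).
    """
    t = np.linspace(0.0, 1.0, n_grid)
    if isinstance(f, SmoothFunction) and f.n_grid == n_grid:
        _, y = f.grid()
    elif callable(f):
        y = np.asarray(f(t), dtype=float)
    else:
        y = np.asarray(f, dtype=float)
        if y.shape != t.shape:
            raise ValueError(f"grid values must have length {n_grid}")
    if y.size < 5:
        raise ValueError("need at least 5 grid points")
    h = t[1] - t[0]
    d2 = _second_derivative(y, h)
    curvature = float(simpson(d2 * d2, x=t))
    proj0 = float(simpson(y, x=t))
    proj1 = float(simpson(y * _k1(t), x=t))
    proj2 = float(simpson(y * _k2(t), x=t))
    return curvature + proj0 ** 2 + proj1 ** 2 + proj2 ** 2


def fit_smooth_function(times: np.ndarray, targets: np.ndarray,
                        weights: np.ndarray,
                        penalty: PenaltyConfig | float = 0.0) -> SmoothFunction:
    """Penalized least-squares fit of a smooth function of pseudotime.

    Minimizes ``sum_u w_u (z_u - xi(t_u))^2 + C ||xi||_H^2`` over the RKHS.
    By the representer theorem the minimizer lies in the span of
    ``K(., t_u)`` over the distinct observed times, reducing the problem to
    the linear system ``(W G + C I) c = W z``.

    Duplicate times are collapsed to a single anchor with summed weight and
    weight-averaged target (an exact reduction of the least-squares term).
    """
    c_pen = penalty.effective(0) if isinstance(penalty, PenaltyConfig) else float(penalty)
    times = np.asarray(times, dtype=float)
    targets = np.asarray(targets, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not (times.shape == targets.shape == weights.shape):
        raise ValueError("times, targets and weights must have equal length")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if not np.any(weights > 0):
        raise ValueError("need at least one positive weight")

    # collapse duplicates, drop zero-weight points
    order = np.argsort(times, kind="stable")
    t_s, z_s, w_s = times[order], targets[order], weights[order]
    uniq, start = np.unique(t_s, return_index=True)
    w_u = np.add.reduceat(w_s, start)
    z_u = np.add.reduceat(w_s * z_s, start)
    pos = w_u > 0
    uniq, w_u, z_u = uniq[pos], w_u[pos], z_u[pos] / w_u[pos]

    gram = gram_matrix(uniq)
    lhs = w_u[:, None] * gram + c_pen * np.eye(uniq.size)
    try:
        coef = np.linalg.solve(lhs, w_u * z_u)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(lhs)
        raise np.linalg.LinAlgError(
            f"singular smoothing system (condition number {cond:.3e})") from exc
    return SmoothFunction(uniq, coef)
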