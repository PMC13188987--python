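"""Trajectory binning, gene filtering, HVG selection and standardization.

The chain mirrors the usual preparation of multi-sample pseudotemporal
data for decomposition: cells are collapsed into per-(sample, bin) median
"metacells" on an equal-width pseudotime grid, lowly expressed genes are
dropped, highly variable genes are selected by the sign of their residual
from a local-polynomial (LOESS) fit of standard deviation on mean, and the
surviving genes are standardized to zero mean and unit variance across all
metacells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .tensor import TemporalTensor

logger = logging.getLogger(__name__)

__all__ = [
    "BinningSpec",
    "HVGSpec",
    "bin_cells",
    "filter_genes",
    "select_hvg",
    "standardize_genes",
    "loess_fit",
]


@dataclass
class BinningSpec:
    """Equal-width pseudotime bins over a closed domain.

    Bins are left-closed/right-open except the last, which is closed so the
    domain's right endpoint is assigned.  Each nonempty (sample, bin) pair
    becomes one metacell at the bin midpoint.
    """

    n_bins: int = 50
    domain: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.domain[1] <= self.domain[0]:
            raise ValueError("degenerate binning domain")

    def assign(self, t: np.ndarray) -> np.ndarray:
        lo, hi = self.domain
        idx = np.floor((t - lo) / (hi - lo) * self.n_bins).astype(int)
        return np.clip(idx, 0, self.n_bins - 1)

    def midpoints(self) -> np.ndarray:
        lo, hi = self.domain
        width = (hi - lo) / self.n_bins
        return lo + width * (np.arange(self.n_bins) + 0.5)


@dataclass
class HVGSpec:
    loess_span: float = 0.75
    loess_degree: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must be in (0, 1]")
        if self.loess_degree < 1:
            raise ValueError("loess_degree must be >= 1")


def bin_cells(tensor: TemporalTensor, spec: BinningSpec | None = None) -> TemporalTensor:
    """Collapse cells into per-(sample, bin) median metacells.

    Each metacell carries the per-gene median over the sample's cells whose
    pseudotime falls in the bin, and sits at the bin midpoint.  Empty bins
    are absent, so the output grids remain sample-specific.
    """
    spec = spec or BinningSpec()
    lo, hi = spec.domain
    mids = spec.midpoints()
    times, values = [], []
    for sid, t, v in zip(tensor.sample_ids, tensor.times, tensor.values):
        if t.min() < lo - 1e-12 or t.max() > hi + 1e-12:
            raise ValueError(f"sample {sid!r}: pseudotimes outside binning domain")
        idx = spec.assign(t)
        present = np.unique(idx)
        med = np.stack([np.median(v[idx == b], axis=0) for b in present])
        times.append(mids[present])
        values.append(med)
    return replace(tensor, times=times, values=values, time_domain=spec.domain)


def filter_genes(tensor: TemporalTensor, min_expr: float = 0.1,
                 min_frac: float = 0.05) -> TemporalTensor:
    """Keep genes expressed above ``min_expr`` in at least ``min_frac`` of metacells.

    Expression is compared strictly (> min_expr); the prevalence fraction is
    compared inclusively (>= min_frac).
    """
    stacked = tensor.stacked_values()
    if stacked.size == 0:
        raise ValueError("empty tensor")
    frac = np.mean(stacked > min_expr, axis=0)
    keep = frac >= min_frac
    if not np.any(keep):
        raise ValueError(
            f"no genes pass the expression filter (0 of {tensor.n_genes} have "
            f"value > {min_expr} in >= {min_frac:.0%} of {stacked.shape[0]} metacells)")
    logger.info("filter_genes: kept %d of %d genes", int(keep.sum()), tensor.n_genes)
    return tensor.subset_genes(keep)


def loess_fit(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray,
              span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    For each evaluation point the nearest ``ceil(span * len(x))`` points by
    |x - x0| are weighted by the tricube kernel and a degree-``degree``
    weighted polynomial is fit and evaluated at x0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.atleast_1d(np.asarray(x_eval, dtype=float))
    n = x.size
    q = max(int(np.ceil(span * n)), degree + 1)
    q = min(q, n)
    out = np.empty(x_eval.size)
    for i, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        nearest = np.argpartition(d, q - 1)[:q]
        dmax = d[nearest].max()
        if dmax == 0:
            raise ValueError("degenerate LOESS fit: all predictor values identical "
                             "within the local window")
        w = (1 - (d[nearest] / dmax) ** 3) ** 3
        w = np.maximum(w, 1e-12)
        coeffs = np.polynomial.polynomial.polyfit(
            x[nearest] - x0, y[nearest], deg=degree, w=np.sqrt(w))
        out[i] = coeffs[0]
    return out


def select_hvg(tensor: TemporalTensor, spec: HVGSpec | None = None) -> TemporalTensor:
    """Retain highly variable genes: positive residual from LOESS of sd on mean."""
    spec = spec or HVGSpec()
    if tensor.n_genes < 5:
        raise ValueError("need at least 5 genes for the LOESS mean-variance fit")
    stacked = tensor.stacked_values()
    if stacked.shape[0] < 2:
        raise ValueError("each gene needs at least 2 metacell values")
    means = stacked.mean(axis=0)
    sds = stacked.std(axis=0, ddof=1)
    if np.ptp(means) == 0:
        raise ValueError("degenerate fit: all gene means identical")
    fitted = loess_fit(means, sds, means, span=spec.loess_span, degree=spec.loess_degree)
    keep = (sds - fitted) > 0
    logger.info("select_hvg: kept %d of %d genes", int(keep.sum()), tensor.n_genes)
    return tensor.subset_genes(keep)


def standardize_genes(tensor: TemporalTensor,
                      params: tuple[np.ndarray, np.ndarray] | None = None,
                      return_params: bool = False):
    """Standardize each gene to zero mean / unit variance across all metacells.

    Uses the sample standard deviation (divisor N-1).  Constant genes are
    dropped with a warning rather than producing non-finite values.  Pass
    ``params`` (means, sds from a training tensor) to apply a frozen
    transform to held-out data; with ``return_params`` the fitted
    ``(means, sds)`` are returned alongside the tensor.
    """
    stacked = tensor.stacked_values()
    if params is None:
        means = stacked.mean(axis=0)
        sds = stacked.std(axis=0, ddof=1)
    else:
        means, sds = (np.asarray(p, dtype=float) for p in params)
    keep = sds > 0
    if not np.any(keep):
        raise ValueError("all genes are constant; nothing to standardize")
    if not np.all(keep):
        dropped = [g for g, k in zip(tensor.gene_ids, keep) if not k]
        logger.warning("standardize_genes: dropping %d constant genes (e.g. %r)",
                       len(dropped), dropped[0])
    out = tensor.subset_genes(keep)
    mu, sd = means[keep], sds[keep]
    out = replace(out, values=[(v - mu) / sd for v in out.values])
    if return_params:
        return out, (means, sds)
    return out
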