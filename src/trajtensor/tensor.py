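"""Core data model for multi-sample pseudotemporal expression data.

A :class:`TemporalTensor` holds, for each sample, an irregular grid of
pseudotime points and an expression vector over a shared gene panel at each
point.  Grids may differ across samples, which is the normal situation after
trajectory binning (empty bins are simply absent).  Readers accept either a
dense CSV expression matrix or a MatrixMarket triplet with id sidecars, plus
a cell-level metadata table mapping each cell to its sample and pseudotime.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "TemporalTensor",
    "read_expression",
    "read_metadata",
    "build_tensor",
    "rescale_pseudotime",
    "write_tensor",
    "read_tensor",
]

METADATA_COLUMNS = ("cell_id", "sample_id", "pseudotime")


@dataclass
class ExpressionMatrix:
    """Cell x gene matrix of normalized, log-scale expression values."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class TemporalTensor:
    """Order-3 temporal tensor with sample-specific pseudotime grids.

    Parameters
    ----------
    sample_ids
        Identifiers of the ``m`` samples.
    gene_ids
        Identifiers of the ``n`` genes, shared by all samples.
    times
        Per sample, a sorted vector of pseudotime points within
        ``time_domain``.  Grids may differ across samples; duplicate time
        points are permitted before binning (each observation enters the
        decomposition objective separately).
    values
        Per sample, an ``(len(times_i), n)`` array of expression values.
    time_domain
        Closed interval the pseudotimes live on, canonically ``(0, 1)``.
    time_map
        Optional ``(lo, hi)`` affine map recording the original pseudotime
        range before rescaling to ``[0, 1]``; reused to project new data
        through the same map.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    times: list[np.ndarray]
    values: list[np.ndarray]
    time_domain: tuple[float, float] = (0.0, 1.0)
    time_map: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if not (len(self.times) == len(self.values) == len(self.sample_ids)):
            raise ValueError("times/values must align with sample_ids")
        n = len(self.gene_ids)
        lo, hi = self.time_domain
        clean_t, clean_v = [], []
        for sid, t, v in zip(self.sample_ids, self.times, self.values):
            t = np.asarray(t, dtype=float)
            v = np.asarray(v, dtype=float)
            if v.ndim == 1:
                v = v.reshape(-1, n)
            if v.shape != (t.size, n):
                raise ValueError(f"sample {sid!r}: values shape {v.shape} "
                                 f"does not match {t.size} times x {n} genes")
            if t.size == 0:
                raise ValueError(f"sample {sid!r} has no observations")
            if np.any(np.diff(t) < 0):
                raise ValueError(f"sample {sid!r}: times must be sorted")
            if np.any(t < lo - 1e-12) or np.any(t > hi + 1e-12):
                raise ValueError(f"sample {sid!r}: times outside domain {self.time_domain}")
            if not np.all(np.isfinite(v)) or not np.all(np.isfinite(t)):
                raise ValueError(f"sample {sid!r}: non-finite entries")
            clean_t.append(t)
            clean_v.append(v)
        self.times = clean_t
        self.values = clean_v

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        """Total number of (sample, time) observation slices."""
        return int(sum(t.size for t in self.times))

    @property
    def n_triples(self) -> int:
        """Total number of observed (sample, gene, time) entries."""
        return self.n_obs * self.n_genes

    def total_ss(self) -> float:
        return float(sum(np.sum(v * v) for v in self.values))

    def stacked_values(self) -> np.ndarray:
        """All observation slices concatenated into an (n_obs, n) array."""
        return np.concatenate(self.values, axis=0)

    def copy(self) -> "TemporalTensor":
        return replace(
            self,
            times=[t.copy() for t in self.times],
            values=[v.copy() for v in self.values],
        )

    def subset_samples(self, sample_ids: list[str]) -> "TemporalTensor":
        index = {s: k for k, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        idx = [index[s] for s in sample_ids]
        return replace(
            self,
            sample_ids=list(sample_ids),
            times=[self.times[k].copy() for k in idx],
            values=[self.values[k].copy() for k in idx],
        )

    def subset_genes(self, keep: np.ndarray) -> "TemporalTensor":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            gene_ids=[self.gene_ids[j] for j in keep],
            times=[t.copy() for t in self.times],
            values=[v[:, keep].copy() for v in self.values],
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format view: one row per observed (sample, time, gene) triple."""
        frames = []
        for sid, t, v in zip(self.sample_ids, self.times, self.values):
            df = pd.DataFrame(v, columns=self.gene_ids)
            df.insert(0, "pseudotime", t)
            df.insert(0, "sample_id", sid)
            frames.append(df)
        wide = pd.concat(frames, ignore_index=True)
        return wide.melt(
            id_vars=["sample_id", "pseudotime"],
            var_name="gene_id",
            value_name="value",
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, format: str = "dense_csv") -> ExpressionMatrix:
    """Read a cell x gene expression matrix.

    ``dense_csv``: cells as rows, genes as columns, first column = cell_id.
    ``mtx_triplet``: MatrixMarket file with ``cells.tsv`` / ``genes.tsv``
    sidecars (one id per line) in the same directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dense_csv":
        df = pd.read_csv(path, index_col=0)
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
        return ExpressionMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))
    if format == "mtx_triplet":
        cells_path = path.parent / "cells.tsv"
        genes_path = path.parent / "genes.tsv"
        for p in (cells_path, genes_path):
            if not p.exists():
                raise FileNotFoundError(f"missing id sidecar {p}")
        cell_ids = cells_path.read_text().split()
        gene_ids = genes_path.read_text().split()
        mat = np.asarray(mmread(path).todense(), dtype=float)
        if mat.shape != (len(cell_ids), len(gene_ids)):
            raise ValueError(
                f"matrix {mat.shape} does not match {len(cell_ids)} cells x "
                f"{len(gene_ids)} genes from sidecars"
            )
        return ExpressionMatrix(mat, cell_ids, gene_ids)
    raise ValueError(f"unknown format {format!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the cell metadata CSV (cell_id, sample_id, pseudotime)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = pd.read_csv(path, dtype={"cell_id": str, "sample_id": str})
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    meta = meta.copy()
    meta["cell_id"] = meta["cell_id"].astype(str)
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["pseudotime"] = meta["pseudotime"].astype(float)
    if meta["cell_id"].duplicated().any():
        dup = meta.loc[meta["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell_id in metadata: {dup!r}")
    if not np.all(np.isfinite(meta["pseudotime"])):
        raise ValueError("non-finite pseudotime in metadata")
    return meta


# ---------------------------------------------------------------------------
# Tensor construction
# ---------------------------------------------------------------------------

def build_tensor(expr: ExpressionMatrix, meta: pd.DataFrame,
                 time_domain: tuple[float, float] | None = None) -> TemporalTensor:
    """Assemble the order-3 temporal tensor from cells and their metadata.

    Each cell contributes one observation slice at its pseudotime.  Cells of
    a sample sharing an identical pseudotime are retained as separate
    observations unless their expression vectors are identical too, in which
    case the duplicates collapse to one.
    """
    meta = validate_metadata(meta)
    meta_idx = meta.set_index("cell_id")
    missing = [c for c in expr.cell_ids if c not in meta_idx.index]
    if missing:
        raise ValueError(f"{len(missing)} cells lack metadata (first: {missing[0]!r})")
    sub = meta_idx.loc[expr.cell_ids]
    sample_of = sub["sample_id"].to_numpy()
    ptime = sub["pseudotime"].to_numpy(dtype=float)

    sample_ids = list(pd.unique(sample_of))
    if len(sample_ids) < 2:
        raise ValueError(f"need at least 2 samples, found {len(sample_ids)}")

    if time_domain is None:
        lo = float(min(0.0, ptime.min()))
        hi = float(max(1.0, ptime.max()))
        time_domain = (lo, hi)

    times, values = [], []
    for sid in sample_ids:
        rows = np.flatnonzero(sample_of == sid)
        if rows.size == 0:
            raise ValueError(f"sample {sid!r} has zero cells")
        order = rows[np.argsort(ptime[rows], kind="stable")]
        t = ptime[order]
        v = expr.values[order]
        t, v = _dedup_identical(t, v)
        times.append(t)
        values.append(v)
    return TemporalTensor(sample_ids, list(expr.gene_ids), times, values,
                          time_domain=time_domain)


def _dedup_identical(t: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop observations that duplicate both time and the full value vector."""
    if t.size < 2:
        return t, v
    keep = np.ones(t.size, dtype=bool)
    start = 0
    for k in range(1, t.size + 1):
        if k == t.size or t[k] != t[start]:
            if k - start > 1:
                block = v[start:k]
                seen: list[int] = []
                for r in range(start, k):
                    if any(np.array_equal(v[r], v[s]) for s in seen):
                        keep[r] = False
                    else:
                        seen.append(r)
            start = k
    return t[keep], v[keep]


def rescale_pseudotime(tensor: TemporalTensor,
                       time_map: tuple[float, float] | None = None) -> TemporalTensor:
    """Affinely map pseudotimes onto [0, 1].

    When ``time_map`` is None the map is fit from the tensor's own global
    minimum and maximum and stored on the result, so held-out data can be
    pushed through the training map later (values outside the training range
    clip to [0, 1]).
    """
    if time_map is None:
        lo = min(float(t.min()) for t in tensor.times)
        hi = max(float(t.max()) for t in tensor.times)
        if hi <= lo:
            raise ValueError("all pseudotimes identical; cannot rescale")
    else:
        lo, hi = float(time_map[0]), float(time_map[1])
        if hi <= lo:
            raise ValueError("degenerate time_map")
    new_times = [np.clip((t - lo) / (hi - lo), 0.0, 1.0) for t in tensor.times]
    return replace(
        tensor,
        times=new_times,
        values=[v.copy() for v in tensor.values],
        time_domain=(0.0, 1.0),
        time_map=(lo, hi),
    )


# ---------------------------------------------------------------------------
# Serialization: long CSV + JSON sidecar
# ---------------------------------------------------------------------------

def write_tensor(tensor: TemporalTensor, out_dir: str | Path) -> Path:
    """Write a tensor as long-format CSV plus a JSON sidecar with ids/maps."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    long = tensor.to_long()
    long.to_csv(out_dir / "tensor.csv", index=False, float_format="%.17g")
    sidecar = {
        "sample_ids": tensor.sample_ids,
        "gene_ids": tensor.gene_ids,
        "time_domain": list(tensor.time_domain),
        "time_map": list(tensor.time_map) if tensor.time_map is not None else None,
    }
    (out_dir / "tensor.json").write_text(json.dumps(sidecar, indent=1))
    return out_dir


def read_tensor(in_dir: str | Path) -> TemporalTensor:
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "tensor.json").read_text())
    long = pd.read_csv(in_dir / "tensor.csv",
                       dtype={"sample_id": str, "gene_id": str},
                       float_precision="round_trip")
    gene_ids = [str(g) for g in sidecar["gene_ids"]]
    times, values = [], []
    # Rows are grouped by sample and, within a sample, stacked gene by gene
    # in sidecar order with observations in time order.  Reconstructing from
    # row order (rather than pivoting) keeps duplicate pseudotimes intact.
    for sid in sidecar["sample_ids"]:
        block = long[long["sample_id"] == str(sid)]
        n_obs, rem = divmod(len(block), len(gene_ids))
        if rem or n_obs == 0:
            raise ValueError(f"sample {sid!r}: row count not a multiple of gene count")
        file_genes = block["gene_id"].to_numpy().reshape(len(gene_ids), n_obs)
        if list(file_genes[:, 0]) != gene_ids or not (file_genes.T == file_genes[:, 0]).all():
            raise ValueError(f"sample {sid!r}: gene blocks out of order")
        t_all = block["pseudotime"].to_numpy(dtype=float).reshape(len(gene_ids), n_obs)
        if not np.array_equal(t_all, np.broadcast_to(t_all[0], t_all.shape)):
            raise ValueError(f"sample {sid!r}: inconsistent pseudotimes across genes")
        v = block["value"].to_numpy(dtype=float).reshape(len(gene_ids), n_obs).T
        times.append(t_all[0])
        values.append(v)
    return TemporalTensor(
        [str(s) for s in sidecar["sample_ids"]],
        gene_ids,
        times,
        values,
        time_domain=tuple(sidecar["time_domain"]),
        time_map=tuple(sidecar["time_map"]) if sidecar["time_map"] else None,
    )
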