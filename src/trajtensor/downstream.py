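"""Gene embedding, pseudotime-informed gene modules, and overlap statistics.

The gene embedding matrix stacks the scaled gene loadings,
``B^(l) = lambda^(l) b^(l)``, one column per component; genes whose rows are
correlated combine the same temporal programs with similar weights and are
grouped into modules by average-linkage hierarchical clustering under the
Pearson-correlation distance.  Module behaviour over pseudotime is
summarized by metagenes (per-sample averages of member genes), and agreement
between two fitted models is quantified by the top-L overlap proportion of
their component-wise gene rankings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist

from .decomposition import DecompositionResult
from .tensor import TemporalTensor

logger = logging.getLogger(__name__)

__all__ = [
    "GeneEmbedding",
    "GeneModules",
    "gene_embedding",
    "cluster_gene_modules",
    "metagene_curves",
    "overlap_proportion",
    "rank_genes",
]

SENTINEL_MODULE = 0  # constant embedding rows, excluded from clustering


@dataclass
class GeneEmbedding:
    """n x r matrix with column l equal to lambda^(l) * b^(l)."""

    gene_ids: list[str]
    matrix: np.ndarray


@dataclass
class GeneModules:
    gene_ids: list[str]
    labels: np.ndarray       # 1..k, or SENTINEL_MODULE for degenerate rows
    linkage: np.ndarray | None


def gene_embedding(result: DecompositionResult) -> GeneEmbedding:
    if result.rank == 0:
        raise ValueError("empty decomposition result")
    matrix = result.gene_loadings * result.lambdas[None, :]
    return GeneEmbedding(list(result.gene_ids), matrix)


def cluster_gene_modules(emb: GeneEmbedding, k: int) -> GeneModules:
    """Cut an average-linkage tree under 1 - Pearson correlation into k modules.

    Labels are renumbered by decreasing module size (ties broken by the
    first member's position).  Rows with zero variance across components
    have undefined correlation and receive the sentinel label 0.
    """
    n, r = emb.matrix.shape
    if k > n:
        raise ValueError(f"k={k} exceeds {n} genes")
    if k < 1:
        raise ValueError("k must be >= 1")
    if r < 2:
        raise ValueError("row correlations need at least 2 components")
    variable = emb.matrix.std(axis=1) > 0
    if not np.all(variable):
        logger.warning("cluster_gene_modules: %d constant embedding rows assigned "
                       "to sentinel module 0", int((~variable).sum()))
    sub = emb.matrix[variable]
    labels = np.full(n, SENTINEL_MODULE, dtype=int)
    if sub.shape[0] == 0:
        return GeneModules(list(emb.gene_ids), labels, None)
    k_eff = min(k, sub.shape[0])
    if sub.shape[0] == 1:
        raw = np.array([1])
        link = None
    else:
        dist = pdist(sub, metric="correlation")
        dist = np.clip(dist, 0.0, None)  # guard tiny negative rounding
        link = average(dist)
        raw = fcluster(link, t=k_eff, criterion="maxclust")
    labels[np.flatnonzero(variable)] = _renumber_by_size(raw)
    return GeneModules(list(emb.gene_ids), labels, link)


def _renumber_by_size(raw: np.ndarray) -> np.ndarray:
    ids, counts = np.unique(raw, return_counts=True)
    first_pos = {c: int(np.argmax(raw == c)) for c in ids}
    order = sorted(ids, key=lambda c: (-counts[list(ids).index(c)], first_pos[c]))
    remap = {c: i + 1 for i, c in enumerate(order)}
    return np.array([remap[c] for c in raw])


def metagene_curves(tensor: TemporalTensor, modules: GeneModules) -> dict:
    """Per (sample, module) mean expression trajectories.

    Returns a mapping ``(sample_id, module_label) -> (times, values)`` where
    the values are the unweighted mean over the module's member genes.
    """
    gene_pos = {g: j for j, g in enumerate(tensor.gene_ids)}
    missing = [g for g in modules.gene_ids if g not in gene_pos]
    if missing:
        raise KeyError(f"module genes absent from tensor: {missing[:3]}")
    out = {}
    for label in np.unique(modules.labels):
        if label == SENTINEL_MODULE:
            continue
        member_cols = [gene_pos[g] for g, lab in zip(modules.gene_ids, modules.labels)
                       if lab == label]
        if not member_cols:
            raise ValueError(f"module {label} is empty")
        for sid, t, v in zip(tensor.sample_ids, tensor.times, tensor.values):
            out[(sid, int(label))] = (t.copy(), v[:, member_cols].mean(axis=1))
    return out


def rank_genes(result: DecompositionResult, l: int) -> list[str]:
    """Gene ids ordered by |b_j^(l)| descending; ties broken lexicographically."""
    if not 1 <= l <= result.rank:
        raise ValueError(f"component index {l} outside 1..{result.rank}")
    b = result.components[l - 1].gene_loading
    order = sorted(range(len(b)), key=lambda j: (-abs(b[j]), result.gene_ids[j]))
    return [result.gene_ids[j] for j in order]


def overlap_proportion(rank_a: list[str], rank_b: list[str], L):
    """Top-L overlap proportion |A ∩ B| / L between two gene rankings."""
    scalar = np.isscalar(L)
    Ls = [int(L)] if scalar else [int(x) for x in L]
    for name, lst in (("first", rank_a), ("second", rank_b)):
        if len(set(lst)) != len(lst):
            raise ValueError(f"duplicate entries in the {name} list")
    out = []
    for l in Ls:
        if l > len(rank_a) or l > len(rank_b):
            raise ValueError(f"L={l} exceeds a list length")
        if l < 1:
            raise ValueError("L must be positive")
        out.append(len(set(rank_a[:l]) & set(rank_b[:l])) / l)
    return out[0] if scalar else np.array(out)
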