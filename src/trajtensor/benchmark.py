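"""Simulation, permutation nulls, baseline, and phenotype-prediction benchmark.

The generator emulates a multi-sample pseudotemporal experiment: genes carry
smooth mean curves over pseudotime (an increasing logistic trend, its
decreasing mirror, and a single Gaussian peak), samples fall into groups,
and group structure is induced by permuting selected gene sets' values
within each sample of the affected groups — which destroys the temporal
trend while preserving every per-sample marginal distribution, so
aggregate (pseudobulk) summaries are blind to it by construction.  Additive
Gaussian noise is applied last.

Three permutation null scenarios break the sample/trajectory linkage in
different ways; a Pseudobulk-PCA baseline and a stratified cross-validated
AUC evaluator (with strictly out-of-fold projection of sample loadings)
complete the benchmarking machinery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .decomposition import FitConfig, decompose, project_samples
from .kernel import PenaltyConfig
from .preprocess import BinningSpec, bin_cells, standardize_genes
from .tensor import ExpressionMatrix, TemporalTensor, build_tensor, rescale_pseudotime

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_multisample",
    "apply_null",
    "pseudobulk_pca",
    "cv_predict_auc",
    "wilcoxon_loading_test",
    "make_trajectory_loader",
    "make_pseudobulk_loader",
    "NULL_SCHEMES",
]

NULL_SCHEMES = ("all_sample_expression", "all_sample_pseudotime",
                "sample_specific_pseudotime")


def _increasing(t):
    return 1.0 / (1.0 + np.exp(-10.0 * (t - 0.5)))


def _decreasing(t):
    return 1.0 / (1.0 + np.exp(10.0 * (t - 0.5)))


def _peak(t):
    return np.exp(-((t - 0.5) ** 2) / (2.0 * 0.15 ** 2))


DEFAULT_CURVES = {"increasing": _increasing, "decreasing": _decreasing, "peak": _peak}


@dataclass
class SimulationConfig:
    """Study conditions of the simulated multi-sample experiment.

    Defaults follow the reference design: 161 samples in three groups,
    10 increasing + 10 decreasing + 5 single-peak genes, 300 cells per
    sample, additive Gaussian noise with sd 0.1 (raised to 3 when stressing
    phenotype prediction).  ``curves`` may override the parametric trend
    shapes with user-fitted functions of pseudotime.
    """

    n_samples: int = 161
    n_groups: int = 3
    genes_increasing: int = 10
    genes_decreasing: int = 10
    genes_peak: int = 5
    cells_per_sample: int = 300
    noise_sd: float = 0.1
    seed: int | None = None
    curves: dict = field(default_factory=lambda: dict(DEFAULT_CURVES))

    def __post_init__(self) -> None:
        counts = (self.n_samples, self.n_groups, self.genes_increasing,
                  self.genes_decreasing, self.genes_peak, self.cells_per_sample)
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class SimulatedDataset:
    """Cell-level simulated data plus generation truth."""

    expression: ExpressionMatrix
    metadata: pd.DataFrame
    group_labels: pd.Series                  # sample_id -> group label
    gene_trends: pd.Series                   # gene_id -> trend name
    permuted: pd.DataFrame                   # sample x gene boolean flags
    config: SimulationConfig
    null_scheme: str | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.group_labels.index)

    def tensor(self) -> TemporalTensor:
        return build_tensor(self.expression, self.metadata)

    def subset_samples(self, sample_ids: list[str]) -> "SimulatedDataset":
        keep = self.metadata["sample_id"].isin(sample_ids).to_numpy()
        cells = np.flatnonzero(keep)
        expr = ExpressionMatrix(self.expression.values[cells],
                                [self.expression.cell_ids[c] for c in cells],
                                list(self.expression.gene_ids))
        return replace(self,
                       expression=expr,
                       metadata=self.metadata.loc[keep].reset_index(drop=True),
                       group_labels=self.group_labels.loc[sample_ids],
                       permuted=self.permuted.loc[sample_ids])


def simulate_multisample(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate a multi-sample pseudotemporal dataset with group structure.

    Cells receive iid Uniform(0, 1) pseudotimes; each gene's noiseless value
    is its trend curve at the cell's pseudotime.  Group effects: decreasing
    genes are permuted within each sample of group 2; single-peak genes are
    permuted within each sample of groups 2 and 3 (permutation scrambles the
    value-to-time assignment inside a sample).  Gaussian noise is added
    after permutation.  Fully reproducible from ``config.seed``.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    m, cells = config.n_samples, config.cells_per_sample
    sample_ids = [f"s{i + 1:03d}" for i in range(m)]
    gene_ids = ([f"inc{j + 1}" for j in range(config.genes_increasing)]
                + [f"dec{j + 1}" for j in range(config.genes_decreasing)]
                + [f"peak{j + 1}" for j in range(config.genes_peak)])
    trends = (["increasing"] * config.genes_increasing
              + ["decreasing"] * config.genes_decreasing
              + ["peak"] * config.genes_peak)

    # random near-equal split of samples into groups
    shuffled = rng.permutation(m)
    group_of = np.empty(m, dtype=int)
    for g, block in enumerate(np.array_split(shuffled, config.n_groups)):
        group_of[block] = g + 1

    permuted_in_group = {
        "increasing": set(),
        "decreasing": {2},
        "peak": {2, 3},
    }

    n_genes = len(gene_ids)
    values = np.empty((m * cells, n_genes))
    ptimes = np.empty(m * cells)
    cell_ids, cell_samples = [], []
    flags = np.zeros((m, n_genes), dtype=bool)
    for i, sid in enumerate(sample_ids):
        rows = slice(i * cells, (i + 1) * cells)
        t = rng.uniform(0.0, 1.0, size=cells)
        ptimes[rows] = t
        cell_ids.extend(f"{sid}_c{c + 1}" for c in range(cells))
        cell_samples.extend([sid] * cells)
        for j, trend in enumerate(trends):
            col = config.curves[trend](t)
            if group_of[i] in permuted_in_group[trend]:
                col = rng.permutation(col)
                flags[i, j] = True
            values[rows, j] = col
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=values.shape)

    expr = ExpressionMatrix(values, cell_ids, gene_ids)
    meta = pd.DataFrame({"cell_id": cell_ids, "sample_id": cell_samples,
                         "pseudotime": ptimes})
    return SimulatedDataset(
        expression=expr,
        metadata=meta,
        group_labels=pd.Series([f"group{g}" for g in group_of],
                               index=sample_ids, name="group"),
        gene_trends=pd.Series(trends, index=gene_ids, name="trend"),
        permuted=pd.DataFrame(flags, index=sample_ids, columns=gene_ids),
        config=config,
    )


def apply_null(data: SimulatedDataset, scheme: str,
               seed: int | None = None) -> SimulatedDataset:
    """Apply one of the three permutation null schemes.

    ``all_sample_expression``: each gene's values permuted across all cells
    of all samples.  ``all_sample_pseudotime``: pseudotimes permuted across
    all cells, keeping cell-sample membership.  ``sample_specific_pseudotime``:
    pseudotimes permuted within each sample.
    """
    if scheme not in NULL_SCHEMES:
        raise ValueError(f"unknown null scheme {scheme!r}; choose from {NULL_SCHEMES}")
    rng = np.random.default_rng(seed)
    meta = data.metadata.copy()
    values = data.expression.values.copy()
    if scheme == "all_sample_expression":
        for j in range(values.shape[1]):
            values[:, j] = rng.permutation(values[:, j])
    elif scheme == "all_sample_pseudotime":
        meta["pseudotime"] = rng.permutation(meta["pseudotime"].to_numpy())
    else:
        pt = meta["pseudotime"].to_numpy().copy()
        for sid in data.sample_ids:
            rows = np.flatnonzero((meta["sample_id"] == sid).to_numpy())
            pt[rows] = pt[rng.permutation(rows)]
        meta["pseudotime"] = pt
    expr = ExpressionMatrix(values, list(data.expression.cell_ids),
                            list(data.expression.gene_ids))
    return replace(data, expression=expr, metadata=meta, null_scheme=scheme)


# ---------------------------------------------------------------------------
# Pseudobulk-PCA baseline
# ---------------------------------------------------------------------------

def _pseudobulk(expr: ExpressionMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mean expression over cells (sample x gene)."""
    order = {c: k for k, c in enumerate(expr.cell_ids)}
    rows = meta["cell_id"].map(order)
    df = pd.DataFrame(expr.values[rows.to_numpy()], columns=expr.gene_ids)
    df["sample_id"] = meta["sample_id"].to_numpy()
    return df.groupby("sample_id", sort=False).mean()


def pseudobulk_pca(expr: ExpressionMatrix, meta: pd.DataFrame,
                   n_pc: int) -> np.ndarray:
    """Sample-level PCA of per-sample mean expression.

    Cells are averaged per sample, genes are z-scored across samples
    (sample sd, divisor N-1; constant genes dropped), and the top ``n_pc``
    principal-component scores are returned with a deterministic sign
    (the largest-magnitude gene loading of each component is positive).
    """
    pb = _pseudobulk(expr, meta)
    m = pb.shape[0]
    if m < 2:
        raise ValueError("need at least 2 samples")
    mu = pb.mean(axis=0)
    sd = pb.std(axis=0, ddof=1)
    keep = sd > 0
    z = ((pb.loc[:, keep] - mu[keep]) / sd[keep]).to_numpy()
    if n_pc > min(z.shape):
        raise ValueError(f"n_pc={n_pc} exceeds min(m, n)={min(z.shape)}")
    pca = PCA(n_components=n_pc, svd_solver="full")
    scores = pca.fit_transform(z)
    for l in range(n_pc):
        load = pca.components_[l]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, l] = -scores[:, l]
    return scores


# ---------------------------------------------------------------------------
# Loading producers for the CV benchmark
# ---------------------------------------------------------------------------

def make_trajectory_loader(rank: int = 3, n_bins: int = 50,
                           penalty: PenaltyConfig | None = None,
                           fit_seed: int = 0):
    """Loader running the full pipeline: bin, standardize, decompose, project.

    Returns a function mapping (train dataset, test dataset) to
    (train loadings, test loadings); all fitting — the pseudotime rescale
    map, gene standardization, and the decomposition itself — uses training
    samples only, and test samples are embedded by out-of-sample projection.
    """
    penalty = penalty or PenaltyConfig()

    def loader(train: SimulatedDataset, test: SimulatedDataset):
        tt_train = rescale_pseudotime(train.tensor())
        tt_test = rescale_pseudotime(test.tensor(), time_map=tt_train.time_map)
        spec = BinningSpec(n_bins=n_bins)
        tt_train = bin_cells(tt_train, spec)
        tt_test = bin_cells(tt_test, spec)
        tt_train, params = standardize_genes(tt_train, return_params=True)
        tt_test = standardize_genes(tt_test, params=params)
        fit = decompose(tt_train, FitConfig(rank=rank, penalty=penalty,
                                            seed=fit_seed))
        train_load = fit.sample_loadings * fit.lambdas[None, :]
        test_load = project_samples(tt_test, fit)
        return train_load, test_load

    return loader


def make_pseudobulk_loader(n_pc: int = 3):
    """Loader computing Pseudobulk-PCA scores on train and projecting test."""

    def loader(train: SimulatedDataset, test: SimulatedDataset):
        pb_train = _pseudobulk(train.expression, train.metadata)
        pb_test = _pseudobulk(test.expression, test.metadata)
        mu = pb_train.mean(axis=0)
        sd = pb_train.std(axis=0, ddof=1)
        keep = sd > 0
        z_train = ((pb_train.loc[:, keep] - mu[keep]) / sd[keep]).to_numpy()
        z_test = ((pb_test.loc[:, keep] - mu[keep]) / sd[keep]).to_numpy()
        pca = PCA(n_components=min(n_pc, min(z_train.shape)), svd_solver="full")
        return pca.fit_transform(z_train), pca.transform(z_test)

    return loader


# ---------------------------------------------------------------------------
# Cross-validated phenotype prediction
# ---------------------------------------------------------------------------

def cv_predict_auc(data: SimulatedDataset, labels, loading_fn,
                   folds: int = 10, classifier: str = "logistic",
                   seed: int | None = None) -> dict:
    """Stratified K-fold AUC of phenotype prediction from sample loadings.

    Within each fold, ``loading_fn`` fits on training samples only and
    returns loadings for both partitions (no leakage); features are
    standardized with training-fold statistics before classification.
    Binary problems use the rank-statistic AUC; three or more classes use
    the Hand-Till pairwise-average multiclass AUC.  Returns per-fold AUCs,
    their mean, and the AUC pooled over out-of-fold predictions.
    """
    labels = pd.Series(labels)
    sample_ids = np.asarray(labels.index)
    y = labels.to_numpy()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    min_count = min(np.sum(y == c) for c in classes)
    if min_count < folds:
        warnings.warn(f"reducing folds from {folds} to {min_count} "
                      "(smallest class size)")
        folds = int(min_count)
    if classifier == "logistic":
        def new_clf():
            return LogisticRegression(max_iter=2000)
    elif classifier == "random_forest":
        def new_clf():
            return RandomForestClassifier(n_estimators=500, random_state=seed)
    else:
        raise ValueError(f"unknown classifier {classifier!r}")

    multiclass = classes.size > 2
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold = []
    pooled_proba = np.empty((len(y), classes.size))
    for train_idx, test_idx in skf.split(sample_ids, y):
        train = data.subset_samples(list(sample_ids[train_idx]))
        test = data.subset_samples(list(sample_ids[test_idx]))
        load_train, load_test = loading_fn(train, test)
        scaler = StandardScaler().fit(load_train)
        clf = new_clf().fit(scaler.transform(load_train), y[train_idx])
        proba = clf.predict_proba(scaler.transform(load_test))
        # align columns to the global class order
        col = {c: k for k, c in enumerate(clf.classes_)}
        proba = proba[:, [col[c] for c in classes]]
        pooled_proba[test_idx] = proba
        per_fold.append(_auc(y[test_idx], proba, classes, multiclass))
    pooled = _auc(y, pooled_proba, classes, multiclass)
    return {"per_fold": per_fold, "mean": float(np.mean(per_fold)),
            "pooled": float(pooled), "folds": folds, "classifier": classifier}


def _auc(y_true, proba, classes, multiclass: bool) -> float:
    if multiclass:
        return float(roc_auc_score(y_true, proba, multi_class="ovo",
                                   average="macro", labels=list(classes)))
    return float(roc_auc_score(y_true == classes[1], proba[:, 1]))


def wilcoxon_loading_test(loadings, labels) -> float:
    """Two-sided Wilcoxon rank-sum p-value for a binary sample grouping.

    Normal approximation with tie correction (no continuity correction, so
    identical groups give p = 1 exactly).
    """
    loadings = np.asarray(loadings, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 groups, found {classes.size}")
    x = loadings[labels == classes[0]]
    y = loadings[labels == classes[1]]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             use_continuity=False, method="asymptotic")
    return float(res.pvalue)
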