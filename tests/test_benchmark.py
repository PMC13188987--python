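import numpy as np
import pandas as pd
import pytest

from trajtensor import (
    SimulationConfig,
    apply_null,
    cv_predict_auc,
    pseudobulk_pca,
    simulate_multisample,
    wilcoxon_loading_test,
)
from trajtensor.benchmark import _pseudobulk


@pytest.fixture(scope="module")
def small_sim():
    return simulate_multisample(SimulationConfig(
        n_samples=12, cells_per_sample=50, noise_sd=0.5, seed=0))


class TestSimulateMultisample:
    def test_default_dimensions(self):
        data = simulate_multisample(SimulationConfig(
            n_samples=30, cells_per_sample=40, seed=1))
        assert len(data.sample_ids) == 30
        assert data.expression.n_genes == 25
        assert data.expression.n_cells == 30 * 40
        assert data.group_labels.value_counts().sum() == 30

    def test_noiseless_group1_on_curve(self):
        data = simulate_multisample(SimulationConfig(
            n_samples=6, cells_per_sample=30, noise_sd=0.0, seed=2))
        sid = data.group_labels[data.group_labels == "group1"].index[0]
        rows = data.metadata["sample_id"] == sid
        t = data.metadata.loc[rows, "pseudotime"].to_numpy()
        j = list(data.expression.gene_ids).index("inc1")
        vals = data.expression.values[rows.to_numpy(), j]
        assert np.allclose(vals, 1 / (1 + np.exp(-10 * (t - 0.5))))

    def test_same_seed_identical(self):
        cfg = dict(n_samples=5, cells_per_sample=20, seed=9)
        d1 = simulate_multisample(SimulationConfig(**cfg))
        d2 = simulate_multisample(SimulationConfig(**cfg))
        assert np.array_equal(d1.expression.values, d2.expression.values)
        assert d1.metadata.equals(d2.metadata)
        assert d1.group_labels.equals(d2.group_labels)

    def test_permutation_flags_follow_scheme(self, small_sim):
        flags = small_sim.permuted
        groups = small_sim.group_labels
        for sid in small_sim.sample_ids:
            g = groups[sid]
            inc = flags.loc[sid, [c for c in flags.columns if c.startswith("inc")]]
            dec = flags.loc[sid, [c for c in flags.columns if c.startswith("dec")]]
            peak = flags.loc[sid, [c for c in flags.columns if c.startswith("peak")]]
            assert not inc.any()
            assert dec.all() == (g == "group2")
            assert peak.all() == (g in ("group2", "group3"))

    def test_permutation_preserves_per_sample_marginals(self):
        base = simulate_multisample(SimulationConfig(
            n_samples=9, cells_per_sample=40, noise_sd=0.0, seed=4))
        # a permuted (sample, gene) pair holds the same value multiset as the
        # curve evaluated at that sample's pseudotimes
        sid = base.group_labels[base.group_labels == "group2"].index[0]
        rows = (base.metadata["sample_id"] == sid).to_numpy()
        t = base.metadata.loc[rows, "pseudotime"].to_numpy()
        j = list(base.expression.gene_ids).index("dec1")
        vals = base.expression.values[rows, j]
        expected = 1 / (1 + np.exp(10 * (t - 0.5)))
        assert sorted(vals) == pytest.approx(sorted(expected))
        assert not np.allclose(vals, expected)   # order destroyed


class TestApplyNull:
    def test_sample_specific_pseudotime_preserves_values(self, small_sim):
        null = apply_null(small_sim, "sample_specific_pseudotime", seed=1)
        assert np.array_equal(null.expression.values, small_sim.expression.values)
        for sid in small_sim.sample_ids:
            rows = (small_sim.metadata["sample_id"] == sid).to_numpy()
            assert sorted(small_sim.metadata.loc[rows, "pseudotime"]) == \
                pytest.approx(sorted(null.metadata.loc[rows, "pseudotime"]))

    def test_all_sample_pseudotime_preserves_global_multiset(self, small_sim):
        null = apply_null(small_sim, "all_sample_pseudotime", seed=1)
        assert sorted(small_sim.metadata["pseudotime"]) == pytest.approx(
            sorted(null.metadata["pseudotime"]))
        assert null.metadata["sample_id"].equals(small_sim.metadata["sample_id"])

    def test_all_sample_expression_preserves_gene_multisets(self, small_sim):
        null = apply_null(small_sim, "all_sample_expression", seed=1)
        for j in range(small_sim.expression.n_genes):
            assert sorted(null.expression.values[:, j]) == pytest.approx(
                sorted(small_sim.expression.values[:, j]))

    def test_pseudotime_nulls_keep_per_sample_gene_means(self, small_sim):
        pb = _pseudobulk(small_sim.expression, small_sim.metadata)
        for scheme in ("all_sample_pseudotime", "sample_specific_pseudotime"):
            null = apply_null(small_sim, scheme, seed=2)
            pb_null = _pseudobulk(null.expression, null.metadata)
            assert np.allclose(pb.to_numpy(), pb_null.to_numpy())

    def test_unknown_scheme_rejected(self, small_sim):
        with pytest.raises(ValueError, match="unknown null scheme"):
            apply_null(small_sim, "bogus")


class TestPseudobulkPCA:
    def test_two_sample_hand_computation(self):
        from trajtensor import ExpressionMatrix
        expr = ExpressionMatrix(np.array([[0.0], [2.0], [4.0], [6.0]]),
                                ["c1", "c2", "c3", "c4"], ["g"])
        meta = pd.DataFrame({"cell_id": ["c1", "c2", "c3", "c4"],
                             "sample_id": ["a", "a", "b", "b"],
                             "pseudotime": [0.1, 0.2, 0.3, 0.4]})
        # pseudobulk (1, 5); z-scores with divisor N-1 -> (-1/sqrt 2, +1/sqrt 2)
        scores = pseudobulk_pca(expr, meta, n_pc=1)
        assert scores[:, 0] == pytest.approx([-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_invariant_to_within_sample_pseudotime_permutation(self, small_sim):
        null = apply_null(small_sim, "sample_specific_pseudotime", seed=3)
        s1 = pseudobulk_pca(small_sim.expression, small_sim.metadata, 3)
        s2 = pseudobulk_pca(null.expression, null.metadata, 3)
        assert np.allclose(s1, s2, atol=1e-10)

    def test_full_rank_exact_reconstruction(self):
        rng = np.random.default_rng(5)
        from trajtensor import ExpressionMatrix
        expr = ExpressionMatrix(rng.normal(size=(12, 4)),
                                [f"c{i}" for i in range(12)],
                                [f"g{j}" for j in range(4)])
        meta = pd.DataFrame({"cell_id": expr.cell_ids,
                             "sample_id": [f"s{i // 2}" for i in range(12)],
                             "pseudotime": rng.uniform(size=12)})
        scores = pseudobulk_pca(expr, meta, n_pc=4)
        pb = _pseudobulk(expr, meta)
        z = (pb - pb.mean()) / pb.std(ddof=1)
        # full PCA preserves all variance
        assert np.sum(scores ** 2) == pytest.approx(
            np.sum((z - z.mean()).to_numpy() ** 2))

    def test_n_pc_too_large_rejected(self, small_sim):
        with pytest.raises(ValueError, match="n_pc"):
            pseudobulk_pca(small_sim.expression, small_sim.metadata, n_pc=999)


class TestCvPredictAuc:
    def test_perfectly_separating_loadings(self, small_sim):
        labels = pd.Series(["x"] * 6 + ["y"] * 6, index=small_sim.sample_ids)
        rank = {s: i for i, s in enumerate(small_sim.sample_ids)}

        def loader(train, test):
            f = lambda d: np.array([[rank[s]] for s in d.sample_ids], dtype=float)
            return f(train), f(test)

        res = cv_predict_auc(small_sim, labels, loader, folds=3, seed=0)
        assert res["pooled"] == 1.0

    def test_permuted_labels_near_half(self, small_sim):
        rng = np.random.default_rng(0)
        rank = {s: i for i, s in enumerate(small_sim.sample_ids)}

        def loader(train, test):
            f = lambda d: np.array([[rank[s]] for s in d.sample_ids], dtype=float)
            return f(train), f(test)

        aucs = []
        for rep in range(20):
            labels = pd.Series(rng.permutation(["x"] * 6 + ["y"] * 6),
                               index=small_sim.sample_ids)
            aucs.append(cv_predict_auc(small_sim, labels, loader, folds=3,
                                       seed=rep)["pooled"])
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_folds_reduced_with_warning(self, small_sim):
        labels = pd.Series(["x"] * 3 + ["y"] * 9, index=small_sim.sample_ids)

        def loader(train, test):
            return (np.ones((len(train.sample_ids), 1)),
                    np.ones((len(test.sample_ids), 1)))

        with pytest.warns(UserWarning, match="reducing folds"):
            res = cv_predict_auc(small_sim, labels, loader, folds=5, seed=0)
        assert res["folds"] == 3

    def test_single_class_rejected(self, small_sim):
        labels = pd.Series(["x"] * 12, index=small_sim.sample_ids)
        with pytest.raises(ValueError, match="classes"):
            cv_predict_auc(small_sim, labels, lambda a, b: (None, None))


class TestWilcoxonLoadingTest:
    def test_identical_groups_p_one(self):
        load = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        assert wilcoxon_loading_test(load, labels) == pytest.approx(1.0)

    def test_fully_separated_small_groups(self):
        load = np.array([1.0, 2.0, 3.0, 101.0, 102.0, 103.0])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        p = wilcoxon_loading_test(load, labels)
        assert p < 0.05
        assert p <= 0.11   # exact two-sided enumeration gives 0.1

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        load = rng.normal(size=14)
        labels = np.array(["a"] * 7 + ["b"] * 7)
        assert wilcoxon_loading_test(load, labels) == pytest.approx(
            wilcoxon_loading_test(load + 123.4, labels))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_loading_test(np.ones(3), np.array(["a", "a", "a"]))
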