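"""Network construction, TOM, dynamic cut, eigengenes, and trait association."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import modulesig as ms
from modulesig.network import (
    UNASSIGNED,
    ExpressionDataset,
    NetworkParams,
    _pearson_with_p,
)


def make_dataset(values, traits=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if traits is None:
        traits = pd.DataFrame(
            {"carrier": np.tile([0.0, 1.0], n_samples)[:n_samples]},
            index=[f"s{i}" for i in range(n_samples)],
        )
    return ExpressionDataset(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        sample_ids=[f"s{i}" for i in range(n_samples)],
        values=values,
        traits=traits,
    )


class TestCorrelationMatrix:
    def test_duplicate_and_negated_genes(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=6)
        data = make_dataset([base, base.copy(), -base])
        corr = ms.correlation_matrix(data)
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)
        assert np.allclose(corr, corr.T, atol=1e-12)
        assert np.allclose(np.diag(corr), 1.0)

    def test_matches_textbook_pearson_on_hand_matrix(self):
        values = np.array(
            [[1.0, 2.0, 4.0, 3.0], [2.0, 1.0, 5.0, 2.0], [9.0, 3.0, 1.0, 4.0]]
        )
        corr = ms.correlation_matrix(make_dataset(values))
        for i in range(3):
            for j in range(3):
                x, y = values[i], values[j]
                num = np.sum((x - x.mean()) * (y - y.mean()))
                den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
                assert corr[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            ms.correlation_matrix(make_dataset(np.array([[1.0, 2.0], [2.0, 1.0]])))


class TestSoftAdjacency:
    def test_power_one_is_absolute_correlation(self):
        corr = np.array([[1.0, -0.4], [-0.4, 1.0]])
        adj = ms.soft_adjacency(corr, NetworkParams(soft_power=1))
        assert adj[0, 1] == pytest.approx(0.4)
        assert adj[0, 0] == 0.0

    def test_power_nine_direct_value_and_monotonicity(self):
        corr = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.8], [0.3, 0.8, 1.0]])
        adj = ms.soft_adjacency(corr, NetworkParams(soft_power=9))
        assert adj[0, 1] == pytest.approx(0.5**9)
        # |corr| ordering preserved
        flat = np.abs(corr)[np.triu_indices(3, 1)]
        order = np.argsort(flat)
        assert np.all(np.diff(adj[np.triu_indices(3, 1)][order]) >= 0)

    def test_nonpositive_power_rejected(self):
        with pytest.raises(ValueError):
            NetworkParams(soft_power=0)


class TestScaleFreeFit:
    def test_planted_power_law_scores_high(self):
        # rank-one adjacency with power-law weights w ~ u^(-1/(gamma-1)): the
        # connectivity k_i ~ w_i follows an (truncated) exact power law
        n, gamma = 500, 2.5
        u = 0.05 + 0.95 * (np.arange(n) + 0.5) / n
        w = u ** (-1.0 / (gamma - 1.0))
        w = w / w.max()
        adj = np.outer(w, w) * 0.9
        np.fill_diagonal(adj, 0.0)
        r2 = ms.scale_free_fit(adj)
        assert r2 >= 0.95

    def test_constant_connectivity_returns_zero_with_warning(self):
        adj = np.full((12, 12), 0.5)
        np.fill_diagonal(adj, 0.0)
        with pytest.warns(UserWarning, match="constant connectivity"):
            assert ms.scale_free_fit(adj) == 0.0

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        adj = rng.random((30, 30))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0)
        assert ms.scale_free_fit(adj) == ms.scale_free_fit(adj)


class TestTomSimilarity:
    def test_two_node_full_edge(self):
        adj = np.array([[0.0, 1.0], [1.0, 0.0]])
        tom = ms.tom_similarity(adj)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_isolated_gene_has_zero_overlap(self):
        adj = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.7], [0.0, 0.7, 0.0]])
        tom = ms.tom_similarity(adj)
        assert tom[0, 1] == 0.0
        assert tom[0, 2] == 0.0

    def test_triangle_hand_value(self):
        adj = np.full((3, 3), 0.5)
        np.fill_diagonal(adj, 0.0)
        tom = ms.tom_similarity(adj)
        # (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert tom[0, 1] == pytest.approx(0.5)

    def test_range_symmetry_unit_diagonal(self):
        rng = np.random.default_rng(3)
        adj = rng.random((20, 20)) * 0.8
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0.0)
        tom = ms.tom_similarity(adj)
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)


def block_tom(sizes, within, between):
    n = sum(sizes)
    tom = np.full((n, n), between)
    start = 0
    for s in sizes:
        tom[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(tom, 1.0)
    return tom


class TestClusterAndCut:
    def test_two_planted_blocks_recovered_exactly(self):
        tom = block_tom([20, 20], within=0.9, between=0.05)
        params = NetworkParams(min_module_size=15, cut_height=0.5)
        modules = ms.cluster_and_cut(tom, params)
        sizes = sorted(modules.sizes().values())
        assert sizes == [20, 20]
        labels = [modules.assignment[f"g{i}"] for i in range(40)]
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_undersized_block_stays_unassigned(self):
        tom = block_tom([10, 20], within=0.9, between=0.05)
        params = NetworkParams(min_module_size=15, cut_height=0.5)
        modules = ms.cluster_and_cut(tom, params)
        small_block = [modules.assignment[f"g{i}"] for i in range(10)]
        assert set(small_block) == {UNASSIGNED}

    def test_deep_split_never_reduces_module_count(self):
        # nested structure: two tight sub-blocks inside one loose block
        tom = block_tom([20, 20], within=0.95, between=0.55)
        tom[tom == 0.55] = 0.55  # loose but below-cut linkage between sub-blocks
        for ds0, ds2 in [(0, 2)]:
            p0 = NetworkParams(min_module_size=15, cut_height=0.9, deep_split=ds0)
            p2 = NetworkParams(min_module_size=15, cut_height=0.9, deep_split=ds2)
            n0 = len(ms.cluster_and_cut(tom, p0).labels)
            n2 = len(ms.cluster_and_cut(tom, p2).labels)
            assert n0 <= n2

    def test_min_module_size_above_gene_count_warns(self):
        tom = block_tom([5], within=0.9, between=0.1)
        with pytest.warns(UserWarning, match="unassigned"):
            modules = ms.cluster_and_cut(tom, NetworkParams(min_module_size=10))
        assert modules.labels == []


class TestModuleEigengene:
    def test_rank_one_module_recovers_factor(self):
        rng = np.random.default_rng(4)
        factor = rng.normal(size=30)
        values = np.outer(rng.uniform(0.5, 1.5, size=6), factor)
        data = make_dataset(values)
        eig = ms.module_eigengene(data, data.gene_ids)
        assert abs(np.corrcoef(eig, factor)[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_orientation_follows_module_mean(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(5, 20))
        data = make_dataset(values)
        data_neg = make_dataset(-values)
        e1 = ms.module_eigengene(data, data.gene_ids)
        e2 = ms.module_eigengene(data_neg, data_neg.gene_ids)
        z1 = stats.zscore(values, axis=1).mean(axis=0)
        z2 = stats.zscore(-values, axis=1).mean(axis=0)
        assert np.corrcoef(e1, z1)[0, 1] >= 0
        assert np.corrcoef(e2, z2)[0, 1] >= 0

    def test_maximizes_explained_variance_against_random_projections(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(5, 25))
        data = make_dataset(values)
        eig = ms.module_eigengene(data, data.gene_ids)
        z = stats.zscore(values, axis=1)
        best = np.linalg.norm(z @ eig) ** 2
        for _ in range(200):
            v = rng.normal(size=25)
            v /= np.linalg.norm(v)
            assert np.linalg.norm(z @ v) ** 2 <= best + 1e-9

    def test_constant_rows_rejected(self):
        data = make_dataset(np.array([[1.0, 1.0, 1.0, 2.0], [3.0, 1.0, 2.0, 2.0]]))
        # first gene row was dropped as zero-variance? no - it varies; build truly constant
        values = np.vstack([np.ones(4), [3.0, 1.0, 2.0, 2.0]])
        with pytest.raises(ValueError):
            ExpressionDataset(
                gene_ids=["a", "b"],
                sample_ids=[f"s{i}" for i in range(4)],
                values=values,
                traits=data.traits,
            ).gene_ids.index("a")  # zero-variance row dropped -> "a" missing


class TestMergeModules:
    def _split_module_data(self, seed=7):
        rng = np.random.default_rng(seed)
        factor = rng.normal(size=30)
        values = np.vstack(
            [factor + 0.1 * rng.normal(size=30) for _ in range(10)]
            + [rng.normal(size=30) for _ in range(10)]
        )
        data = make_dataset(values)
        # artificially split the planted module into two halves
        assignment = {}
        for i in range(5):
            assignment[f"g{i}"] = "M1"
        for i in range(5, 10):
            assignment[f"g{i}"] = "M2"
        for i in range(10, 15):
            assignment[f"g{i}"] = "M3"
        for i in range(15, 20):
            assignment[f"g{i}"] = UNASSIGNED
        return data, ms.ModuleSet(assignment)

    def test_tiny_threshold_is_identity(self, strong_study):
        data = strong_study["datasets"]["blood"]
        modules = ms.detect_modules(data, ms.scenario_network_params())
        merged = ms.merge_modules(data, modules, 0.0001)
        assert merged.assignment == modules.assignment

    def test_artificially_split_module_remerged(self):
        data, modules = self._split_module_data()
        merged = ms.merge_modules(data, modules, 0.30)
        halves = {merged.assignment["g0"], merged.assignment["g5"]}
        assert len(halves) == 1

    def test_zero_threshold_identity_and_idempotence(self):
        data, modules = self._split_module_data()
        assert ms.merge_modules(data, modules, 0.0).assignment == modules.assignment
        once = ms.merge_modules(data, modules, 0.30)
        twice = ms.merge_modules(data, once, 0.30)
        assert once.assignment == twice.assignment


class TestModuleTraitCorrelation:
    def test_module_tracking_trait_gets_r_one(self):
        rng = np.random.default_rng(8)
        trait = rng.normal(size=20)
        values = np.outer(np.array([1.0, 2.0, 0.5]), trait)
        traits = pd.DataFrame({"carrier": trait}, index=[f"s{i}" for i in range(20)])
        data = make_dataset(values, traits=traits)
        modules = ms.ModuleSet({g: "M1" for g in data.gene_ids})
        res = ms.module_trait_correlation(data, modules)
        assert res.r.loc["M1", "carrier"] == pytest.approx(1.0, abs=1e-10)
        assert res.p.loc["M1", "carrier"] < 1e-10
        assert res.disease_associated()["M1"]

    def test_pearson_p_matches_closed_form_oracle(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, p = _pearson_with_p(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_perfectly_linear_vectors(self):
        r, p = _pearson_with_p(np.arange(1.0, 6.0), 2.0 * np.arange(1.0, 6.0))
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_constant_trait_reports_p_one_with_warning(self):
        rng = np.random.default_rng(10)
        values = rng.normal(size=(3, 12))
        traits = pd.DataFrame(
            {"carrier": np.ones(12)}, index=[f"s{i}" for i in range(12)]
        )
        data = make_dataset(values, traits=traits)
        modules = ms.ModuleSet({g: "M1" for g in data.gene_ids})
        with pytest.warns(UserWarning, match="constant"):
            res = ms.module_trait_correlation(data, modules)
        assert res.p.loc["M1", "carrier"] == 1.0
        assert not res.disease_associated()["M1"]


class TestModuleRecovery:
    def test_planted_modules_recovered_with_high_ari(self, strong_study):
        from sklearn.metrics import adjusted_rand_score

        for tissue, data in strong_study["datasets"].items():
            truth = strong_study["truths"][tissue]
            modules = ms.detect_modules(data, ms.scenario_network_params())
            ari = adjusted_rand_score(
                [truth.gene_module[g] for g in data.gene_ids],
                [modules.assignment[g] for g in data.gene_ids],
            )
            assert ari >= 0.9

    def test_assignment_partitions_gene_set(self, strong_report, strong_study):
        for tissue, modules in strong_report.modules.items():
            data = strong_study["datasets"][tissue]
            assert sorted(modules.assignment) == sorted(data.gene_ids)
            for size in modules.sizes().values():
                assert size >= ms.scenario_network_params().min_module_size
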