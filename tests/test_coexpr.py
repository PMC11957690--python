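"""Signed adjacency, TOM, module detection, eigengenes, hubs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from mccrewire import synthetic
from mccrewire.coexpr import (CoexpressionNetwork, ModulePartition,
                              _eigengene, build_network, detect_modules,
                              hub_and_leading_edges, module_trait_correlation,
                              signed_adjacency, soft_threshold_scan,
                              tom_matrix)
from mccrewire.errors import UndefinedCorrelationError

from conftest import make_expr


def _tom_bruteforce(a):
    """Direct triple-loop evaluation of the TOM formula."""
    n = a.shape[0]
    k = a.sum(axis=1) - np.diag(a)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n)
                         if u != i and u != j)
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestAdjacency:
    def test_signed_transform_landmarks(self):
        values = np.array([[1.0, 0.0], [0.5, 1.0]])
        # r = 0 at beta = 1 -> 0.5; r = -1 -> 0 for any beta
        r = np.array([[1.0, 0.0], [0.0, 1.0]])
        a = np.power((1 + r) / 2, 1.0)
        assert a[0, 1] == pytest.approx(0.5)
        r_anti = np.array([[1.0, -1.0], [-1.0, 1.0]])
        for beta in (1, 6, 16):
            a = np.power((1 + r_anti) / 2, beta)
            assert a[0, 1] == pytest.approx(0.0)

    def test_perfectly_correlated_genes(self):
        base = np.arange(5.0)
        expr = pd.DataFrame([base, 2 * base + 1, base + 3])
        a = signed_adjacency(expr, power=7)
        assert np.allclose(a, 1.0)

    @given(st.floats(-1, 1), st.floats(-1, 1))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_r(self, r1, r2):
        beta = 16.0
        a1 = ((1 + r1) / 2) ** beta
        a2 = ((1 + r2) / 2) ** beta
        if r1 <= r2:
            assert a1 <= a2 + 1e-15


class TestTOM:
    def test_hand_example_uniform_half(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        tom = tom_matrix(a)
        assert tom[0, 1] == pytest.approx(0.5)  # (0.25 + 0.5) / (1 + 1 - 0.5)
        assert np.allclose(np.diag(tom), 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_bruteforce_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, size=(6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_matrix(a)
        assert np.allclose(tom, _tom_bruteforce(a), atol=1e-12)
        assert np.allclose(tom, tom.T)
        assert ((tom >= 0) & (tom <= 1)).all()


class TestSoftThresholdScan:
    def test_default_grid_includes_sixteen(self, timecourse):
        expr, _ = timecourse
        table = soft_threshold_scan(expr.for_condition("ER"))
        assert 16 in set(table["power"])

    def test_all_correlated_connectivity(self):
        base = np.arange(6.0)
        expr = make_expr(np.vstack([base * (i + 1) + i for i in range(40)]))
        table = soft_threshold_scan(expr, powers=(4.0,))
        assert table.loc[0, "mean_connectivity"] == pytest.approx(39.0)

    def test_regression_matches_independent_oracle(self):
        """R^2 and slope match a log-log histogram regression recomputed
        from scratch on the same connectivities."""
        cfg = synthetic.TimecourseConfig(
            blocks={"canonical": 40, "noncanonical": 40, "ne": 40},
            n_noise_genes=60)
        expr, _ = synthetic.gen_timecourse(cfg, seed=13)
        er = expr.for_condition("ER")
        table = soft_threshold_scan(er, powers=(6.0,))

        a = signed_adjacency(er.values, power=6.0)
        k = a.sum(axis=1) - 1.0
        edges = np.linspace(k.min(), k.max(), 11)
        idx = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
        freq = np.bincount(idx, minlength=10).astype(float)
        xs, ys = [], []
        for b_ in range(10):
            if freq[b_] > 0 and k[idx == b_].mean() > 0:
                xs.append(np.log10(k[idx == b_].mean()))
                ys.append(np.log10(freq[b_]))
        fit = stats.linregress(xs, ys)
        assert table.loc[0, "scale_free_R2"] == pytest.approx(fit.rvalue ** 2,
                                                              abs=1e-9)
        assert table.loc[0, "slope"] == pytest.approx(fit.slope, abs=1e-9)


class TestDetectModules:
    def test_planted_three_block_recovery(self):
        cfg = synthetic.TimecourseConfig(
            blocks={"canonical": 60, "noncanonical": 60, "ne": 60},
            n_noise_genes=0)
        expr, truth = synthetic.gen_timecourse(cfg, seed=17)
        network = build_network(expr.for_condition("ER"), power=16)
        partition = detect_modules(network)
        assert len(partition.module_ids()) == 3
        planted = [truth.planted_module_labels[g] for g in partition.labels.index]
        assert adjusted_rand_score(planted, partition.labels.to_numpy()) == 1.0

    def test_single_homogeneous_block(self):
        cfg = synthetic.TimecourseConfig(blocks={"canonical": 50},
                                         n_noise_genes=0)
        expr, _ = synthetic.gen_timecourse(cfg, seed=2)
        network = build_network(expr.for_condition("ER"), power=16)
        partition = detect_modules(network)
        assert partition.module_ids() == [1]
        assert (partition.labels == 1).all()

    def test_defaults_match_study_parameters(self):
        import inspect
        params = inspect.signature(detect_modules).parameters
        assert params["min_size"].default == 30
        assert params["merge_height"].default == 0.25

    def test_min_size_enforced(self, timecourse):
        expr, _ = timecourse
        network = build_network(expr.for_condition("ER"), power=16)
        partition = detect_modules(network)
        for m in partition.module_ids():
            assert len(partition.genes_of(m)) >= 30

    def test_merge_idempotent(self):
        from mccrewire.coexpr import _merge_by_eigengene
        cfg = synthetic.TimecourseConfig(
            blocks={"canonical": 40, "noncanonical": 40}, n_noise_genes=0)
        expr, _ = synthetic.gen_timecourse(cfg, seed=3)
        network = build_network(expr.for_condition("ER"), power=16)
        partition = detect_modules(network)
        merged_again = _merge_by_eigengene(network.expression,
                                           partition.labels, 0.25)
        assert merged_again.equals(partition.labels)

    def test_tiny_input_left_unassigned(self):
        expr = make_expr(np.random.default_rng(0).normal(size=(5, 8)))
        network = build_network(expr, power=2)
        with pytest.warns(UserWarning):
            partition = detect_modules(network, min_size=30)
        assert (partition.labels == 0).all()


class TestEigengene:
    def test_first_pc_optimality(self):
        """The eigengene explains at least the variance of any other
        unit-norm combination of the standardized module genes (checked
        against an independent eigendecomposition)."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=(12, 20)) + rng.normal(size=(1, 20))
        values = pd.DataFrame(x)
        e = _eigengene(values)
        z = x - x.mean(axis=1, keepdims=True)
        z = z / z.std(axis=1, keepdims=True)
        var_e = float(np.sum((z @ e) ** 2))
        evals, evecs = np.linalg.eigh(z.T @ z)
        assert var_e == pytest.approx(evals[-1], rel=1e-9)
        for _ in range(20):
            v = rng.normal(size=e.shape)
            v /= np.linalg.norm(v)
            assert var_e >= np.sum((z @ v) ** 2) - 1e-9

    def test_orientation_follows_module_mean(self, timecourse):
        expr, truth = timecourse
        network = build_network(expr.for_condition("ER"), power=16)
        partition = detect_modules(network)
        for m in partition.module_ids():
            e = partition.eigengenes[m]
            mean_prof = network.expression.loc[partition.genes_of(m)].mean(axis=0)
            assert np.corrcoef(e, mean_prof)[0, 1] >= 0


class TestModuleTrait:
    def test_proportional_eigengene(self):
        trait = np.arange(8.0)
        eig = pd.DataFrame({1: (trait - trait.mean())
                            / np.linalg.norm(trait - trait.mean())})
        part = ModulePartition(labels=pd.Series([1]), eigengenes=eig)
        table = module_trait_correlation(part, trait)
        assert table.loc[1, "r"] == pytest.approx(1.0)
        assert table.loc[1, "p"] < 1e-10

    def test_hand_example(self):
        # eigengene (1,2,3,4) vs trait (1,3,2,4): r = 0.8
        eig = pd.DataFrame({1: [1.0, 2.0, 3.0, 4.0]})
        part = ModulePartition(labels=pd.Series([1]), eigengenes=eig)
        table = module_trait_correlation(part, [1.0, 3.0, 2.0, 4.0])
        assert table.loc[1, "r"] == pytest.approx(0.8)
        t = 0.8 * np.sqrt(2 / 0.36)
        assert table.loc[1, "p"] == pytest.approx(2 * stats.t.sf(t, df=2))

    def test_orthogonal_gives_p_one(self):
        eig = pd.DataFrame({1: [1.0, -1.0] * 6})
        part = ModulePartition(labels=pd.Series([1]), eigengenes=eig)
        trait = np.tile([1.0, 1.0, -1.0, -1.0], 3)
        table = module_trait_correlation(part, trait)
        assert table.loc[1, "r"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc[1, "p"] == pytest.approx(1.0)

    def test_constant_trait_rejected(self):
        eig = pd.DataFrame({1: [1.0, 2.0, 3.0]})
        part = ModulePartition(labels=pd.Series([1]), eigengenes=eig)
        with pytest.raises(UndefinedCorrelationError):
            module_trait_correlation(part, [2.0, 2.0, 2.0])


@pytest.fixture(scope="module")
def network_partition():
    cfg = synthetic.TimecourseConfig(
        blocks={"canonical": 60, "noncanonical": 60}, n_noise_genes=0)
    expr, _ = synthetic.gen_timecourse(cfg, seed=6)
    network = build_network(expr.for_condition("ER"), power=16)
    return network, detect_modules(network)


class TestHubsAndEdges:
    def test_forty_hubs_per_module_by_default(self, network_partition):
        network, partition = network_partition
        hubs, _ = hub_and_leading_edges(network, partition)
        for m, genes in hubs.items():
            assert len(genes) == 40

    def test_small_module_keeps_top_tom_sums(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.2, 0.9, size=(5, 5))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_matrix(a)
        genes = [f"g{i}" for i in range(5)]
        network = CoexpressionNetwork(
            genes=genes, samples=["s1"], power=1.0, adjacency=a, tom=tom,
            expression=pd.DataFrame(np.zeros((5, 1)), index=genes))
        partition = ModulePartition(
            labels=pd.Series(1, index=genes),
            eigengenes=pd.DataFrame(index=["s1"]))
        hubs, _ = hub_and_leading_edges(network, partition, n_hubs=2,
                                        edge_quantile=0.5)
        score = tom.sum(axis=1) - 1
        expected = [genes[i] for i in np.argsort(-score)[:2]]
        assert hubs[1] == expected

    def test_quintile_filter_keeps_ceil_fraction(self, network_partition):
        """With distinct edge weights the 0.80-quantile filter keeps exactly
        ceil(0.2 * E) edges, the heaviest ones."""
        network, partition = network_partition
        hubs, edges = hub_and_leading_edges(network, partition, n_hubs=5,
                                            edge_quantile=0.80)
        n_hub_genes = len({g for hs in hubs.values() for g in hs})
        n_candidates = n_hub_genes * (n_hub_genes - 1) // 2
        assert len(edges) == int(np.ceil(0.2 * n_candidates))

    def test_hub_selection_gene_order_invariant(self):
        cfg = synthetic.TimecourseConfig(blocks={"canonical": 40},
                                         n_noise_genes=0)
        expr, _ = synthetic.gen_timecourse(cfg, seed=8)
        perm = np.random.default_rng(0).permutation(expr.n_genes)
        shuffled = synthetic.ExpressionMatrix(expr.values.iloc[perm], expr.meta)
        for e in (expr, shuffled):
            network = build_network(e.for_condition("ER"), power=16)
            partition = detect_modules(network)
            hubs, _ = hub_and_leading_edges(network, partition, n_hubs=10)
            if e is expr:
                reference = {m: set(g) for m, g in hubs.items()}
            else:
                assert {m: set(g) for m, g in hubs.items()} == reference
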