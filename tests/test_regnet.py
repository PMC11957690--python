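"""Message-passing inference, single-sample extraction, period averaging,
and differential-community detection."""

import numpy as np
import pandas as pd
import pytest

from mccrewire import synthetic
from mccrewire.errors import AlignmentError, InsufficientSamplesError
from mccrewire.regnet import (BipartiteNetwork, PeriodMap, _tanimoto,
                              _zscore, bipartite_modularity,
                              differential_communities, infer_network,
                              single_sample_networks, transform_and_average,
                              register_transform, TRANSFORMS)

from conftest import make_expr
from oracles import modularity_by_enumeration


@pytest.fixture(scope="module")
def small_inference_inputs():
    cfg = synthetic.TimecourseConfig(blocks={"canonical": 20,
                                             "noncanonical": 20},
                                     n_noise_genes=0)
    expr, _ = synthetic.gen_timecourse(cfg, seed=4)
    sub = expr.subset_samples(expr.samples[:8])
    prior_cfg = synthetic.PriorConfig(n_tfs=4, n_genes=40,
                                      gene_names=tuple(expr.genes))
    motif, ppi = synthetic.gen_network_priors(prior_cfg, seed=5)
    return sub, motif, ppi


class TestInference:
    def test_alpha_zero_returns_normalized_prior(self, small_inference_inputs):
        expr, motif, ppi = small_inference_inputs
        net = infer_network(expr, motif, ppi, alpha=0.0)
        assert np.allclose(net.weights, _zscore(motif.to_numpy(float)))

    def test_output_shape(self, small_inference_inputs):
        expr, motif, ppi = small_inference_inputs
        net = infer_network(expr, motif, ppi, alpha=0.1)
        assert net.weights.shape == (motif.shape[0], motif.shape[1])
        assert net.tag["converged"]

    def test_one_update_step_matches_straightline_oracle(self):
        """A single damped update on a 2 TF x 3 gene toy equals a
        straight-line evaluation of the message-passing formulas."""
        values = np.array([[1.0, 2.0, 4.0, 3.0],
                           [2.0, 1.0, 3.0, 5.0],
                           [5.0, 4.0, 1.0, 2.0]])
        expr = make_expr(values, genes=["g1", "g2", "g3"])
        motif = pd.DataFrame([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]],
                             index=["g1", "g2"], columns=["g1", "g2", "g3"])
        ppi = pd.DataFrame([[1.0, 0.3], [0.3, 1.0]],
                           index=["g1", "g2"], columns=["g1", "g2"])
        alpha = 0.5
        net = infer_network(expr, motif, ppi, alpha=alpha, max_iter=1)

        # independent one-step evaluation
        w0 = _zscore(motif.to_numpy())
        p0 = _zscore(ppi.to_numpy())
        c0 = _zscore(np.corrcoef(values))

        def t_oracle(x, y):
            out = np.zeros((x.shape[0], y.shape[1]))
            for i in range(x.shape[0]):
                for j in range(y.shape[1]):
                    num = float(x[i] @ y[:, j])
                    den = np.sqrt(max((x[i] ** 2).sum() + (y[:, j] ** 2).sum()
                                      - abs(num), 1e-12))
                    out[i, j] = num / den
            return out

        expected = (1 - alpha) * w0 + alpha * 0.5 * (t_oracle(p0, w0)
                                                     + t_oracle(w0, c0))
        assert np.allclose(net.weights, expected, atol=1e-12)

    def test_permutation_invariance(self, small_inference_inputs):
        """Consistently permuting TF and gene orderings permutes the output
        weights accordingly."""
        expr, motif, ppi = small_inference_inputs
        net = infer_network(expr, motif, ppi, alpha=0.1, max_iter=40)
        rng = np.random.default_rng(0)
        gperm = rng.permutation(motif.shape[1])
        tperm = rng.permutation(motif.shape[0])
        motif2 = motif.iloc[tperm, gperm]
        ppi2 = ppi.iloc[tperm, tperm]
        net2 = infer_network(expr, motif2, ppi2, alpha=0.1, max_iter=40)
        assert np.allclose(net2.weights, net.weights[np.ix_(tperm, gperm)],
                           atol=1e-10)

    def test_too_few_samples_rejected(self, small_inference_inputs):
        expr, motif, ppi = small_inference_inputs
        with pytest.raises(InsufficientSamplesError):
            infer_network(expr.subset_samples(expr.samples[:2]), motif, ppi)


class TestSingleSample:
    def test_lioness_formula_with_correlation_stub(self):
        """With a pairwise-correlation stub, e_1 equals the hand evaluation
        of 3 * e(all) - 2 * e(without sample 1)."""
        values = np.array([[1.0, 2.0, 4.0], [2.0, 1.0, 5.0], [4.0, 5.0, 1.0]])
        expr = make_expr(values, genes=["g1", "g2", "g3"])
        motif = pd.DataFrame(np.ones((2, 3)), index=["g1", "g2"],
                             columns=["g1", "g2", "g3"])
        ppi = pd.DataFrame(np.eye(2), index=["g1", "g2"],
                           columns=["g1", "g2"])

        def stub(e):
            return np.corrcoef(e.values.to_numpy())[:2, :]

        nets = single_sample_networks(expr, motif, ppi, inference=stub,
                                      recenter=False)
        e_all = np.corrcoef(values)[:2, :]
        e_wo1 = np.corrcoef(values[:, 1:])[:2, :]
        assert np.allclose(nets[0].weights, 3 * e_all - 2 * e_wo1, atol=1e-12)

    def test_mean_identity_with_message_passing(self, small_inference_inputs):
        """Recentered single-sample networks average to the aggregate for
        the full message-passing inference."""
        expr, motif, ppi = small_inference_inputs
        nets = single_sample_networks(expr, motif, ppi, alpha=0.1)
        agg = infer_network(expr, motif, ppi, alpha=0.1).weights
        mean = np.mean([n.weights for n in nets], axis=0)
        assert np.max(np.abs(mean - agg)) < 1e-10

    def test_recentering_is_noop_for_linear_inference(self):
        """For a sample-linear inference function the raw decomposition
        already averages to the aggregate, so recentering changes nothing."""
        rng = np.random.default_rng(7)
        values = rng.normal(size=(4, 6))
        expr = make_expr(values)
        motif = pd.DataFrame(np.ones((2, 4)), index=expr.genes[:2],
                             columns=expr.genes)
        ppi = pd.DataFrame(np.eye(2), index=expr.genes[:2],
                           columns=expr.genes[:2])

        def linear(e):  # mean outer product: linear in the sample set
            x = e.values.to_numpy()
            return (x[:2] @ x.T) / x.shape[1]

        raw = single_sample_networks(expr, motif, ppi, inference=linear,
                                     recenter=False)
        rec = single_sample_networks(expr, motif, ppi, inference=linear,
                                     recenter=True)
        for a, b in zip(raw, rec):
            assert np.allclose(a.weights, b.weights, atol=1e-10)

    def test_duplicated_samples_get_equal_networks(self):
        values = np.array([[1.0, 2.0, 2.0, 5.0], [3.0, 1.0, 1.0, 2.0],
                           [2.0, 4.0, 4.0, 1.0]])
        expr = make_expr(values, genes=["g1", "g2", "g3"])
        motif = pd.DataFrame(np.ones((2, 3)), index=["g1", "g2"],
                             columns=["g1", "g2", "g3"])
        ppi = pd.DataFrame(np.eye(2), index=["g1", "g2"],
                           columns=["g1", "g2"])

        def stub(e):
            return np.corrcoef(e.values.to_numpy())[:2, :]

        nets = single_sample_networks(expr, motif, ppi, inference=stub)
        assert np.allclose(nets[1].weights, nets[2].weights, atol=1e-12)


class TestTransformAndAverage:
    def test_softplus_closed_forms(self):
        fn = TRANSFORMS["softplus"]
        assert fn(np.array(0.0)) == pytest.approx(np.log(2.0))
        assert fn(np.array(-50.0)) > 0
        w = np.linspace(-5, 5, 101)
        out = fn(w)
        assert (np.diff(out) > 0).all()
        assert (out > 0).all()

    def test_period_average_closed_form(self):
        tfs, genes = ["t1"], ["g1"]
        nets = [BipartiteNetwork(tfs, genes, np.array([[w]]),
                                 tag={"condition": "ER", "time_hours": t})
                for w, t in ((1.0, 0), (3.0, 4))]
        out = transform_and_average(nets)
        expected = (np.log1p(np.exp(1.0)) + np.log1p(np.exp(3.0))) / 2
        assert out[("ER", 1)].weights[0, 0] == pytest.approx(expected)

    def test_ten_timepoints_give_five_periods_per_condition(self, timecourse):
        expr, _ = timecourse
        tfs, genes = ["t1"], ["g1"]
        nets = []
        for s in expr.samples:
            row = expr.meta.loc[s]
            nets.append(BipartiteNetwork(tfs, genes, np.zeros((1, 1)),
                                         tag={"condition": row["condition"],
                                              "time_hours": int(row["time_hours"]),
                                              "sample": s}))
        out = transform_and_average(nets)
        for cond in ("ER", "CTRL"):
            assert sorted(p for c, p in out if c == cond) == [1, 2, 3, 4, 5]

    def test_unmapped_timepoint_rejected(self):
        net = BipartiteNetwork(["t1"], ["g1"], np.zeros((1, 1)),
                               tag={"condition": "ER", "time_hours": 99})
        with pytest.raises(AlignmentError):
            transform_and_average([net])

    def test_registered_transform_hook(self):
        register_transform("square", lambda w: w ** 2)
        net = BipartiteNetwork(["t1"], ["g1"], np.array([[3.0]]),
                               tag={"condition": "ER", "time_hours": 0})
        out = transform_and_average([net], transform="square")
        assert out[("ER", 1)].weights[0, 0] == pytest.approx(9.0)


class TestCommunities:
    def test_q_matches_enumeration_small_graphs(self):
        """Bipartite and differential modularity agree with exhaustive
        set-partition enumeration on graphs of up to 8 nodes."""
        rng = np.random.default_rng(2)
        for n_tf, n_gene in ((2, 2), (2, 4), (3, 3), (4, 4)):
            base = rng.uniform(0.1, 1.0, size=(n_tf, n_gene))
            pert = base + rng.uniform(0, 2.0, size=(n_tf, n_gene))
            best_q, _, q_of = modularity_by_enumeration(pert, base)
            # spot-check the Q function on random label assignments
            for _ in range(10):
                tf_l = rng.integers(0, 3, size=n_tf)
                gene_l = rng.integers(0, 3, size=n_gene)
                q = bipartite_modularity(pert, tf_l, gene_l,
                                         null_weights=base,
                                         null_total=base.sum())
                assert q == pytest.approx(q_of(tf_l, gene_l), abs=1e-12)

    def test_greedy_returns_argmax_on_two_by_two_toy(self):
        base = BipartiteNetwork(["t1", "t2"], ["g1", "g2"],
                                np.full((2, 2), 0.5))
        pert = BipartiteNetwork(["t1", "t2"], ["g1", "g2"],
                                np.array([[2.5, 0.5], [0.5, 2.5]]))
        result = differential_communities(base, pert, min_size=0)
        best_q, _, _ = modularity_by_enumeration(pert.weights, base.weights)
        assert result.modularity == pytest.approx(best_q, abs=1e-12)
        assert (result.membership[("tf", "t1")]
                == result.membership[("gene", "g1")])
        assert (result.membership[("tf", "t2")]
                == result.membership[("gene", "g2")])
        assert (result.membership[("tf", "t1")]
                != result.membership[("tf", "t2")])

    def test_null_comparison_no_spurious_rewiring(self):
        base, _, _ = synthetic.planted_differential_pair(seed=0)
        result = differential_communities(base, base, min_size=30)
        from mccrewire.regnet import detect_base_communities
        tf_l, gene_l = detect_base_communities(base)
        q_seed = bipartite_modularity(base.weights, tf_l, gene_l,
                                      null_weights=base.weights)
        assert result.modularity - q_seed <= 1e-9

    def test_planted_blocks_recovered_and_filtered(self):
        """Blocks of 10/50/200 nodes are all found; only the two larger than
        the 30-node filter are retained."""
        base, pert, truth = synthetic.planted_differential_pair(seed=0)
        result = differential_communities(base, pert, min_size=30)
        assert len(result.retained) == 2
        retained_sizes = sorted(result.sizes[c] for c in result.retained)
        assert retained_sizes == [50, 200]
        # the 10-node block exists as a community but is filtered out
        all_sizes = sorted(s for s in result.sizes.values() if s > 1)
        assert 10 in all_sizes

    def test_contributions_sum_to_modularity(self):
        base, pert, _ = synthetic.planted_differential_pair(seed=0)
        result = differential_communities(base, pert, min_size=30)
        assert sum(result.diff_modularity.values()) == pytest.approx(
            result.modularity, rel=1e-9)

    def test_mismatched_spaces_rejected(self):
        a = BipartiteNetwork(["t1"], ["g1"], np.ones((1, 1)))
        b = BipartiteNetwork(["t2"], ["g1"], np.ones((1, 1)))
        with pytest.raises(AlignmentError):
            differential_communities(a, b)

    def test_empty_perturbed_warns_and_returns_empty(self):
        a = BipartiteNetwork(["t1"], ["g1"], np.ones((1, 1)))
        z = BipartiteNetwork(["t1"], ["g1"], np.zeros((1, 1)))
        with pytest.warns(UserWarning):
            result = differential_communities(a, z)
        assert result.retained == []


class TestPeriodMap:
    def test_default_assignment(self):
        pm = PeriodMap()
        assert pm.period_of(0) == 1 and pm.period_of(4) == 1
        assert pm.period_of(24) == 4 and pm.period_of(32) == 4
        assert pm.period_of(48) == 5
        assert pm.periods() == [1, 2, 3, 4, 5]

    def test_uncovered_time_rejected(self):
        with pytest.raises(AlignmentError):
            PeriodMap().period_of(7)
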