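"""Mutual linearity scores, network construction, permutation null."""

import itertools

import numpy as np
import pytest

import linsimplex as ls
from linsimplex import collinearity as coll


def _norm_matrix(values):
    values = np.asarray(values, dtype=float)
    expr = ls.ExpressionMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
    )
    return ls.row_normalize(expr)


class TestSymmetricLinearity:
    def test_proportional_genes_score_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert coll.symmetric_linearity(x, 1.89 * x) == pytest.approx(1.0)

    def test_identity(self):
        x = np.array([0.5, 1.5, 2.0, 4.0])
        assert coll.symmetric_linearity(x, x) == pytest.approx(1.0)

    def test_hand_computed_negative_case(self):
        # normalized profiles (0.5,0.5,0,0) and (0,0,0.5,0.5):
        # each direction gives 1 - 1.0/0.25 = -3
        x = np.array([0.5, 0.5, 0.0, 0.0])
        y = np.array([0.0, 0.0, 0.5, 0.5])
        assert coll.symmetric_linearity(x, y) == pytest.approx(-3.0)

    def test_constant_profile_is_sentinel(self):
        x = np.array([2.0, 2.0, 2.0, 2.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.isnan(coll.symmetric_linearity(x, y))

    def test_symmetry_and_scale_invariance(self, rng):
        x = rng.uniform(0.5, 5.0, 8)
        y = rng.uniform(0.5, 5.0, 8)
        a = coll.symmetric_linearity(x, y)
        assert a == pytest.approx(coll.symmetric_linearity(y, x), abs=1e-12)
        assert a == pytest.approx(
            coll.symmetric_linearity(3.7 * x, 0.2 * y), abs=1e-12
        )


class TestPairwiseScores:
    def test_matches_brute_force_pair_loop(self, rng):
        vals = rng.uniform(0.1, 10.0, size=(10, 12))
        norm = _norm_matrix(vals)
        lin, rho = coll.pairwise_scores(norm)
        import scipy.stats

        for i, j in itertools.combinations(range(10), 2):
            expected = coll.symmetric_linearity(vals[i], vals[j])
            assert lin[i, j] == pytest.approx(expected, abs=1e-12)
            exp_rho = scipy.stats.spearmanr(vals[i], vals[j]).statistic
            assert rho[i, j] == pytest.approx(exp_rho, abs=1e-12)
        np.testing.assert_allclose(np.diag(lin), 1.0)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_monotone_nonlinear_pair(self):
        x = np.linspace(1.0, 3.0, 10)
        norm = _norm_matrix(np.vstack([x, x**3]))
        lin, rho = coll.pairwise_scores(norm)
        assert rho[0, 1] == pytest.approx(1.0)
        assert lin[0, 1] < 1.0

    def test_gene_ceiling(self, rng):
        norm = _norm_matrix(rng.uniform(1, 2, size=(30, 5)))
        with pytest.raises(ValueError, match="ceiling"):
            coll.pairwise_scores(norm, gene_ceiling=10)

    def test_blocked_equals_unblocked(self, rng):
        vals = rng.uniform(0.1, 5.0, size=(37, 9))
        norm = _norm_matrix(vals)
        a_lin, a_rho = coll.pairwise_scores(norm, block_size=7)
        b_lin, b_rho = coll.pairwise_scores(norm, block_size=1000)
        np.testing.assert_allclose(a_lin, b_lin, atol=1e-13)
        np.testing.assert_allclose(a_rho, b_rho, atol=1e-13)


class TestBuildNetwork:
    def test_weight_is_product_and_sign_rule(self):
        lin = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.5], [0.9, -0.5, 1.0]])
        rho = np.array([[1.0, 0.8, -0.1], [0.8, 1.0, 0.9], [-0.1, 0.9, 1.0]])
        net = coll.build_network(lin, rho)
        # only the (0,1) pair has both scores positive
        assert net.n_edges == 1
        assert net.weights[0] == pytest.approx(0.72)
        np.testing.assert_allclose(net.power, [0.72, 0.72, 0.0])

    def test_identical_clique_powers(self):
        vals = np.vstack([[1.0, 2.0, 3.0, 4.0]] * 3) * np.array([[1], [2], [5]])
        norm = _norm_matrix(vals)
        lin, rho = coll.pairwise_scores(norm)
        net = coll.build_network(lin, rho)
        np.testing.assert_allclose(net.power, 2.0, atol=1e-10)

    def test_power_matches_incident_weights(self, rng):
        vals = rng.uniform(0.1, 5.0, size=(15, 8))
        lin, rho = coll.pairwise_scores(_norm_matrix(vals))
        net = coll.build_network(lin, rho)
        manual = np.zeros(15)
        for (i, j), w in zip(net.edges, net.weights):
            manual[i] += w
            manual[j] += w
        np.testing.assert_allclose(net.power, manual, atol=1e-10)


def _planted_blocks_matrix(seed=0):
    """3 mutually linear blocks of 5 genes + 15 independent noise genes."""
    rng = np.random.default_rng(seed)
    m = 20
    rows = []
    for _ in range(3):
        base = rng.uniform(0.5, 5.0, m)
        for _ in range(5):
            rows.append(base * rng.uniform(0.5, 3.0))
    for _ in range(15):
        rows.append(np.exp2(rng.normal(6.0, 1.5, m)))
    return np.array(rows)


class TestSignificanceFilter:
    def test_eq6_boundary_p_values(self):
        lin = np.array([[1.0, 0.9], [0.9, 1.0]])
        rho = np.array([[1.0, 0.8], [0.8, 1.0]])
        net = coll.build_network(lin, rho)
        out = coll.significance_filter(net, k_iterations=99, seed=0)
        # single edge: every shuffle reproduces the same powers, so every
        # round ties and Success = K, p = 1
        np.testing.assert_allclose(out.p_value, 1.0)
        # p can never undercut 1/(K+1)
        assert (out.p_value >= 1.0 / 100.0).all()

    def test_selection_enriches_linear_signal(self):
        """On a noisy mixture the filter keeps the genes whose expression
        actually tracks cell-type proportions (high signature values) and
        rejects the noise-dominated rest.  The edge multiset must be
        heterogeneous for the null to have power — with a handful of
        equal-weight edges every shuffle ties (the >= rule counts ties as
        successes) and nothing can reach significance."""
        expr, truth = ls.simulate_dataset(300, 30, 3, noise_sd=2.0, seed=2)
        lin, rho = coll.pairwise_scores(ls.row_normalize(expr))
        net = coll.build_network(lin, rho)
        out = coll.significance_filter(net, k_iterations=999, alpha=0.01, seed=5)
        sel = out.selected
        assert 20 <= sel.sum() <= 200
        signal = (truth.W + 1.0).max(axis=1)
        assert np.median(signal[sel]) > 1.5 * np.median(signal[~sel])

    def test_degenerate_equal_weights_select_nothing(self):
        """Three exactly-linear blocks produce only equal-weight edges;
        every permutation ties, so all p-values are large."""
        vals = _planted_blocks_matrix()
        lin, rho = coll.pairwise_scores(_norm_matrix(vals))
        net = coll.build_network(lin, rho)
        out = coll.significance_filter(net, k_iterations=999, alpha=0.01, seed=5)
        assert out.selected.sum() <= 2

    def test_permutation_conserves_total_power(self, rng):
        vals = rng.uniform(0.1, 5.0, size=(12, 9))
        lin, rho = coll.pairwise_scores(_norm_matrix(vals))
        net = coll.build_network(lin, rho)
        w = rng.permutation(net.weights)
        sampled = np.bincount(net.edges[:, 0], weights=w, minlength=12) + \
            np.bincount(net.edges[:, 1], weights=w, minlength=12)
        assert sampled.sum() == pytest.approx(2 * net.weights.sum())
        assert net.power.sum() == pytest.approx(2 * net.weights.sum())

    def test_reproducible_with_seed(self):
        vals = _planted_blocks_matrix(3)
        lin, rho = coll.pairwise_scores(_norm_matrix(vals))
        net = coll.build_network(lin, rho)
        a = coll.significance_filter(net, 199, seed=42)
        b = coll.significance_filter(net, 199, seed=42)
        np.testing.assert_array_equal(a.p_value, b.p_value)

    def test_matches_exhaustive_permutation_on_toy_graph(self):
        """Monte-Carlo p-values agree with the exact permutation
        distribution enumerated over all weight orderings of a 6-edge
        graph."""
        edges = np.array([[0, 1], [0, 2], [1, 2], [2, 3], [3, 4], [0, 4]])
        weights = np.array([0.9, 0.1, 0.4, 0.7, 0.2, 0.5])
        n = 5
        power = np.bincount(edges[:, 0], weights=weights, minlength=n) + \
            np.bincount(edges[:, 1], weights=weights, minlength=n)
        net = coll.CollinearityNetwork(
            [f"g{i}" for i in range(n)], edges, weights, power
        )
        exact = np.zeros(n)
        perms = list(itertools.permutations(weights))
        for perm in perms:
            w = np.array(perm)
            sampled = np.bincount(edges[:, 0], weights=w, minlength=n) + \
                np.bincount(edges[:, 1], weights=w, minlength=n)
            exact += sampled >= power - 1e-12
        exact_p = exact / len(perms)
        out = coll.significance_filter(net, k_iterations=4_999, seed=17)
        np.testing.assert_allclose(out.p_value, exact_p, atol=0.03)

    def test_bonferroni_iteration_bound(self):
        lin = np.array([[1.0, 0.9], [0.9, 1.0]])
        rho = np.array([[1.0, 0.8], [0.8, 1.0]])
        net = coll.build_network(lin, rho)
        with pytest.raises(ValueError, match="N/alpha"):
            coll.significance_filter(net, k_iterations=10, alpha=0.01,
                                     bonferroni=True)


class TestThresholdFilter:
    def test_both_conditions_required(self):
        n = 14
        lin = np.zeros((n, n))
        # gene 0: one strong partner + 12 moderate partners -> kept
        lin[0, 1] = lin[1, 0] = 0.80
        for j in range(2, 14):
            lin[0, j] = lin[j, 0] = 0.30
        mask = coll.threshold_filter(lin)
        assert mask[0]
        # gene 1: strong partner but only 4 partners above 0.25 -> removed
        lin2 = np.zeros((n, n))
        lin2[1, 0] = lin2[0, 1] = 0.80
        for j in range(2, 6):
            lin2[1, j] = lin2[j, 1] = 0.30
        assert not coll.threshold_filter(lin2)[1]

    def test_negative_values_zeroed_first(self):
        # strongly negative linearities must never satisfy a positive
        # threshold (they are zeroed, not taken by magnitude)
        lin = np.full((3, 3), -0.9)
        np.fill_diagonal(lin, 1.0)
        mask = coll.threshold_filter(lin, k1=1, t1=0.5, k2=1, t2=0.25)
        assert not mask.any()

    def test_warns_when_thresholds_inverted(self):
        lin = np.eye(3)
        with pytest.warns(UserWarning, match="threshold1"):
            coll.threshold_filter(lin, t1=0.1, k2=1, t2=0.5)


class TestClusterLinearGenes:
    def test_two_planted_blocks(self):
        vals = _planted_blocks_matrix(7)[:10]  # two blocks of 5
        lin, rho = coll.pairwise_scores(_norm_matrix(vals))
        labels, _ = coll.cluster_linear_genes(lin)
        assert len(np.unique(labels)) == 2
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_single_block_single_cluster(self):
        base = np.array([1.0, 2.0, 3.0, 5.0, 7.0])
        vals = np.vstack([base * k for k in (1.0, 2.0, 0.5, 3.0)])
        lin, _ = coll.pairwise_scores(_norm_matrix(vals))
        labels, _ = coll.cluster_linear_genes(lin)
        assert len(np.unique(labels)) == 1

    def test_gene_order_invariance(self, rng):
        vals = _planted_blocks_matrix(9)[:10]
        lin, _ = coll.pairwise_scores(_norm_matrix(vals))
        labels, _ = coll.cluster_linear_genes(lin)
        perm = rng.permutation(10)
        labels_p, _ = coll.cluster_linear_genes(lin[np.ix_(perm, perm)])
        # identical partition up to relabeling
        for i in range(10):
            for j in range(10):
                same = labels[perm[i]] == labels[perm[j]]
                same_p = labels_p[i] == labels_p[j]
                assert same == same_p


def test_null_p_values_super_uniform():
    """On independent noise genes the permutation p-values are
    super-uniform: well under 10% of genes reach p < 0.05 at K_iter = 199."""
    rng = np.random.default_rng(99)
    vals = np.exp2(rng.normal(6.0, 1.5, size=(50, 40)))
    lin, rho = coll.pairwise_scores(_norm_matrix(vals))
    net = coll.build_network(lin, rho)
    out = coll.significance_filter(net, k_iterations=199, seed=123)
    frac = float((out.p_value < 0.05).mean())
    assert frac <= 0.10
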