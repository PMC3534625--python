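import numpy as np
import pytest

import cogevo as cg
from cogevo import gainloss as gl

from conftest import random_model, random_tree


class TestBranchMatrix:
    @pytest.mark.parametrize(
        "g,l,expected",
        [
            (0.0, 0.0, [[1, 0], [0, 1]]),
            (1.0, 1.0, [[0, 1], [1, 0]]),
            (0.3, 0.1, [[0.7, 0.3], [0.1, 0.9]]),
        ],
    )
    def test_values(self, g, l, expected):
        np.testing.assert_allclose(gl.branch_matrix(g, l), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gl.branch_matrix(1.2, 0.1)


class TestFamilyLoglik:
    def test_single_leaf_present_is_log_root_gain(self):
        t = cg.read_newick("A;")
        m = cg.GainLossModel([0.4], [0.2], condition_on_observed=False)
        assert gl.family_loglik({"A": 1}, t, m) == pytest.approx(np.log(0.4))
        assert gl.family_loglik({"A": 0}, t, m) == pytest.approx(np.log(0.6))

    def test_two_leaf_matches_enumeration(self):
        t = cg.read_newick("(A,B);")
        m = cg.GainLossModel([0.3, 0.6, 0.2], [0.25, 0.1, 0.45], condition_on_observed=False)
        # enumerate root state: origin absent -> root via branch 0
        g, l = m.gain, m.loss
        manual = (1 - g[0]) * g[1] * g[2] + g[0] * (1 - l[1]) * (1 - l[2])
        assert gl.family_loglik({"A": 1, "B": 1}, t, m) == pytest.approx(np.log(manual), rel=1e-12)

    def test_conditioning_subtracts_empty_mass(self):
        t = cg.read_newick("(A,B);")
        mu = cg.GainLossModel([0.3] * 3, [0.2] * 3, condition_on_observed=False)
        mc = cg.GainLossModel([0.3] * 3, [0.2] * 3, condition_on_observed=True)
        pat = {"A": 1, "B": 0}
        l_empty = np.exp(gl.family_loglik({"A": 0, "B": 0}, t, mu))
        expect = gl.family_loglik(pat, t, mu) - np.log1p(-l_empty)
        assert gl.family_loglik(pat, t, mc) == pytest.approx(expect, rel=1e-12)

    def test_leaf_mismatch_raises(self, three_leaf_tree):
        m = cg.GainLossModel([0.3] * 5, [0.2] * 5)
        with pytest.raises(ValueError):
            gl.family_loglik({"A": 1, "B": 0}, three_leaf_tree, m)


class TestPosteriorOracle:
    """Pruning/up-down results must equal exhaustive enumeration."""

    def _compare(self, tree, model, pattern):
        fast = gl.posteriors(pattern, tree, model)
        slow = gl.brute_force_posteriors(pattern, tree, model)
        np.testing.assert_allclose(fast.node_presence, slow.node_presence, atol=1e-10)
        np.testing.assert_allclose(fast.branch_gain, slow.branch_gain, atol=1e-10)
        np.testing.assert_allclose(fast.branch_loss, slow.branch_loss, atol=1e-10)
        np.testing.assert_allclose(fast.category_posterior, slow.category_posterior, atol=1e-10)
        assert fast.loglik == pytest.approx(slow.loglik, rel=1e-10, abs=1e-10)
        return fast

    def test_random_trees_and_models(self, rng):
        for trial in range(60):
            n_leaves = int(rng.integers(2, 7))
            tree = random_tree(rng, n_leaves)
            model = random_model(
                rng,
                tree.n_branches,
                two_cat=bool(trial % 2),
                condition=bool(trial % 3 == 0),
            )
            pattern = {n: int(rng.integers(0, 2)) for n in tree.leaf_names}
            self._compare(tree, model, pattern)

    def test_all_absent_unconditioned(self, five_leaf_tree, rng):
        model = random_model(rng, five_leaf_tree.n_branches)
        pattern = {n: 0 for n in five_leaf_tree.leaf_names}
        post = self._compare(five_leaf_tree, model, pattern)
        assert post.node_presence.max() < 1.0

    def test_deterministic_model_gives_binary_posteriors(self):
        t = cg.read_newick("(A,B);")
        eps = gl.PROB_FLOOR
        m = cg.GainLossModel([1 - eps, eps, eps], [eps] * 3, condition_on_observed=False)
        post = gl.posteriors({"A": 1, "B": 1}, t, m)
        np.testing.assert_allclose(post.branch_gain, [1, 0, 0], atol=1e-4)
        np.testing.assert_allclose(post.node_presence, 1.0, atol=1e-4)

    def test_half_half_two_leaf_hand_sum(self):
        # g = l = 0.5 everywhere: every transition equally likely
        t = cg.read_newick("(A,B);")
        m = cg.GainLossModel([0.5] * 3, [0.5] * 3, condition_on_observed=False)
        post = gl.posteriors({"A": 1, "B": 0}, t, m)
        # root state is 0 or 1 with prob .5 each; leaves fixed; all 4-term sums equal
        assert post.node_presence[0] == pytest.approx(0.5)
        assert post.branch_gain[0] == pytest.approx(0.5)
        slow = gl.brute_force_posteriors({"A": 1, "B": 0}, t, m)
        np.testing.assert_allclose(post.branch_gain, slow.branch_gain, atol=1e-12)

    def test_brute_force_refuses_large_trees(self, rng):
        tree = random_tree(rng, 12)
        if tree.n_nodes > 14:
            model = random_model(rng, tree.n_branches)
            with pytest.raises(ValueError):
                gl.brute_force_posteriors({n: 1 for n in tree.leaf_names}, tree, model)


class TestPosteriorInvariants:
    def test_event_and_marginal_consistency(self, rng):
        for _ in range(20):
            tree = random_tree(rng, int(rng.integers(2, 7)))
            model = random_model(rng, tree.n_branches, two_cat=True)
            pattern = {n: int(rng.integers(0, 2)) for n in tree.leaf_names}
            post = gl.posteriors(pattern, tree, model)
            assert (post.branch_gain + post.branch_loss <= 1 + 1e-10).all()
            # gain(b) <= presence(child) and <= 1 - presence(parent)
            for b in range(tree.n_branches):
                parent_presence = 0.0 if b == tree.root else post.node_presence[tree.parent[b]]
                assert post.branch_gain[b] <= post.node_presence[b] + 1e-10
                assert post.branch_gain[b] <= 1 - parent_presence + 1e-10

    def test_leaf_posteriors_match_observations(self, five_leaf_tree, rng):
        model = random_model(rng, five_leaf_tree.n_branches)
        pattern = {n: int(rng.integers(0, 2)) for n in five_leaf_tree.leaf_names}
        post = gl.posteriors(pattern, five_leaf_tree, model)
        for leaf in five_leaf_tree.leaves:
            assert post.node_presence[leaf] == pytest.approx(
                pattern[five_leaf_tree.names[leaf]], abs=1e-12
            )


class TestFitModel:
    def test_boundary_recovery_all_ones(self):
        t = cg.read_newick("((A,B),(C,D));")
        m = cg.PresenceMatrix(
            [f"f{i}" for i in range(60)], ["A", "B", "C", "D"], np.ones((60, 4), dtype=int)
        )
        with pytest.warns(UserWarning, match="ubiquitous"):
            fit = gl.fit_model(m, t, n_categories=1)
        assert fit.gain[0] > 0.99
        # origin-branch loss has no opportunity (parent always absent) and is
        # not identified; every real branch's loss must hit the floor
        assert fit.loss[1:].max() < 0.05

    def test_single_category_close_to_truth_loglik(self, rng):
        tree = cg.read_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        B = tree.n_branches
        truth = cg.GainLossModel(
            np.full(B, 0.15), np.full(B, 0.3), condition_on_observed=True
        )
        truth.gain[0] = 0.8
        mat, _ = cg.simulate_presence(tree, truth, 2000, seed=11)
        fit = gl.fit_model(mat, tree, n_categories=1)
        ll_truth = gl.matrix_loglik(mat, tree, truth)
        assert fit.loglik >= ll_truth - 2.0

    def test_likelihood_of_fit_beats_init(self, rng):
        tree = cg.read_newick("((A,B),(C,D));")
        B = tree.n_branches
        truth = cg.GainLossModel(np.full(B, 0.3), np.full(B, 0.3), condition_on_observed=False)
        mat, _ = cg.simulate_presence(tree, truth, 500, seed=3, condition_nonempty=False)
        mat = mat.drop_empty()
        init = cg.GainLossModel(
            np.full(B, 0.5), np.full(B, 0.5), condition_on_observed=True
        )
        fit = gl.fit_model(mat, tree, n_categories=1, init=init)
        assert fit.loglik >= gl.matrix_loglik(mat, tree, init)

    def test_conditioning_corrects_observability_bias(self):
        # data filtered to non-empty patterns: the unconditioned fit shrinks
        # ancestral presence (it buys likelihood by minimizing the mass it
        # puts on the never-observable all-absent pattern, which penalizes
        # gain-then-extinction histories); conditioning removes that penalty
        # and lands much closer to the simulated truth
        tree = cg.read_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        B = tree.n_branches
        truth = cg.GainLossModel(np.full(B, 0.05), np.full(B, 0.2))
        truth.gain[0] = 0.5  # modest root: many families unobservable
        mat, sim_truth = cg.simulate_presence(tree, truth, 3000, seed=21, condition_nonempty=True)
        true_root = sim_truth.states[:, 0].sum()

        fit_c = gl.fit_model(mat, tree, n_categories=1, condition_on_observed=True)
        fit_u = gl.fit_model(mat, tree, n_categories=1, condition_on_observed=False)
        root_c = gl.ancestral_sizes(gl.all_posteriors(mat, tree, fit_c)).expected_count[0]
        root_u = gl.ancestral_sizes(gl.all_posteriors(mat, tree, fit_u)).expected_count[0]
        assert abs(root_c - true_root) < abs(root_u - true_root)
        assert abs(root_c - root_u) > 0.1 * true_root  # the flag matters


class TestSummaries:
    def test_posterior_sum_semantics(self):
        posts = [
            gl.FamilyPosterior(
                node_presence=np.array([0.25, 1.0, 1.0]),
                branch_gain=np.zeros(3),
                branch_loss=np.zeros(3),
                category_posterior=np.array([1.0]),
                loglik=0.0,
            )
            for _ in range(8)
        ]
        summ = gl.ancestral_sizes(posts, threshold=0.9)
        assert summ.expected_count[0] == pytest.approx(2.0)
        assert summ.high_confidence_count[0] == 0

    def test_threshold_is_strict(self):
        post = gl.FamilyPosterior(
            node_presence=np.array([0.9]),
            branch_gain=np.zeros(1),
            branch_loss=np.zeros(1),
            category_posterior=np.array([1.0]),
            loglik=0.0,
        )
        summ = gl.ancestral_sizes([post], threshold=0.9)
        assert summ.high_confidence_count[0] == 0

    def test_expected_events_sums(self):
        posts = [
            gl.FamilyPosterior(
                node_presence=np.zeros(2),
                branch_gain=np.array([0.6, 0.1]),
                branch_loss=np.array([0.0, 0.2]),
                category_posterior=np.array([1.0]),
                loglik=0.0,
            ),
            gl.FamilyPosterior(
                node_presence=np.zeros(2),
                branch_gain=np.array([0.7, 0.0]),
                branch_loss=np.array([0.0, 0.5]),
                category_posterior=np.array([1.0]),
                loglik=0.0,
            ),
        ]
        summ = gl.expected_events(posts)
        np.testing.assert_allclose(summ.expected_gains, [1.3, 0.1])
        np.testing.assert_allclose(summ.family_gains, [0.7, 0.7])
        np.testing.assert_allclose(summ.expected_losses, [0.0, 0.7])

    def test_summary_table_trivial(self):
        out = gl.summary_table(100.0, 0.0, 100)
        assert out["acquisitions_per_family"] == 0.0
        assert out["loss_gain_ratio"] == 0.0
        zero = gl.summary_table(0.0, 5.0, 10)
        assert zero["loss_gain_ratio"] is None

    def test_genome_size_two_significant_figures(self):
        assert gl.genome_size_estimate(1725, 1.5) == 2600
        assert gl.round_sig(2212.4, 2) == 2200


def test_simulated_event_totals_within_monte_carlo_error():
    tree = cg.read_newick("(((A,B),(C,D)),((E,F),(G,H)));")
    B = tree.n_branches
    model = cg.GainLossModel(np.full(B, 0.2), np.full(B, 0.25), condition_on_observed=False)
    model.gain[0] = 0.7
    mat, truth = cg.simulate_presence(tree, model, 5000, seed=9, condition_nonempty=False)
    post = gl.all_posteriors(mat, tree, model)  # true model: posterior = conditional truth
    summ = gl.expected_events(post)
    for b in range(B):
        expected = summ.expected_gains[b]
        observed = truth.gains_per_branch[b]
        se = max(np.sqrt(expected), 1.0)
        assert abs(observed - expected) < 4 * se
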