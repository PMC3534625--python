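import numpy as np
import pytest
from scipy import stats

import cogevo as cg
from cogevo import gain_patterns as gp


def make_pattern(branches, total=None, fam="f"):
    branches = frozenset(branches)
    if total is None:
        total = float(len(branches))
    return gp.GainPattern(fam, branches, total)


def make_posterior(gains):
    gains = np.asarray(gains, dtype=float)
    return cg.FamilyPosterior(
        node_presence=np.zeros_like(gains),
        branch_gain=gains,
        branch_loss=np.zeros_like(gains),
        category_posterior=np.array([1.0]),
        loglik=0.0,
    )


class TestLikelyGains:
    def test_below_threshold_everywhere_is_zero_gain(self):
        pat = gp.likely_gains(make_posterior([0.4] * 6))
        assert pat.pattern_class == "zero-gain"
        assert pat.total_posterior_gain == pytest.approx(2.4)

    def test_single_strong_gain(self):
        pat = gp.likely_gains(make_posterior([0, 0.9, 0, 0]))
        assert pat.pattern_class == "single-gain"
        assert pat.likely_gain_branches == frozenset({1})

    def test_boundary_is_strict(self):
        pat = gp.likely_gains(make_posterior([0.5, 0.5001]))
        assert pat.likely_gain_branches == frozenset({1})

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        gains = rng.random(20)
        post = make_posterior(gains)
        prev = gp.likely_gains(post, threshold=0.1).likely_gain_branches
        for thr in (0.3, 0.5, 0.7, 0.9):
            cur = gp.likely_gains(post, threshold=thr).likely_gain_branches
            assert cur <= prev
            prev = cur


class TestPhyleticPatternTable:
    def test_counts(self):
        m = cg.PresenceMatrix(
            list("abcd"), list("AB"), [[1, 0], [1, 0], [1, 0], [0, 1]]
        )
        out = gp.phyletic_pattern_table(m)
        assert out["n_distinct"] == 2
        assert out["n_unique"] == 1
        assert out["unique_fraction_pct"] == 50

    def test_all_identical(self):
        m = cg.PresenceMatrix(list("ab"), list("AB"), [[1, 1], [1, 1]])
        out = gp.phyletic_pattern_table(m)
        assert (out["n_distinct"], out["n_unique"], out["unique_fraction_pct"]) == (1, 0, 0)

    def test_percentage_formula(self):
        assert gp.unique_fraction_percent(5998, 6736) == 89


class TestUbiquity:
    def test_identity_has_none(self):
        m = cg.PresenceMatrix(list("xyz"), list("ABC"), np.eye(3))
        assert gp.ubiquity_counts(m)["ubiquitous"] == 0

    def test_all_ones(self):
        m = cg.PresenceMatrix(list("abcde"), list("WXYZ"), np.ones((5, 4)))
        out = gp.ubiquity_counts(m, excluded_genome="X")
        assert out == {"ubiquitous": 5, "ubiquitous_excluding": 0}

    def test_exclusion_count(self):
        m = cg.PresenceMatrix(["f"], list("ABC"), [[1, 0, 1]])
        out = gp.ubiquity_counts(m, excluded_genome="B")
        assert out["ubiquitous_excluding"] == 1

    def test_unknown_genome_rejected(self):
        m = cg.PresenceMatrix(["f"], list("AB"), [[1, 1]])
        with pytest.raises(ValueError):
            gp.ubiquity_counts(m, excluded_genome="Q")


class TestGainCountDistribution:
    def _patterns_from_histogram(self, histogram):
        pats = []
        i = 0
        for n_gains, n_families in histogram.items():
            for _ in range(n_families):
                pats.append(make_pattern(range(n_gains), fam=f"f{i}"))
                i += 1
        return pats

    def test_exact_geometric_decay(self):
        pats = self._patterns_from_histogram({1: 800, 2: 400, 3: 200, 4: 100})
        out = gp.gain_count_distribution(pats)
        assert out["decay_rate"] == pytest.approx(np.log(2), abs=1e-6)
        assert out["single_gain_fraction"] == pytest.approx(800 / 1500)

    def test_all_single_gain(self):
        pats = self._patterns_from_histogram({1: 20})
        out = gp.gain_count_distribution(pats)
        assert out["single_gain_fraction"] == 1.0
        assert np.isnan(out["decay_rate"])  # no multi-gain tail to fit

    def test_kde_density_integrates(self):
        rng = np.random.default_rng(0)
        pats = [make_pattern([0], total=t) for t in rng.exponential(1.0, 200) + 0.5]
        out = gp.gain_count_distribution(pats)
        grid = np.linspace(0, 12, 600)
        mass = np.trapezoid(out["density"](grid), grid)
        assert mass == pytest.approx(1.0, abs=0.05)

    def test_too_few_patterns_rejected(self):
        with pytest.raises(ValueError):
            gp.gain_count_distribution([make_pattern([0])] * 5)


class TestMultigainStats:
    def test_perfectly_monotone(self):
        posts = [make_posterior(g) for g in ([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])]
        pats = [gp.likely_gains(p) for p in posts]
        out = gp.multigain_branch_stats(pats, posts)
        # branch totals vs multi-subset totals share the ordering
        assert out["rho_all"] in (1.0, pytest.approx(1.0))

    def test_hand_computed_rho(self):
        x = np.array([1, 2, 3, 4, 5])
        y = np.array([1, 3, 2, 5, 4])
        rho, _ = stats.spearmanr(x, y)
        assert rho == pytest.approx(0.8)

    def test_internal_branch_subset(self):
        rng = np.random.default_rng(3)
        posts = [make_posterior(rng.random(8) * 2) for _ in range(50)]
        pats = [gp.likely_gains(p) for p in posts]
        out = gp.multigain_branch_stats(pats, posts, internal_branches=range(4))
        assert -1 <= out["rho_internal"] <= 1

    def test_too_few_branches(self):
        posts = [make_posterior([1.0, 0.5])]
        with pytest.raises(ValueError):
            gp.multigain_branch_stats([gp.likely_gains(p) for p in posts], posts)


class TestTwoGainPairs:
    def test_pair_counted(self):
        pats = [make_pattern({3, 7}), make_pattern({3, 7}), make_pattern({2, 5})]
        t = gp.two_gain_pairs(pats)
        assert t.n2 == 3
        assert t.observed[frozenset({3, 7})] == 2

    def test_root_involvement_excluded(self):
        pats = [make_pattern({0, 7}), make_pattern({3, 7})]
        t = gp.two_gain_pairs(pats, root_branch=0)
        assert t.n2 == 1

    def test_three_gain_families_excluded(self):
        pats = [make_pattern({1, 2, 3})]
        assert gp.two_gain_pairs(pats).n2 == 0


class TestExpectedPairs:
    def test_symmetric_totals(self):
        pats = [make_pattern({1, 2})] * 10 + [make_pattern({1, 3})] * 10 + [make_pattern({2, 3})] * 10
        t = gp.two_gain_pairs(pats)
        out = gp.expected_pair_counts(t, [0.0, 5.0, 5.0, 5.0])
        assert all(v == pytest.approx(10.0) for v in out.expected.values())

    def test_product_normalization(self):
        t = gp.PairExchangeTable(n2=5, observed={})
        out = gp.expected_pair_counts(t, [0.0, 2.0, 1.0, 1.0])
        assert out.expected[frozenset({1, 2})] == pytest.approx(2.0)
        assert out.expected[frozenset({1, 3})] == pytest.approx(2.0)
        assert out.expected[frozenset({2, 3})] == pytest.approx(1.0)

    def test_expected_sums_to_n2(self):
        rng = np.random.default_rng(8)
        totals = np.concatenate([[0.0], rng.random(12) * 5])
        t = gp.PairExchangeTable(n2=321, observed={})
        out = gp.expected_pair_counts(t, totals)
        assert sum(out.expected.values()) == pytest.approx(321, abs=1e-9)

    def test_all_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            gp.expected_pair_counts(gp.PairExchangeTable(1, {}), [0.0, 0.0])

    def test_planted_null_gives_uniform_pvalues_and_high_rho(self):
        # plant transfers with pair probability proportional to product of totals
        rng = np.random.default_rng(17)
        totals = np.concatenate([[0.0], rng.uniform(1, 10, 25)])
        branches = np.arange(1, 26)
        import itertools

        pairs = list(itertools.combinations(branches, 2))
        probs = np.array([totals[i] * totals[j] for i, j in pairs])
        probs = probs / probs.sum()
        draws = rng.multinomial(4000, probs)
        pats = []
        for (i, j), n in zip(pairs, draws):
            pats.extend(make_pattern({int(i), int(j)}, fam=f"f{i}_{j}_{k}") for k in range(n))
        t = gp.two_gain_pairs(pats)
        out = gp.expected_pair_counts(t, totals)
        assert out.rho_observed_expected > 0.8
        pvals = np.array(list(out.pvalues.values()))
        # discrete Poisson p-values are super-uniform; check no excess of small ones
        assert (pvals < 0.01).mean() < 0.03


class TestPoissonPvalue:
    def test_zero_observed(self):
        assert gp.poisson_upper_pvalue(0, 3.7) == 1.0

    def test_partial_sum_example(self):
        assert gp.poisson_upper_pvalue(3, 1.0) == pytest.approx(
            1 - np.exp(-1) * (1 + 1 + 0.5), abs=1e-9
        )

    def test_matches_pmf_summation(self):
        mu, obs = 10.0, 10
        brute = sum(stats.poisson.pmf(k, mu) for k in range(obs, 200))
        assert gp.poisson_upper_pvalue(obs, mu) == pytest.approx(brute, abs=1e-12)

    def test_negative_observed_rejected(self):
        with pytest.raises(ValueError):
            gp.poisson_upper_pvalue(-1, 2.0)
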