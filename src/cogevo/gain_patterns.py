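"""Gain patterns and horizontal-transfer statistics from event posteriors.

A family's *likely-gain pattern* is the set of branches where its posterior
gain probability exceeds 0.5.  Families with zero, one, or several likely
gains correspond to un-placeable, vertically inherited (single acquisition)
and repeatedly exchanged genes respectively.  The two-gain families — exactly
two likely gains, neither on the origin-to-root branch — are the raw material
for within-domain transfer-route analysis: under random exchange, the count
for a branch pair should be proportional to the product of the two branches'
total gains, and departures are scored with an upper-tail Poisson p-value.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phylo_io import PresenceMatrix

__all__ = [
    "GainPattern",
    "PairExchangeTable",
    "likely_gains",
    "phyletic_pattern_table",
    "unique_fraction_percent",
    "ubiquity_counts",
    "gain_count_distribution",
    "multigain_branch_stats",
    "two_gain_pairs",
    "expected_pair_counts",
    "poisson_upper_pvalue",
]


@dataclass(frozen=True)
class GainPattern:
    """Likely-gain branch set for one family."""

    family_id: str
    likely_gain_branches: frozenset
    total_posterior_gain: float

    @property
    def n_gains(self) -> int:
        return len(self.likely_gain_branches)

    @property
    def pattern_class(self) -> str:
        if self.n_gains == 0:
            return "zero-gain"
        return "single-gain" if self.n_gains == 1 else "multi-gain"


def likely_gains(posterior, family_id: str = "", threshold: float = 0.5) -> GainPattern:
    """Branches with gain posterior strictly above the threshold.

    The total posterior gain sums over *all* branches regardless of the
    threshold — the thresholded set and the posterior sum answer different
    questions.
    """
    gains = np.asarray(posterior.branch_gain)
    return GainPattern(
        family_id=family_id,
        likely_gain_branches=frozenset(int(b) for b in np.nonzero(gains > threshold)[0]),
        total_posterior_gain=float(gains.sum()),
    )


def phyletic_pattern_table(matrix: PresenceMatrix) -> dict:
    """Distinct/unique phyletic-pattern statistics of a presence matrix."""
    if matrix.n_families == 0:
        raise ValueError("empty matrix")
    rows = [tuple(r) for r in matrix.values]
    freq = Counter(rows)
    n_distinct = len(freq)
    n_unique = sum(1 for c in freq.values() if c == 1)
    table = pd.Series(dict(freq)).sort_values(ascending=False)
    return {
        "n_distinct": n_distinct,
        "n_unique": n_unique,
        "unique_fraction_pct": unique_fraction_percent(n_unique, n_distinct),
        "frequency_table": table,
    }


def unique_fraction_percent(n_unique: int, n_distinct: int) -> int:
    """Share of patterns seen exactly once, as an integer percent."""
    if n_distinct <= 0:
        raise ValueError("n_distinct must be positive")
    return int(round(100.0 * n_unique / n_distinct))


def ubiquity_counts(matrix: PresenceMatrix, excluded_genome: str | None = None) -> dict:
    """Strictly ubiquitous families, and near-ubiquitous ones missing only
    the named genome."""
    totals = matrix.values.sum(axis=1)
    ubiquitous = int((totals == matrix.n_genomes).sum())
    near = 0
    if excluded_genome is not None:
        if excluded_genome not in matrix.genome_ids:
            raise ValueError(f"unknown genome: {excluded_genome!r}")
        col = matrix.genome_ids.index(excluded_genome)
        near = int(
            ((totals == matrix.n_genomes - 1) & (matrix.values[:, col] == 0)).sum()
        )
    return {"ubiquitous": ubiquitous, "ubiquitous_excluding": near}


def gain_count_distribution(patterns, min_patterns: int = 10) -> dict:
    """Distribution of gains per family: discrete, smoothed, and its decay.

    Returns the histogram of likely-gain counts, a Gaussian-kernel density
    (Silverman bandwidth) over the posterior gain sums, the exponential decay
    rate fitted by least squares on the log histogram over counts >= 1
    (zero-count bins skipped), and the single-gain fraction among families
    with at least one likely gain.
    """
    patterns = list(patterns)
    if len(patterns) < min_patterns:
        raise ValueError(f"need at least {min_patterns} patterns")
    counts = np.array([p.n_gains for p in patterns])
    totals = np.array([p.total_posterior_gain for p in patterns])
    hist = Counter(counts.tolist())

    ks = np.array(sorted(k for k in hist if k >= 1))
    ys = np.array([hist[k] for k in ks], dtype=float)
    decay = np.nan
    if len(ks) >= 2:
        slope, _ = np.polyfit(ks, np.log(ys), 1)
        decay = float(-slope)

    density = None
    if len(np.unique(totals)) > 1:
        density = stats.gaussian_kde(totals)  # Silverman bandwidth default

    with_gain = counts[counts >= 1]
    single_fraction = float((with_gain == 1).mean()) if with_gain.size else np.nan
    return {
        "histogram": dict(sorted(hist.items())),
        "decay_rate": decay,
        "density": density,
        "single_gain_fraction": single_fraction,
    }


def multigain_branch_stats(
    patterns, posteriors, internal_branches=None, multi_threshold: float = 1.5
) -> dict:
    """Correlation between branch totals of all gains vs multi-gain gains.

    Per branch: the summed posterior gain over all families, and over
    families whose total posterior gain exceeds ``multi_threshold``
    (multi-gain families).  Spearman rank correlation (average ranks on
    ties, large-sample t p-value) is reported for all branches and, when
    ``internal_branches`` (an id collection) is given, for those only.
    """
    gains = np.stack([p.branch_gain for p in posteriors])
    if gains.shape[1] < 5:
        raise ValueError("need at least 5 branches")
    totals = np.array([p.total_posterior_gain for p in patterns])
    multi_mask = totals > multi_threshold
    all_by_branch = gains.sum(axis=0)
    multi_by_branch = gains[multi_mask].sum(axis=0)

    def spear(x, y):
        if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
            return np.nan, np.nan
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)

    rho_all, p_all = spear(all_by_branch, multi_by_branch)
    out = {
        "total_gains_by_branch": all_by_branch,
        "multigain_gains_by_branch": multi_by_branch,
        "rho_all": rho_all,
        "p_all": p_all,
        "rho_internal": np.nan,
        "p_internal": np.nan,
    }
    if internal_branches is not None:
        idx = np.asarray(sorted(internal_branches), dtype=int)
        out["rho_internal"], out["p_internal"] = spear(
            all_by_branch[idx], multi_by_branch[idx]
        )
    return out


@dataclass
class PairExchangeTable:
    """Observed vs expected two-gain branch pairs under the random-exchange null."""

    n2: int
    observed: dict  # frozenset({i, j}) -> int
    expected: dict = field(default_factory=dict)  # frozenset -> float
    pvalues: dict = field(default_factory=dict)
    rho_observed_expected: float = np.nan
    p_observed_expected: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        pairs = sorted(set(self.observed) | set(self.expected), key=sorted)
        rows = []
        for pr in pairs:
            i, j = sorted(pr)
            rows.append(
                (i, j, self.observed.get(pr, 0), self.expected.get(pr, np.nan),
                 self.pvalues.get(pr, np.nan))
            )
        df = pd.DataFrame(rows, columns=["branch_i", "branch_j", "observed", "expected", "p"])
        ok = df["p"].notna()
        df["bh_q"] = np.nan
        if ok.any():
            df.loc[ok, "bh_q"] = stats.false_discovery_control(df.loc[ok, "p"], method="bh")
        return df


def two_gain_pairs(patterns, root_branch: int = 0) -> PairExchangeTable:
    """Count families with exactly two likely gains, neither at the root branch."""
    observed: Counter = Counter()
    for p in patterns:
        if p.n_gains == 2 and root_branch not in p.likely_gain_branches:
            observed[frozenset(p.likely_gain_branches)] += 1
    return PairExchangeTable(n2=sum(observed.values()), observed=dict(observed))


def expected_pair_counts(
    table: PairExchangeTable, branch_gain_totals, root_branch: int = 0
) -> PairExchangeTable:
    """Random-exchange expectations and Poisson p-values for pair counts.

    expected(i, j) = N2 · g_i·g_j / Σ_{k<l} g_k·g_l over branches with
    positive gain totals (root branch excluded), so expectations sum to N2.
    The observed/expected Spearman correlation is computed over pairs
    observed more than once.
    """
    g = np.asarray(branch_gain_totals, dtype=float)
    branches = [b for b in range(len(g)) if g[b] > 0 and b != root_branch]
    if not branches:
        raise ValueError("all branch gain totals are zero")
    denom = sum(g[i] * g[j] for i, j in itertools.combinations(branches, 2))
    if denom <= 0:
        raise ValueError("need at least two branches with positive gain totals")
    expected = {
        frozenset((i, j)): table.n2 * g[i] * g[j] / denom
        for i, j in itertools.combinations(branches, 2)
    }
    pvalues = {
        pr: poisson_upper_pvalue(table.observed.get(pr, 0), mu)
        for pr, mu in expected.items()
    }
    repeat = [pr for pr, c in table.observed.items() if c > 1 and pr in expected]
    rho = p = np.nan
    if len(repeat) >= 3:
        obs = [table.observed[pr] for pr in repeat]
        exp = [expected[pr] for pr in repeat]
        if len(np.unique(obs)) > 1 and len(np.unique(exp)) > 1:
            rho, p = stats.spearmanr(obs, exp)
    return PairExchangeTable(
        n2=table.n2,
        observed=dict(table.observed),
        expected=expected,
        pvalues=pvalues,
        rho_observed_expected=float(rho) if rho == rho else np.nan,
        p_observed_expected=float(p) if p == p else np.nan,
    )


def poisson_upper_pvalue(observed: int, expected: float) -> float:
    """P(X >= observed) for X ~ Poisson(expected), by the exact tail."""
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if observed == 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, expected))
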