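"""Synthetic data with known ground truth for every pipeline stage.

Three generators: presence/absence matrices evolved family-by-family under a
:class:`~cogevo.gainloss.GainLossModel` (with the true ancestral states and
event lists retained), commonality histograms drawn bin-wise from Poisson
counts around an exponential mixture, and all-vs-all hit tables with planted
ortholog groups over a background of noise hits.  All randomness flows from a
single integer seed through ``numpy.random.default_rng``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import HitTable
from .commonality import CommonalityHistogram, mixture_curve
from .gainloss import GainLossModel
from .phylo_io import Phylogeny, PresenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationTruth",
    "simulate_presence",
    "simulate_commonality",
    "simulate_hit_table",
    "balanced_tree",
    "reference_gainloss_study",
]


@dataclass
class SimulationTruth:
    """Complete record of a forward simulation.

    ``states[f, n]`` is the true state of family f at node n; ``gain_events``
    and ``loss_events`` mark branches (entering node n) on which the family
    flipped 0→1 / 1→0; ``n_rejected`` counts all-absent redraws when
    conditioning on non-empty patterns.
    """

    states: np.ndarray
    gain_events: np.ndarray
    loss_events: np.ndarray
    categories: np.ndarray
    model: GainLossModel
    seed: int
    n_rejected: int = 0

    @property
    def gains_per_branch(self) -> np.ndarray:
        return self.gain_events.sum(axis=0)

    @property
    def losses_per_branch(self) -> np.ndarray:
        return self.loss_events.sum(axis=0)


def _evolve(tree: Phylogeny, model: GainLossModel, categories: np.ndarray, rng) -> np.ndarray:
    """Sample states (F, N) down the tree; origin fixed absent."""
    F = categories.shape[0]
    N = tree.n_nodes
    states = np.zeros((F, N), dtype=np.int8)
    cat_g = np.stack([model.category_probs(c)[0] for c in range(model.n_categories)])
    cat_l = np.stack([model.category_probs(c)[1] for c in range(model.n_categories)])
    g = cat_g[categories]  # (F, N)
    l = cat_l[categories]
    for node in tree.preorder():
        parent_state = np.zeros(F, dtype=np.int8) if node == tree.root else states[:, tree.parent[node]]
        u = rng.random(F)
        gained = (parent_state == 0) & (u < g[:, node])
        kept = (parent_state == 1) & (u >= l[:, node])
        states[:, node] = (gained | kept).astype(np.int8)
    return states


def simulate_presence(
    tree: Phylogeny,
    model: GainLossModel,
    n_families: int,
    seed: int,
    condition_nonempty: bool = True,
    family_prefix: str = "fam",
    max_reject_fraction: float = 0.999,
) -> tuple:
    """Evolve families down the tree; returns (PresenceMatrix, SimulationTruth).

    Each family draws a rate category, then runs the two-state chain from the
    absent origin over every branch.  With ``condition_nonempty`` families
    absent from every leaf are redrawn by rejection (count logged), matching
    what an observability-conditioned fit assumes about the data.
    """
    if n_families <= 0:
        raise ValueError("n_families must be positive")
    rng = np.random.default_rng(seed)
    categories = rng.choice(model.n_categories, size=n_families, p=model.weights)
    states = _evolve(tree, model, categories, rng)
    leaf_ids = tree.leaves
    n_rejected = 0
    if condition_nonempty:
        for _ in range(10_000):
            empty = states[:, leaf_ids].sum(axis=1) == 0
            if not empty.any():
                break
            n_rejected += int(empty.sum())
            if n_rejected > max_reject_fraction * (n_rejected + n_families) and n_rejected > 1000:
                raise RuntimeError(
                    f"rejection rate too high ({n_rejected} redraws): the model "
                    "almost never produces an observable family"
                )
            categories[empty] = rng.choice(model.n_categories, size=int(empty.sum()), p=model.weights)
            states[empty] = _evolve(tree, model, categories[empty], rng)
        if n_rejected:
            logger.info("redrew %d all-absent families", n_rejected)

    parent_states = np.zeros_like(states)
    parent_states[:, 1:] = states[:, tree.parent[1:]]  # preorder: parent[i] < i
    parent_states[:, tree.root] = 0  # origin
    gain_events = (parent_states == 0) & (states == 1)
    loss_events = (parent_states == 1) & (states == 0)

    matrix = PresenceMatrix(
        family_ids=[f"{family_prefix}{i:05d}" for i in range(n_families)],
        genome_ids=list(tree.leaf_names),
        values=states[:, leaf_ids],
    )
    truth = SimulationTruth(
        states=states,
        gain_events=gain_events,
        loss_events=loss_events,
        categories=categories,
        model=model,
        seed=seed,
        n_rejected=n_rejected,
    )
    return matrix, truth


def simulate_commonality(components, G: int, seed: int) -> CommonalityHistogram:
    """Poisson counts around Σ a_i·exp(b_i·k) for k = 1..G.

    ``components`` is a list of (a_i, b_i); an empty list yields an all-zero
    histogram.
    """
    rng = np.random.default_rng(seed)
    k = np.arange(1, G + 1)
    if components:
        a = [c[0] for c in components]
        b = [c[1] for c in components]
        if any(x <= 0 for x in a):
            raise ValueError("amplitudes must be positive")
        mu = mixture_curve(a, b, k)
    else:
        mu = np.zeros(G)
    return CommonalityHistogram(G=G, counts=rng.poisson(mu))


def simulate_hit_table(
    n_genomes: int,
    n_groups: int,
    seed: int,
    genomes_per_group: int = 3,
    n_singletons_per_genome: int = 2,
    high_score: tuple = (200.0, 10.0),
    low_score_scale: float = 30.0,
    background_rate: float = 0.01,
    max_low_score: float | None = None,
) -> tuple:
    """Hit table with planted ortholog groups; returns (HitTable, true clusters).

    Every cross-genome pair within a planted group receives (both directions)
    a score from a Gaussian ``high_score = (mean, sd)``; background ordered
    cross-genome pairs appear with probability ``background_rate`` and an
    exponential score of scale ``low_score_scale``.  Setting ``max_low_score``
    below the smallest high score makes the supports disjoint, in which case
    triangle clustering must recover the planting exactly.
    """
    if genomes_per_group < 3:
        raise ValueError("planted groups need >= 3 genomes to seed triangles")
    if genomes_per_group > n_genomes:
        raise ValueError("genomes_per_group exceeds n_genomes")
    rng = np.random.default_rng(seed)
    genomes = [f"g{j:02d}" for j in range(n_genomes)]
    gene_genome: dict = {}
    true_clusters: dict = {}
    records = []

    for gi in range(n_groups):
        members_genomes = sorted(rng.choice(n_genomes, size=genomes_per_group, replace=False))
        members = []
        for j in members_genomes:
            gene = f"{genomes[j]}_grp{gi:03d}"
            gene_genome[gene] = genomes[j]
            members.append(gene)
        true_clusters[f"true{gi:03d}"] = frozenset(members)
        for x in members:
            for y in members:
                if x != y:
                    mu, sd = high_score
                    records.append((x, y, max(float(rng.normal(mu, sd)), 1e-3)))

    for j in range(n_genomes):
        for s in range(n_singletons_per_genome):
            gene = f"{genomes[j]}_sng{s:03d}"
            gene_genome[gene] = genomes[j]

    # background noise is one-directional: a spurious alignment found from x's
    # side need not be found from y's, so noise almost never forms mutual best
    # pairs and the planted groups remain the exact triangle-cluster solution
    genes = sorted(gene_genome)
    if background_rate > 0:
        for x in genes:
            for y in genes:
                if x == y or gene_genome[x] == gene_genome[y]:
                    continue
                if rng.random() < background_rate:
                    sc = float(rng.exponential(low_score_scale))
                    if max_low_score is not None:
                        sc = min(sc, max_low_score)
                    records.append((x, y, max(sc, 1e-3)))

    df = pd.DataFrame(records, columns=["query", "subject", "score"])
    return HitTable(df, gene_genome), true_clusters


def reference_gainloss_study(loss_gain_ratio: float = 4.0) -> tuple:
    """The package's standard parameter-recovery study design.

    A 16-leaf balanced tree under a genome-streamlining regime: a gene-rich
    root (origin-branch gain 0.9), rare subsequent gains (0.02 per branch),
    slow internal loss (0.05) and heavy terminal loss, with a 2-category rate
    mixture (multipliers 1 and 2, weights 0.75/0.25).  The terminal loss
    probability is solved so the expected loss/gain event ratio of the mixed
    process equals ``loss_gain_ratio`` exactly.  Returns (tree, model).
    """
    from scipy.optimize import brentq

    from .gainloss import expected_event_rates

    tree = balanced_tree(4)
    B = tree.n_branches
    leaves = set(tree.leaves)

    def make(l_term: float) -> GainLossModel:
        g = np.full(B, 0.02)
        g[tree.root] = 0.9
        l = np.array([l_term if i in leaves else 0.05 for i in range(B)])
        return GainLossModel(
            g, l, multipliers=np.array([1.0, 2.0]), weights=np.array([0.75, 0.25])
        )

    def excess(l_term: float) -> float:
        eg, el = expected_event_rates(tree, make(l_term))
        return el.sum() / eg.sum() - loss_gain_ratio

    l_term = brentq(excess, 0.05, 0.99, xtol=1e-12)
    return tree, make(l_term)


def balanced_tree(depth: int, branch_length: float = 1.0, prefix: str = "L") -> Phylogeny:
    """Strictly bifurcating balanced tree with 2**depth leaves (test scaffold)."""
    names: list = [None]
    parent = [-1]
    children: list = [[]]
    blens = [branch_length]

    def grow(node: int, level: int):
        if level == depth:
            names[node] = f"{prefix}{len([n for n in names if n])}"
            return
        for _ in range(2):
            cid = len(names)
            names.append(None)
            parent.append(node)
            children.append([])
            blens.append(branch_length)
            children[node].append(cid)
            grow(cid, level + 1)

    grow(0, 0)
    # relabel leaves deterministically in preorder
    count = 0
    for i in range(len(names)):
        if not children[i]:
            names[i] = f"{prefix}{count:03d}"
            count += 1
        else:
            names[i] = None
    tree = Phylogeny(
        names=names,
        parent=np.asarray(parent, dtype=int),
        children=children,
        branch_lengths=np.asarray(blens, dtype=float),
    )
    tree.validate()
    return tree
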