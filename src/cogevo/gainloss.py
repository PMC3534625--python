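"""Maximum-likelihood gene gain/loss reconstruction on a rooted phylogeny.

The model is a two-state (absent/present) Markov process running down every
branch of a rooted tree, with branch-specific gain probability ``g_b`` and
loss probability ``l_b``.  The state above the root ("origin") is fixed
*absent*: a family present anywhere must have been gained at least once, and a
gain on the origin-to-root branch is a gain in the last common ancestor.

Rate heterogeneity across families uses a discrete mixture: category ``c``
multiplies every branch's gain and loss *intensity* by ``m_c`` (``m_1 = 1``
by convention), i.e. ``g_b^(c) = 1 - (1 - g_b)^{m_c}`` and likewise for loss.
Family likelihoods are mixed over categories with weights ``w_c``.

Because families absent from every genome can never be observed, the
likelihood can be conditioned on observability: ``L / (1 - L_empty)`` where
``L_empty`` is the probability of the all-absent pattern.  This is on by
default; fitting unconditioned models to data from which empty patterns were
filtered overestimates ancestral presence.

Posteriors of ancestral states and of per-branch gain/loss *events* come from
the standard inward (pruning) and outward (up-down) dynamic programs, giving
exact marginals; a brute-force enumerator over complete ancestral state
assignments is provided as an independent oracle for small trees.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .phylo_io import Phylogeny, PresenceMatrix

__all__ = [
    "GainLossModel",
    "FamilyPosterior",
    "ReconstructionSummary",
    "branch_matrix",
    "family_loglik",
    "matrix_loglik",
    "fit_model",
    "posteriors",
    "all_posteriors",
    "brute_force_posteriors",
    "ancestral_sizes",
    "expected_events",
    "expected_event_rates",
    "summary_table",
    "genome_size_estimate",
    "round_sig",
]

PROB_FLOOR = 1e-6
PROB_CEIL = 1.0 - 1e-6


@dataclass
class GainLossModel:
    """Branch-specific two-state gain/loss model with a discrete rate mixture.

    ``gain[b]`` / ``loss[b]`` are category-1 branch transition probabilities,
    indexed by the node the branch enters (``b = 0`` is the origin-to-root
    branch).  ``multipliers`` holds the per-category intensity scalers
    (``multipliers[0] == 1``); ``weights`` the mixture weights.
    """

    gain: np.ndarray
    loss: np.ndarray
    multipliers: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    weights: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    condition_on_observed: bool = True
    loglik: float | None = None
    converged: bool | None = None

    def __post_init__(self):
        self.gain = np.atleast_1d(np.asarray(self.gain, dtype=float))
        self.loss = np.atleast_1d(np.asarray(self.loss, dtype=float))
        self.multipliers = np.atleast_1d(np.asarray(self.multipliers, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.gain.shape != self.loss.shape:
            raise ValueError("gain and loss must have one entry per branch each")
        if self.multipliers.shape != self.weights.shape:
            raise ValueError("one weight per category required")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if ((self.gain < 0) | (self.gain > 1) | (self.loss < 0) | (self.loss > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_branches(self) -> int:
        return self.gain.shape[0]

    @property
    def n_categories(self) -> int:
        return self.multipliers.shape[0]

    def category_probs(self, c: int):
        """Per-branch (gain, loss) probabilities under category ``c``."""
        m = self.multipliers[c]
        g = 1.0 - (1.0 - self.gain) ** m
        l = 1.0 - (1.0 - self.loss) ** m
        return g, l


def branch_matrix(g: float, l: float) -> np.ndarray:
    """2×2 transition matrix over (absent, present): rows sum to 1."""
    if not (0.0 <= g <= 1.0 and 0.0 <= l <= 1.0):
        raise ValueError("gain and loss probabilities must lie in [0, 1]")
    return np.array([[1.0 - g, g], [l, 1.0 - l]])


def _category_matrices(tree: Phylogeny, model: GainLossModel, c: int) -> np.ndarray:
    g, l = model.category_probs(c)
    P = np.empty((tree.n_nodes, 2, 2))
    P[:, 0, 0] = 1.0 - g
    P[:, 0, 1] = g
    P[:, 1, 0] = l
    P[:, 1, 1] = 1.0 - l
    return P


def _patterns_array(tree: Phylogeny, matrix: PresenceMatrix) -> np.ndarray:
    """(n_families, n_nodes-slots) leaf observations aligned to node ids."""
    if set(matrix.genome_ids) != set(tree.leaf_names):
        raise ValueError("matrix genomes do not match tree leaves")
    aligned = matrix.reorder_genomes(tree.leaf_names)
    obs = np.full((aligned.n_families, tree.n_nodes), -1, dtype=np.int8)
    for k, leaf in enumerate(tree.leaves):
        obs[:, leaf] = aligned.values[:, k]
    return obs


def _down_pass(tree: Phylogeny, P: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Inward (pruning) pass.

    Returns D of shape (F, N, 2): probability of the data at/below each node
    given the node's state.
    """
    F, N = obs.shape[0], tree.n_nodes
    D = np.ones((F, N, 2))
    for node in tree.postorder():
        if tree.is_leaf(node):
            state = obs[:, node]
            D[:, node, 0] = state == 0
            D[:, node, 1] = state == 1
        else:
            acc = np.ones((F, 2))
            for child in tree.children[node]:
                # message from child at each parent state
                acc *= D[:, child, :] @ P[child].T
            D[:, node, :] = acc
    return D


def _category_likelihood(tree: Phylogeny, P: np.ndarray, obs: np.ndarray):
    D = _down_pass(tree, P, obs)
    L = D[:, tree.root, :] @ P[tree.root, 0, :]
    return L, D


def _empty_pattern(tree: Phylogeny) -> np.ndarray:
    obs = np.full((1, tree.n_nodes), -1, dtype=np.int8)
    for leaf in tree.leaves:
        obs[0, leaf] = 0
    return obs


def matrix_loglik(
    matrix: PresenceMatrix,
    tree: Phylogeny,
    model: GainLossModel,
    weights: np.ndarray | None = None,
):
    """Total log-likelihood of a presence matrix (optionally weighted rows)."""
    obs = _patterns_array(tree, matrix)
    per_family = _loglik_vector(tree, model, obs)
    if weights is None:
        return float(per_family.sum())
    return float(per_family @ weights)


def _loglik_vector(tree: Phylogeny, model: GainLossModel, obs: np.ndarray) -> np.ndarray:
    F = obs.shape[0]
    mix = np.zeros(F)
    empty = 0.0
    for c in range(model.n_categories):
        P = _category_matrices(tree, model, c)
        Lc, _ = _category_likelihood(tree, P, obs)
        mix += model.weights[c] * Lc
        if model.condition_on_observed:
            L0, _ = _category_likelihood(tree, P, _empty_pattern(tree))
            empty += model.weights[c] * L0[0]
    with np.errstate(divide="ignore"):
        out = np.log(mix)
    if model.condition_on_observed:
        out -= np.log1p(-empty)
    return out


def family_loglik(pattern, tree: Phylogeny, model: GainLossModel) -> float:
    """Log-likelihood of one family's presence/absence pattern.

    ``pattern`` maps leaf names to 0/1 (a dict or a sequence ordered as
    ``tree.leaf_names``).
    """
    obs = _pattern_to_obs(pattern, tree)
    return float(_loglik_vector(tree, model, obs)[0])


def _pattern_to_obs(pattern, tree: Phylogeny) -> np.ndarray:
    names = tree.leaf_names
    if isinstance(pattern, dict):
        missing = [n for n in names if n not in pattern]
        if missing or len(pattern) != len(names):
            raise ValueError(f"pattern leaves do not match tree leaves: missing {missing}")
        vec = [pattern[n] for n in names]
    else:
        vec = list(pattern)
        if len(vec) != len(names):
            raise ValueError("pattern length does not match leaf count")
    obs = np.full((1, tree.n_nodes), -1, dtype=np.int8)
    for leaf, v in zip(tree.leaves, vec):
        if v not in (0, 1):
            raise ValueError("pattern values must be 0 or 1")
        obs[0, leaf] = v
    return obs


@dataclass
class FamilyPosterior:
    """Exact marginal posteriors for one family.

    ``node_presence[i]`` is P(state at node i = present | data);
    ``branch_gain[b]`` / ``branch_loss[b]`` are the probabilities of a 0→1 /
    1→0 event on the branch entering node ``b`` (``b = 0``: the origin-to-root
    branch, whose parent state is the fixed-absent origin).
    """

    node_presence: np.ndarray
    branch_gain: np.ndarray
    branch_loss: np.ndarray
    category_posterior: np.ndarray
    loglik: float

    @property
    def total_gain(self) -> float:
        return float(self.branch_gain.sum())

    @property
    def total_loss(self) -> float:
        return float(self.branch_loss.sum())


def _category_posteriors(tree: Phylogeny, P: np.ndarray, obs: np.ndarray):
    """Up-down pass for one category.

    Returns (L, presence, gain, loss), each family-major, computed from the
    joint parent/child distributions on every branch.
    """
    F, N = obs.shape[0], tree.n_nodes
    L, D = _category_likelihood(tree, P, obs)
    U = np.zeros((F, N, 2))
    U[:, tree.root, :] = P[tree.root, 0, :]  # origin fixed absent
    gain = np.zeros((F, N))
    loss = np.zeros((F, N))
    presence = np.zeros((F, N))
    safe_L = np.where(L > 0, L, 1.0)

    for node in tree.preorder():
        kids = tree.children[node]
        if not kids:
            continue
        # child messages at each state of `node`
        msgs = [D[:, c, :] @ P[c].T for c in kids]  # each (F, 2)
        for j, child in enumerate(kids):
            sib = np.ones((F, 2))
            for k, m in enumerate(msgs):
                if k != j:
                    sib *= m
            parent_part = U[:, node, :] * sib  # (F,2): P(outside data, node state)
            # joint over (parent state s, child state t)
            joint = parent_part[:, :, None] * P[child][None, :, :] * D[:, child, None, :]
            U[:, child, :] = np.einsum("fst->ft", parent_part[:, :, None] * P[child][None, :, :])
            gain[:, child] = joint[:, 0, 1] / safe_L
            loss[:, child] = joint[:, 1, 0] / safe_L

    # origin-to-root branch events
    root_joint = P[tree.root, 0, :] * D[:, tree.root, :]  # parent(origin)=0
    gain[:, tree.root] = root_joint[:, 1] / safe_L
    loss[:, tree.root] = 0.0
    presence = U[:, :, 1] * D[:, :, 1] / safe_L[:, None]
    return L, presence, gain, loss


def all_posteriors(
    matrix: PresenceMatrix, tree: Phylogeny, model: GainLossModel
) -> list:
    """Posteriors for every family of a matrix (vectorized across families)."""
    obs = _patterns_array(tree, matrix)
    return _posteriors_from_obs(tree, model, obs)


def _posteriors_from_obs(tree: Phylogeny, model: GainLossModel, obs: np.ndarray) -> list:
    F = obs.shape[0]
    C = model.n_categories
    Ls = np.zeros((C, F))
    pres = np.zeros((C, F, tree.n_nodes))
    gains = np.zeros((C, F, tree.n_nodes))
    losses = np.zeros((C, F, tree.n_nodes))
    empty = 0.0
    for c in range(C):
        P = _category_matrices(tree, model, c)
        Ls[c], pres[c], gains[c], losses[c] = _category_posteriors(tree, P, obs)
        if model.condition_on_observed:
            L0, _ = _category_likelihood(tree, P, _empty_pattern(tree))
            empty += model.weights[c] * L0[0]
    wL = model.weights[:, None] * Ls  # (C, F)
    mix = wL.sum(axis=0)
    safe_mix = np.where(mix > 0, mix, 1.0)
    cat_post = wL / safe_mix  # Bayes over categories
    node_p = np.einsum("cf,cfn->fn", cat_post, pres)
    gain_p = np.einsum("cf,cfn->fn", cat_post, gains)
    loss_p = np.einsum("cf,cfn->fn", cat_post, losses)
    with np.errstate(divide="ignore"):
        ll = np.log(mix)
    if model.condition_on_observed:
        ll -= np.log1p(-empty)
    return [
        FamilyPosterior(
            node_presence=node_p[f],
            branch_gain=gain_p[f],
            branch_loss=loss_p[f],
            category_posterior=cat_post[:, f].copy(),
            loglik=float(ll[f]),
        )
        for f in range(F)
    ]


def posteriors(pattern, tree: Phylogeny, model: GainLossModel) -> FamilyPosterior:
    """Node-presence and branch-event posteriors for one family pattern."""
    obs = _pattern_to_obs(pattern, tree)
    return _posteriors_from_obs(tree, model, obs)[0]


def brute_force_posteriors(pattern, tree: Phylogeny, model: GainLossModel) -> FamilyPosterior:
    """Posteriors by exhaustive enumeration of ancestral state assignments.

    Independent of the dynamic programs above; exponential in the number of
    internal nodes, so refuses trees with more than 14 nodes.
    """
    if tree.n_nodes > 14:
        raise ValueError("brute force enumeration limited to trees with <= 14 nodes")
    obs = _pattern_to_obs(pattern, tree)[0]
    internals = tree.internal_nodes
    N = tree.n_nodes
    C = model.n_categories

    cat_L = np.zeros(C)
    pres = np.zeros((C, N))
    gains = np.zeros((C, N))
    losses = np.zeros((C, N))
    for c in range(C):
        P = _category_matrices(tree, model, c)
        for assign in itertools.product((0, 1), repeat=len(internals)):
            state = obs.copy()
            for node, s in zip(internals, assign):
                state[node] = s
            prob = P[tree.root, 0, state[tree.root]]
            for node in range(1, N):
                prob *= P[node, state[tree.parent[node]], state[node]]
            cat_L[c] += prob
            for node in range(N):
                if state[node] == 1:
                    pres[c, node] += prob
                ps = 0 if node == tree.root else state[tree.parent[node]]
                if ps == 0 and state[node] == 1:
                    gains[c, node] += prob
                elif ps == 1 and state[node] == 0:
                    losses[c, node] += prob

    wL = model.weights * cat_L
    mix = wL.sum()
    safe = mix if mix > 0 else 1.0
    cat_post = wL / safe
    # per-category event probabilities normalized by that category's likelihood
    safe_cl = np.where(cat_L > 0, cat_L, 1.0)
    node_p = cat_post @ (pres / safe_cl[:, None])
    gain_p = cat_post @ (gains / safe_cl[:, None])
    loss_p = cat_post @ (losses / safe_cl[:, None])
    ll = np.log(mix) if mix > 0 else -np.inf
    if model.condition_on_observed:
        empty = 0.0
        for c in range(C):
            P = _category_matrices(tree, model, c)
            L0, _ = _category_likelihood(tree, P, _empty_pattern(tree))
            empty += model.weights[c] * L0[0]
        ll -= np.log1p(-empty)
    return FamilyPosterior(
        node_presence=node_p,
        branch_gain=gain_p,
        branch_loss=loss_p,
        category_posterior=np.asarray(cat_post),
        loglik=float(ll),
    )


# ---------------------------------------------------------------------------
# model fitting


def _dollo_init(tree: Phylogeny, matrix: PresenceMatrix) -> tuple:
    """Dollo-parsimony event counts → initial branch probabilities.

    Each family is assigned a single gain on the branch entering the MRCA of
    its present leaves; within that clade a node is present iff it has a
    present descendant, and parent-present/child-absent branches count as
    losses.  Branch probabilities are the event counts over their
    opportunities with a half-count prior.
    """
    aligned = matrix.reorder_genomes(tree.leaf_names)
    leaf_col = {leaf: k for k, leaf in enumerate(tree.leaves)}
    N = tree.n_nodes
    F = aligned.n_families
    below = np.zeros((F, N), dtype=np.int32)
    for node in tree.postorder():
        if tree.is_leaf(node):
            below[:, node] = aligned.values[:, leaf_col[node]]
        else:
            below[:, node] = sum(below[:, c] for c in tree.children[node])
    gains = np.zeros(N)
    losses = np.zeros(N)
    opp_gain = np.zeros(N)
    opp_loss = np.zeros(N)
    for f in range(F):
        total = below[f, tree.root]
        if total == 0:
            continue
        mrca = tree.root
        while True:
            full = [c for c in tree.children[mrca] if below[f, c] == total]
            if len(full) != 1:
                break
            mrca = full[0]
        state = np.zeros(N, dtype=np.int8)
        stack = [mrca]
        while stack:
            v = stack.pop()
            if below[f, v] > 0:
                state[v] = 1
                stack.extend(tree.children[v])
        parent_state = np.zeros(N, dtype=np.int8)
        parent_state[1:] = state[tree.parent[1:]]
        absent_parent = parent_state == 0
        opp_gain += absent_parent
        gains += absent_parent & (state == 1)
        opp_loss += ~absent_parent
        losses += (~absent_parent) & (state == 0)
    g0 = np.clip((gains + 0.5) / (opp_gain + 1.0), 0.01, 0.95)
    l0 = np.clip((losses + 0.5) / (opp_loss + 1.0), 0.01, 0.95)
    return g0, l0


INTENSITY_LO = -np.log1p(-PROB_FLOOR)  # prob floor on the intensity scale
INTENSITY_HI = -np.log(1.0 - PROB_CEIL)


def _pack(model: GainLossModel) -> np.ndarray:
    gam = np.clip(-np.log1p(-np.clip(model.gain, PROB_FLOOR, PROB_CEIL)), INTENSITY_LO, INTENSITY_HI)
    lam = np.clip(-np.log1p(-np.clip(model.loss, PROB_FLOOR, PROB_CEIL)), INTENSITY_LO, INTENSITY_HI)
    x = [np.log(gam), np.log(lam)]
    if model.n_categories == 2:
        w2 = np.clip(model.weights[1], 1e-4, 1 - 1e-4)
        x.append([np.log(model.multipliers[1]), np.log(w2 / (1 - w2))])
    return np.concatenate(x)


def _unpack(x: np.ndarray, B: int, two_cat: bool, condition: bool) -> GainLossModel:
    gam = np.exp(x[:B])
    lam = np.exp(x[B : 2 * B])
    gain = np.clip(-np.expm1(-gam), PROB_FLOOR, PROB_CEIL)
    loss = np.clip(-np.expm1(-lam), PROB_FLOOR, PROB_CEIL)
    if two_cat:
        m2 = np.exp(x[2 * B])
        w2 = 1.0 / (1.0 + np.exp(-x[2 * B + 1]))
        mult = np.array([1.0, m2])
        wts = np.array([1.0 - w2, w2])
    else:
        mult = np.array([1.0])
        wts = np.array([1.0])
    return GainLossModel(gain, loss, mult, wts, condition_on_observed=condition)


def fit_model(
    matrix: PresenceMatrix,
    tree: Phylogeny,
    n_categories: int = 2,
    condition_on_observed: bool = True,
    max_iter: int = 500,
    tol_per_family: float = 1e-6,
    init: GainLossModel | None = None,
) -> GainLossModel:
    """Fit branch gain/loss probabilities (and the rate mixture) by ML.

    Optimizes the summed (optionally observability-conditioned) family
    log-likelihoods by L-BFGS on log-intensity transforms of the branch
    parameters.  Identical phyletic patterns are collapsed and weighted,
    which is exact and much faster.

    The likelihood surface carries a known near-flat ridge: presence at the
    root trades off against independent gains on the root's child branches
    (gain-at-root-then-loss-on-one-side and gain-on-the-other-side produce
    identical leaf data).  Initialization is therefore deterministic but
    multistarted along that ridge: a Dollo-parsimony start (one gain at each
    family's MRCA, losses counted from the implied states) plus the same
    start with the origin-branch gain pinned high and low; the best final
    likelihood wins, ties going to the Dollo start.
    """
    if n_categories not in (1, 2):
        raise ValueError("1 or 2 rate categories supported")
    if matrix.n_families == 0:
        raise ValueError("empty matrix")
    if matrix.n_families < 50:
        warnings.warn("fewer than 50 families: branch parameters will be noisy", stacklevel=2)
    if (matrix.values.sum(axis=1) == matrix.n_genomes).all():
        warnings.warn(
            "every family is ubiquitous: loss parameters are not identifiable", stacklevel=2
        )

    obs_full = _patterns_array(tree, matrix)
    uniq, counts = np.unique(obs_full, axis=0, return_counts=True)
    w = counts.astype(float)
    B = tree.n_branches
    two_cat = n_categories == 2

    if init is not None and init.n_categories != n_categories:
        raise ValueError("init model category count does not match n_categories")
    mult0 = np.array([1.0, 3.0]) if two_cat else np.array([1.0])
    wts0 = np.array([0.7, 0.3]) if two_cat else np.array([1.0])
    if init is not None:
        starts = [init]
    else:
        g0, l0 = _dollo_init(tree, matrix)
        starts = []
        for root_gain in (None, 0.9, 0.1):
            g = g0.copy()
            if root_gain is not None:
                g[tree.root] = root_gain
            starts.append(
                GainLossModel(g, l0, mult0, wts0, condition_on_observed=condition_on_observed)
            )

    def objective(x):
        model = _unpack(x, B, two_cat, condition_on_observed)
        ll = _loglik_vector(tree, model, uniq)
        if not np.isfinite(ll).all():
            return 1e12
        return -(ll @ w)

    n_param = 2 * B + (2 if two_cat else 0)
    bounds = [(np.log(INTENSITY_LO), np.log(INTENSITY_HI))] * (2 * B)
    if two_cat:
        bounds += [(np.log(1e-3), np.log(1e3)), (-12.0, 12.0)]
    total_w = w.sum()
    best = None
    for start in starts:
        x0 = _pack(start)
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": max_iter,
                "ftol": tol_per_family * total_w / max(1.0, abs(objective(x0))),
                "maxfun": max_iter * (n_param + 5),
            },
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    model = _unpack(best.x, B, two_cat, condition_on_observed)
    model.loglik = float(-best.fun)
    model.converged = bool(best.success)
    if not best.success:
        warnings.warn(f"optimizer did not report convergence: {best.message}", stacklevel=2)
    return model


# ---------------------------------------------------------------------------
# summaries


@dataclass
class ReconstructionSummary:
    """Node- and branch-level aggregates over a set of family posteriors."""

    expected_count: np.ndarray  # per node: sum of presence posteriors
    high_confidence_count: np.ndarray  # per node: families with posterior > threshold
    threshold: float
    expected_gains: np.ndarray  # per branch
    expected_losses: np.ndarray  # per branch
    family_gains: np.ndarray  # per family: total expected gains
    family_losses: np.ndarray


def ancestral_sizes(posterior_list, threshold: float = 0.9) -> ReconstructionSummary:
    """Expected and high-confidence ancestral family counts per node.

    The expected count at a node is the *sum of posterior presence
    probabilities* over families (eight families at posterior 0.25 contribute
    two expected families); the high-confidence count uses a strict
    ``> threshold`` rule.
    """
    pres = np.stack([p.node_presence for p in posterior_list])
    summary = expected_events(posterior_list)
    summary.expected_count = pres.sum(axis=0)
    summary.high_confidence_count = (pres > threshold).sum(axis=0)
    summary.threshold = threshold
    return summary


def expected_events(posterior_list) -> ReconstructionSummary:
    """Per-branch and per-family expected gain/loss event totals."""
    gains = np.stack([p.branch_gain for p in posterior_list])
    losses = np.stack([p.branch_loss for p in posterior_list])
    return ReconstructionSummary(
        expected_count=np.zeros(gains.shape[1]),
        high_confidence_count=np.zeros(gains.shape[1], dtype=int),
        threshold=np.nan,
        expected_gains=gains.sum(axis=0),
        expected_losses=losses.sum(axis=0),
        family_gains=gains.sum(axis=1),
        family_losses=losses.sum(axis=1),
    )


def expected_event_rates(tree: Phylogeny, model: GainLossModel) -> tuple:
    """Analytic per-branch expected gain/loss event probabilities per family.

    Propagates the marginal presence probability from the absent origin down
    the tree under the (unconditioned) mixed process: on branch b with parent
    presence p, E[gains] = (1-p)·g_b and E[losses] = p·l_b.  Useful for
    designing simulation studies with a prescribed event budget.
    """
    gains = np.zeros(tree.n_nodes)
    losses = np.zeros(tree.n_nodes)
    for c in range(model.n_categories):
        g, l = model.category_probs(c)
        p = np.zeros(tree.n_nodes)
        wc = model.weights[c]
        for node in tree.preorder():
            parent_p = 0.0 if node == tree.root else p[tree.parent[node]]
            gains[node] += wc * (1.0 - parent_p) * g[node]
            losses[node] += wc * parent_p * l[node]
            p[node] = (1.0 - parent_p) * g[node] + parent_p * (1.0 - l[node])
    return gains, losses


def summary_table(gains, losses, n_families: int) -> dict:
    """Domain-level gain/loss summary statistics.

    ``gains`` and ``losses`` may be per-family expected-event vectors or
    pre-summed scalar totals.  Reported values follow the conventional
    rounding: per-family rates and ratios to 2 decimals, fractions to integer
    percent.  ``acquisitions/family`` subtracts the one default gain each
    observed family must have ((gains − n)/n).  The single-gain fraction
    (families whose total expected gains fall below 1.5) requires the
    per-family vector and is ``None`` otherwise.
    """
    if n_families <= 0:
        raise ValueError("n_families must be positive")
    gain_vec = np.atleast_1d(np.asarray(gains, dtype=float))
    loss_vec = np.atleast_1d(np.asarray(losses, dtype=float))
    total_gains = float(gain_vec.sum())
    total_losses = float(loss_vec.sum())
    out = {
        "families": n_families,
        "gains": total_gains,
        "gains_per_family": round(total_gains / n_families, 2),
        "acquisitions_per_family": round((total_gains - n_families) / n_families, 2),
        "losses": total_losses,
        "losses_per_family": round(total_losses / n_families, 2),
        "loss_gain_ratio": round(total_losses / total_gains, 2) if total_gains > 0 else None,
        "single_gain_fraction_pct": None,
    }
    if gain_vec.size == n_families and gain_vec.size > 1:
        out["single_gain_fraction_pct"] = int(round(100.0 * (gain_vec < 1.5).mean()))
    return out


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention for sizes)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def genome_size_estimate(expected_families: float, genes_per_family: float = 1.5) -> float:
    """Extrapolate an ancestral genome size from an expected family count.

    Multiplies by the characteristic genes-per-family ratio of the extant
    genomes (default 1.5) and reports to two significant figures, the
    precision such an extrapolation supports.
    """
    return round_sig(expected_families * genes_per_family, 2)
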