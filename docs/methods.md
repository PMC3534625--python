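# Methods

## The gain/loss model

A gene family's evolution is a two-state (absent/present) Markov chain on a
rooted phylogeny. Every node — including the root — owns the branch entering
it; the root's branch descends from an implicit *origin* whose state is fixed
absent. Branch `b` carries free transition probabilities: gain
`g_b = P(0→1)` and loss `l_b = P(1→0)`. Branch parameters are free
probabilities, not rate × branch-length products: the guide tree contributes
topology only (its branch lengths seed nothing downstream), which matches how
branch-specific gain/loss rates are estimated in ancestral gene-content
reconstruction generally.

Rate heterogeneity across families is a discrete 2-point mixture acting on
branch *intensities*: with `γ_b = −ln(1−g_b)`, category `c` uses
`g_b^{(c)} = 1−exp(−m_c·γ_b)` (and likewise for loss), `m_1 ≡ 1`, `m_2 > 0`
free, weights summing to one. The multiplier scales gain and loss together —
a "fast" family is fast in both directions. A loss-only scaling variant would
be a small change to `GainLossModel.category_probs`; the joint scaling is the
default because nothing in the data the model sees (binary patterns)
identifies the asymmetric variant any better.

**Observability conditioning.** Families absent from every genome cannot be
observed, so by default the likelihood is `L/(1−L_∅)` with `L_∅` the mixture
probability of the all-absent pattern. The flag matters, and its direction of
effect is the opposite of what one might first guess: an *unconditioned* fit
to filtered data buys likelihood by minimizing the mass the model puts on the
all-absent pattern, which penalizes gain-then-extinction histories and
therefore *shrinks* ancestral presence estimates; conditioning removes that
penalty and restores approximately unbiased root sizes (this is tested
directionally). Conditioning is logged in every CLI run.

**Inference.** Felsenstein pruning over the two states gives per-family
likelihoods (identical phyletic patterns are collapsed and weighted — exact
and much faster). The outward (up-down) pass yields, per branch, the joint
posterior of the parent and child states, hence exact marginals: node
presence `P(state=1 | data)`, branch gain `P(parent=0, child=1 | data)` and
branch loss `P(parent=1, child=0 | data)`; on the origin→root branch the
parent is the fixed-absent origin, so a "gain at the last common ancestor" is
an ordinary branch event. Category posteriors come from Bayes' rule on the
per-category likelihoods and mix the event posteriors. A brute-force
enumerator over all ancestral state assignments (trees ≤ 14 nodes) is kept as
an independent oracle; the dynamic programs agree with it to ~1e-15 on random
instances.

**Optimization.** L-BFGS-B on log-intensity transforms (probabilities clipped
to [1e-6, 1−1e-6], category weight on a logit), stopping at 1e-6
log-likelihood per family or 500 iterations. The surface carries a known
near-flat ridge: a gain at the root followed by loss on one child branch
produces exactly the leaf data of a gain on the other child branch, so the
root gain trades off against the deep branch gains. Initialization is
therefore deterministic but multistarted across that ridge: a Dollo-parsimony
start (each family gained once at the MRCA of its present leaves; losses
counted from the implied states; probabilities = events/opportunities with a
half-count prior) plus the same start with the origin-branch gain pinned at
0.9 and at 0.1; the best final likelihood wins. On small trees (≤ 8 leaves)
the ridge is empirically *flat* — per-start likelihoods agree to < 0.1 units
while root-size estimates differ two-fold — so root sizes from small trees
should not be trusted; event totals and their ratios remain well identified.
On the 16-leaf reference design (below) the ridge is resolved and root sizes
recover to a few percent.

**Summaries.** Ancestral size at a node is the sum over families of presence
posteriors (eight families at posterior 0.25 contribute two expected
families); the high-confidence count applies a strict `> 0.9`. Per-branch
expected gains/losses are sums of event posteriors. The domain-level summary
reports gains/family, acquisitions/family `(gains−n)/n` (subtracting each
observed family's one default gain), losses/family, the loss/gain ratio (2
decimals each) and the percentage of families with total expected gains below
1.5 ("single-gain"). The ancestral genome-size extrapolation multiplies the
expected family count by a genes-per-family ratio (default 1.5, the
characteristic paralogy level of prokaryotic genomes) and rounds to two
significant figures — the precision such an extrapolation supports.

## Commonality decomposition

The commonality histogram (families present in exactly `k` of `G` genomes) is
fit with `Σᵢ aᵢ·exp(bᵢ·k)` by minimizing the Poisson deviance — counts are
counts, and least squares on log counts breaks on empty bins. Exponents are
bounded to |b| ≤ 2: one unit of `k` is one genome, and decay faster than
e²-fold per genome is not identifiable from integer `k`. The fit is
multistarted (default 20, seeded) from log-linear fits anchored on equal
thirds of the k-range plus jitter; components are reported ordered by
exponent, which with three components assigns the cloud/shell/core labels.
Component sizes are the discrete integrals over `k = 1..G`, reported exactly
and at two significant figures.

## Clustering

Best hits are per (gene, foreign genome), ties broken to the
lexicographically smallest subject id (determinism; the choice is otherwise
arbitrary). Triangles of symmetric best hits spanning three distinct genomes
seed clusters; triangles merge when they share an *edge* — vertex-sharing
over-merges through promiscuous genes. Because a gene can sit in two
edge-disjoint triangle components, disjointness is enforced by assigning such
a gene to the component holding its strongest incident best-hit edge (tie:
smallest cluster id). The complementary-pattern merge accepts a pair when the
genome overlap relative to the smaller pattern is ≤ `overlap_max` (default
0.2) and the mean cross-cluster best-hit score is ≥ `link_score_min` (default
the 90th percentile of non-BBH background scores), applied to fixpoint,
strongest link first. Profile-based cluster extension (an external search
engine's job) is out of scope; its effect can be supplied via a pre-extended
hit table.

## Synthetic data

`simulate_presence` draws a rate category per family and runs the chain from
the absent origin down every branch, recording all true states and events;
conditioning on non-empty patterns is by rejection, with the redraw count
kept so observability-bias experiments can use it. `simulate_commonality`
draws independent Poisson counts around an exponential mixture.
`simulate_hit_table` plants ortholog groups (all cross-genome member pairs
scored from a Gaussian high distribution, both directions) over background
noise scored from an exponential low distribution. Background records are
emitted *one-directionally*: a spurious alignment found from one side is not
reciprocated, so noise essentially never forms mutual-best pairs and the
planted groups are the exact triangle-cluster solution whenever the score
supports are disjoint (`max_low_score` below the high distribution's
support). What the generator does not emulate: sequence-level similarity
structure, genuinely asymmetric evolutionary rates between group members,
paralogy within genomes, and donor→acceptor transfer paths (transfers appear
as independent gains, which is all the inference could see anyway). Passing
tests therefore validate the algorithms' contracts, not the biological
fidelity of any particular score model.

## The reference recovery study

`reference_gainloss_study()` is the package's standard simulate-and-refit
design: a balanced 16-leaf tree under a genome-streamlining regime — origin
gain 0.9 (a gene-rich ancestor), background gain 0.02 per branch, internal
loss 0.05 and heavy terminal loss, 2-category mixture (multipliers 1 and 2,
weights 0.75/0.25). The terminal loss probability is solved by 1-D root
finding on the process's analytic expected event counts so the true
loss/gain event ratio is exactly 4.0. Loss concentrated on terminal branches
is both the regime that reaches a four-fold loss excess on a shallow tree
(each internal loss silences a whole subtree and caps the loss budget) and
the well-identified one (terminal losses are directly visible in the leaf
data). At 5,000 families the refit recovers the event-total ratio within a
few percent and the root expected size within ~2-5% of the simulated truth
across seeds.

## Numerical choices and degenerate inputs

- Probabilities clipped to [1e-6, 1−1e-6] after fitting; the origin-branch
  *loss* has no opportunity (its parent is always absent) and is reported at
  whatever the optimizer leaves — it is meaningless and documented as such.
- All-ubiquitous matrices fit but warn: losses sit at the clip floor, not
  identified.
- Thresholds are strict everywhere: likely gain `> 0.5`, high confidence
  `> 0.9`, multi-gain by posterior sum `> 1.5`.
- Two-gain pair expectations are normalized to sum to `N2` (the count of
  two-gain families); only proportionality to the product of branch gains is
  inherent, so p-values depend on this normalization — stated prominently.
  The `> 1` occurrence filter applies only to the observed/expected
  correlation, not to which pairs get expectations.
- Poisson upper p-values use the exact regularized-gamma tail, never a normal
  approximation. Benjamini–Hochberg q-values are emitted alongside raw
  p-values; no correction is applied to the p-values themselves.
- The gain-count decay rate is least squares on log histogram counts over
  gain counts ≥ 1, skipping empty bins; it is NA when fewer than two bins
  exist. The kernel density over posterior gain sums uses a Gaussian kernel
  with Silverman bandwidth.
- Matrix cells > 1 are binarized with a warning (paralogs are out of model
  scope); pruning a tree to match a matrix suppresses unary nodes and sums
  their branch lengths, never removing the root.

## Known limitations

- No copy-number/duplication modelling, no continuous (gamma) rate variation,
  no tree inference or root-position testing: the tree is an input.
- Root-size estimates on trees much smaller than ~16 leaves sit on a flat
  likelihood ridge (above) and carry little information.
- The clustering stage operates on a provided hit table; alignment, PSSM
  construction and multi-domain splitting are external concerns.
- Commonality component counts are a user choice; no model selection over
  the number of exponentials is attempted, and no error bars are put on the
  component integrals.
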