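"""COG-style ortholog clustering from all-vs-all similarity hits.

The classical construction: per-genome best hits → symmetric (bidirectional)
best-hit pairs → triangles of symmetric best hits spanning three genomes →
clusters grown by merging triangles that share an *edge* (vertex overlap alone
does not merge — promiscuous genes would chain unrelated clusters together).
A final optional pass merges clusters whose phyletic patterns are
approximately complementary and whose members are highly similar across the
cluster boundary, recovering families split by long-branch attraction of the
similarity scores.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HitTable",
    "OrthologClusterSet",
    "read_hit_table",
    "best_hits",
    "symmetric_best_hits",
    "triangle_clusters",
    "merge_complementary",
    "genome_coverage",
]


@dataclass
class HitTable:
    """All-vs-all similarity records plus the gene → genome assignment."""

    records: pd.DataFrame  # columns: query, subject, score
    gene_genome: dict  # gene id -> genome id

    def __post_init__(self):
        required = {"query", "subject", "score"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"hit table needs columns {sorted(required)}")
        genes = set(self.records["query"]) | set(self.records["subject"])
        unmapped = genes - set(self.gene_genome)
        if unmapped:
            raise ValueError(f"genes without a genome assignment: {sorted(unmapped)[:5]}")
        if (self.records["score"] < 0).any():
            raise ValueError("scores must be non-negative")
        self_hits = self.records["query"] == self.records["subject"]
        if self_hits.any():
            logger.info("dropped %d self-hit records", int(self_hits.sum()))
            self.records = self.records.loc[~self_hits].reset_index(drop=True)

    @property
    def genes(self) -> set:
        return set(self.gene_genome)

    @property
    def genomes(self) -> set:
        return set(self.gene_genome.values())


def read_hit_table(hits_text: str, gene_map_text: str) -> HitTable:
    """Read hits + gene map from TSV text.

    Hits may be 3 columns (query, subject, score) or 12-column BLAST
    tabular rows, in which case the bit score (last column) is used.
    The gene map is two columns: gene id, genome id.
    """
    df = pd.read_csv(io.StringIO(hits_text), sep="\t", header=None, comment="#")
    if df.shape[1] == 3:
        df.columns = ["query", "subject", "score"]
    elif df.shape[1] == 12:
        df = df.iloc[:, [0, 1, 11]]
        df.columns = ["query", "subject", "score"]
    else:
        raise ValueError(f"expected 3 or 12 columns in hit table, got {df.shape[1]}")
    gm = pd.read_csv(io.StringIO(gene_map_text), sep="\t", header=None, comment="#")
    if gm.shape[1] != 2:
        raise ValueError("gene map must have two columns: gene, genome")
    mapping = dict(zip(gm.iloc[:, 0].astype(str), gm.iloc[:, 1].astype(str)))
    df["query"] = df["query"].astype(str)
    df["subject"] = df["subject"].astype(str)
    return HitTable(df, mapping)


@dataclass
class OrthologClusterSet:
    """Disjoint gene clusters with derived phyletic patterns."""

    clusters: dict  # cluster id -> frozenset of gene ids
    unassigned: set
    gene_genome: dict

    def pattern(self, cid) -> frozenset:
        """Genome set covered by a cluster."""
        return frozenset(self.gene_genome[g] for g in self.clusters[cid])

    @property
    def assigned(self) -> set:
        return set().union(*self.clusters.values()) if self.clusters else set()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (cid, g, self.gene_genome[g])
            for cid in sorted(self.clusters)
            for g in sorted(self.clusters[cid])
        ]
        return pd.DataFrame(rows, columns=["cluster", "gene", "genome"])


def best_hits(hits: HitTable) -> dict:
    """(gene, foreign genome) → single highest-scoring subject gene.

    Hits into the gene's own genome are ignored; score ties break to the
    lexicographically smallest subject id, making the map deterministic.
    """
    if hits.records.empty:
        raise ValueError("empty hit table")
    df = hits.records.copy()
    df["sgenome"] = df["subject"].map(hits.gene_genome)
    df["qgenome"] = df["query"].map(hits.gene_genome)
    df = df[df["sgenome"] != df["qgenome"]]
    df = df.sort_values(["query", "sgenome", "score", "subject"], ascending=[True, True, False, True])
    top = df.drop_duplicates(subset=["query", "sgenome"], keep="first")
    return {(q, g): s for q, g, s in zip(top["query"], top["sgenome"], top["subject"])}


def symmetric_best_hits(best: dict, gene_genome: dict) -> set:
    """Unordered gene pairs that are mutually each other's genome-best hit."""
    pairs = set()
    for (q, _), s in best.items():
        if best.get((s, gene_genome[q])) == q:
            pairs.add(frozenset((q, s)))
    return pairs


def _bbh_scores(bbh: set, hits: HitTable) -> dict:
    """Mean directed score per BBH pair (used for deterministic tie-breaks)."""
    lookup = hits.records.groupby(["query", "subject"])["score"].max()
    out = {}
    for pair in bbh:
        a, b = sorted(pair)
        vals = [lookup.get((a, b)), lookup.get((b, a))]
        vals = [v for v in vals if v is not None and not np.isnan(v)]
        out[pair] = float(np.mean(vals)) if vals else 0.0
    return out


def triangle_clusters(bbh: set, gene_genome: dict, hits: HitTable | None = None) -> OrthologClusterSet:
    """Clusters from triangles of symmetric best hits.

    All 3-cliques of the BBH graph whose members lie in three distinct
    genomes seed the clusters; triangles sharing an edge are merged
    transitively.  A gene claimed by several triangle components (vertex-only
    overlap) is assigned to the component holding its strongest incident BBH
    edge, keeping clusters disjoint; ties break to the smallest cluster id.
    """
    G = nx.Graph()
    G.add_nodes_from(gene_genome)
    for pair in bbh:
        a, b = tuple(pair)
        G.add_edge(a, b)

    triangles = []
    for a, b in G.edges():
        for c in sorted(set(G[a]) & set(G[b])):
            tri = tuple(sorted((a, b, c)))
            if len({gene_genome[x] for x in tri}) == 3:
                triangles.append(tri)
    triangles = sorted(set(triangles))

    # union-find over triangles sharing an edge
    parent = list(range(len(triangles)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    edge_to_tris: dict = {}
    for t_idx, tri in enumerate(triangles):
        for e in ((tri[0], tri[1]), (tri[0], tri[2]), (tri[1], tri[2])):
            edge_to_tris.setdefault(e, []).append(t_idx)
    for tris in edge_to_tris.values():
        for other in tris[1:]:
            union(tris[0], other)

    comp_genes: dict = {}
    for t_idx, tri in enumerate(triangles):
        comp_genes.setdefault(find(t_idx), set()).update(tri)

    components = [comp_genes[r] for r in sorted(comp_genes)]
    # resolve genes claimed by more than one component
    claims: dict = {}
    for cid, genes in enumerate(components):
        for g in genes:
            claims.setdefault(g, []).append(cid)
    shared = {g: cids for g, cids in claims.items() if len(cids) > 1}
    if shared:
        scores = _bbh_scores(bbh, hits) if hits is not None else {}

        def edge_strength(gene, cid):
            members = components[cid]
            vals = [
                scores.get(frozenset((gene, other)), 0.0)
                for other in members
                if other != gene and frozenset((gene, other)) in bbh
            ]
            return max(vals, default=0.0)

        for gene, cids in shared.items():
            best_cid = max(sorted(cids), key=lambda c: (edge_strength(gene, c), -c))
            for cid in cids:
                if cid != best_cid:
                    components[cid].discard(gene)

    clusters = {
        f"cluster{idx:05d}": frozenset(genes)
        for idx, genes in enumerate(c for c in components if c)
    }
    assigned = set().union(*clusters.values()) if clusters else set()
    return OrthologClusterSet(
        clusters=clusters,
        unassigned=set(gene_genome) - assigned,
        gene_genome=dict(gene_genome),
    )


def _link_score(members_a, members_b, lookup) -> float:
    """Mean of directed best-hit scores across the cluster boundary."""
    vals = []
    for src, dst in ((members_a, members_b), (members_b, members_a)):
        for g in src:
            candidates = [lookup[(g, h)] for h in dst if (g, h) in lookup]
            if candidates:
                vals.append(max(candidates))
    return float(np.mean(vals)) if vals else 0.0


def merge_complementary(
    clusters: OrthologClusterSet,
    hits: HitTable,
    overlap_max: float = 0.2,
    link_score_min: float | None = None,
) -> OrthologClusterSet:
    """Merge clusters with complementary phyletic patterns and strong cross-hits.

    Two clusters merge when the genome overlap of their patterns, relative to
    the smaller pattern, is at most ``overlap_max`` AND the mean cross-cluster
    best-hit score is at least ``link_score_min`` (default: 90th percentile of
    non-BBH background scores).  Applied to fixpoint, strongest link first.
    """
    lookup = hits.records.groupby(["query", "subject"])["score"].max().to_dict()
    if link_score_min is None:
        bbh_pairs = symmetric_best_hits(best_hits(hits), hits.gene_genome)
        in_bbh = hits.records.apply(
            lambda r: frozenset((r["query"], r["subject"])) in bbh_pairs, axis=1
        )
        background = hits.records.loc[~in_bbh, "score"]
        link_score_min = float(np.percentile(background, 90)) if len(background) else 0.0

    current = dict(clusters.clusters)
    changed = True
    while changed:
        changed = False
        ids = sorted(current)
        candidates = []
        for i, a in enumerate(ids):
            pat_a = frozenset(clusters.gene_genome[g] for g in current[a])
            for b in ids[i + 1 :]:
                pat_b = frozenset(clusters.gene_genome[g] for g in current[b])
                smaller = min(len(pat_a), len(pat_b))
                if smaller == 0:
                    continue
                overlap = len(pat_a & pat_b) / smaller
                if overlap > overlap_max:
                    continue
                link = _link_score(current[a], current[b], lookup)
                if link >= link_score_min:
                    candidates.append((link, a, b))
        if candidates:
            candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
            _, a, b = candidates[0]
            current[a] = frozenset(current[a] | current[b])
            del current[b]
            changed = True
    return OrthologClusterSet(
        clusters=current,
        unassigned=set(clusters.gene_genome) - (set().union(*current.values()) if current else set()),
        gene_genome=clusters.gene_genome,
    )


def genome_coverage(clusters: OrthologClusterSet) -> tuple:
    """Fraction of genes assigned to clusters, per genome and overall."""
    assigned = clusters.assigned
    per_genome: dict = {}
    totals: dict = {}
    got: dict = {}
    for gene, genome in clusters.gene_genome.items():
        totals[genome] = totals.get(genome, 0) + 1
        if gene in assigned:
            got[genome] = got.get(genome, 0) + 1
    for genome in sorted(totals):
        per_genome[genome] = got.get(genome, 0) / totals[genome]
    total = sum(totals.values())
    overall = (sum(got.values()) / total) if total else 0.0
    return per_genome, overall
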