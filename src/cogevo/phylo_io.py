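"""Trees, presence/absence matrices and their file formats.

The central container is :class:`Phylogeny`, a rooted tree with nodes indexed
by *preorder integers* (the root is node 0).  Every node — including the root —
owns the branch that descends to it from its parent; the root's branch descends
from an implicit "origin" outside the tree.  The branch entering node ``i`` is
therefore identified by ``i`` itself, and a tree with N nodes has N branches.
This convention lets the gain/loss machinery treat a gain at the root ("a gain
in the last common ancestor") as an ordinary branch event.

Presence/absence matrices are plain families × genomes tables of 0/1; paralog
counts on input are collapsed to presence (the analyses downstream are strictly
binary).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "PresenceMatrix",
    "PairReport",
    "NewickError",
    "read_newick",
    "write_newick",
    "read_matrix",
    "write_matrix",
    "validate_pair",
]


class NewickError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


@dataclass
class Phylogeny:
    """Rooted tree with preorder-integer node ids.

    Attributes
    ----------
    names : list of str or None
        Node labels; required and unique for leaves, optional for internal
        nodes.
    parent : ndarray of int
        ``parent[i]`` is the parent node id of node ``i``; ``-1`` for the root.
    children : list of list of int
        Ordered children per node; empty for leaves.
    branch_lengths : ndarray of float
        Length of the branch entering each node; ``nan`` when absent.
    """

    names: list
    parent: np.ndarray
    children: list
    branch_lengths: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def n_branches(self) -> int:
        # every node owns its entering branch, the root's coming from origin
        return self.n_nodes

    @property
    def root(self) -> int:
        return 0

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    @property
    def leaves(self) -> list:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_names(self) -> list:
        return [self.names[i] for i in self.leaves]

    @property
    def internal_nodes(self) -> list:
        return [i for i in range(self.n_nodes) if self.children[i]]

    def postorder(self) -> list:
        """Node ids, children always before parents."""
        order: list = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    def preorder(self) -> list:
        return list(range(self.n_nodes))

    def subtree_leaves(self, i: int) -> list:
        """Leaf ids below (and including) node ``i``."""
        out, stack = [], [i]
        while stack:
            node = stack.pop()
            if not self.children[node]:
                out.append(node)
            else:
                stack.extend(self.children[node])
        return out

    def validate(self) -> None:
        n = self.n_nodes
        if n == 0:
            raise NewickError("empty tree")
        if self.parent[0] != -1:
            raise NewickError("node 0 must be the root")
        seen_root = 0
        for i in range(n):
            if self.parent[i] == -1:
                seen_root += 1
            elif not (0 <= self.parent[i] < n):
                raise NewickError(f"node {i} has out-of-range parent")
        if seen_root != 1:
            raise NewickError(f"expected exactly one root, found {seen_root}")
        names = [self.names[i] for i in self.leaves]
        if any(not nm for nm in names):
            raise NewickError("every leaf must carry a non-empty name")
        if len(set(names)) != len(names):
            dupes = sorted({nm for nm in names if names.count(nm) > 1})
            raise NewickError(f"duplicate leaf names: {dupes}")
        # reachability: preorder ids guarantee parent[i] < i for non-roots
        for i in range(1, n):
            if self.parent[i] >= i:
                raise NewickError("node ids are not in preorder")

    def leaf_index(self) -> dict:
        """name → node id for leaves."""
        return {self.names[i]: i for i in self.leaves}


def _from_dendropy(tree: dendropy.Tree) -> Phylogeny:
    dnodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    names, parent, children, blens = [], [], [], []
    for nd in dnodes:
        label = nd.taxon.label if nd.taxon is not None else nd.label
        names.append(label if label else None)
        parent.append(index[id(nd.parent_node)] if nd.parent_node else -1)
        children.append([index[id(c)] for c in nd.child_nodes()])
        blens.append(np.nan if nd.edge.length is None else float(nd.edge.length))
    phy = Phylogeny(
        names=names,
        parent=np.asarray(parent, dtype=int),
        children=children,
        branch_lengths=np.asarray(blens, dtype=float),
    )
    phy.validate()
    return phy


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Quoted labels, branch lengths and internal node labels are supported;
    multifurcations are preserved.  Unlabeled internal nodes keep ``None`` as
    their name — their stable identity is the preorder index.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(tree)


def _quote(name: str) -> str:
    if any(c in name for c in "()[]{}:;,= \t\n'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: Phylogeny) -> str:
    """Serialize; branch lengths to 10 significant digits."""

    def render(i: int) -> str:
        if tree.children[i]:
            body = "(" + ",".join(render(c) for c in tree.children[i]) + ")"
        else:
            body = ""
        label = _quote(tree.names[i]) if tree.names[i] else ""
        bl = tree.branch_lengths[i]
        suffix = "" if np.isnan(bl) else f":{bl:.10g}"
        return body + label + suffix

    return render(tree.root) + ";"


@dataclass
class PresenceMatrix:
    """Binary families × genomes presence/absence matrix."""

    family_ids: list
    genome_ids: list
    values: np.ndarray  # (n_families, n_genomes) of 0/1 int8

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.family_ids), len(self.genome_ids)):
            raise ValueError("matrix shape does not match id lists")
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValueError("presence values must be 0 or 1")
        if len(set(self.family_ids)) != len(self.family_ids):
            raise ValueError("duplicate family ids")

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.family_ids, columns=self.genome_ids)

    def reorder_genomes(self, genome_ids: Sequence) -> "PresenceMatrix":
        idx = [self.genome_ids.index(g) for g in genome_ids]
        return PresenceMatrix(list(self.family_ids), list(genome_ids), self.values[:, idx])

    def drop_empty(self) -> "PresenceMatrix":
        keep = self.values.sum(axis=1) > 0
        return PresenceMatrix(
            [f for f, k in zip(self.family_ids, keep) if k],
            list(self.genome_ids),
            self.values[keep],
        )


def read_matrix(text: str, drop_empty: bool = False) -> PresenceMatrix:
    """Read a presence matrix from TSV text.

    Header row holds genome ids, first column family ids.  Cells must be
    non-negative integers; counts > 1 (paralogs) are collapsed to presence
    with a warning.  Lines starting with ``#`` are ignored.
    """
    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise ValueError(f"duplicate family ids: {dupes}")
    values = df.to_numpy()
    if values.size == 0:
        return PresenceMatrix([str(f) for f in df.index], [str(g) for g in df.columns],
                              np.zeros(values.shape, dtype=np.int8))
    if not np.issubdtype(values.dtype, np.number):
        bad = np.argwhere(~df.map(lambda v: isinstance(v, (int, float, np.number))).to_numpy())
        r, c = bad[0]
        raise ValueError(
            f"non-numeric cell at family {df.index[r]!r}, genome {df.columns[c]!r}"
        )
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing value at family {df.index[r]!r}, genome {df.columns[c]!r}"
        )
    if (values < 0).any():
        raise ValueError("negative counts in presence matrix")
    if (values > 1).any():
        warnings.warn(
            f"{int((values > 1).sum())} cells with count > 1 binarized to presence",
            stacklevel=2,
        )
    matrix = PresenceMatrix(
        [str(f) for f in df.index], [str(g) for g in df.columns], (values > 0).astype(np.int8)
    )
    return matrix.drop_empty() if drop_empty else matrix


def write_matrix(matrix: PresenceMatrix, header: str | None = None) -> str:
    buf = io.StringIO()
    if header:
        buf.write(header if header.startswith("#") else "# " + header)
        if not header.endswith("\n"):
            buf.write("\n")
    matrix.to_frame().to_csv(buf, sep="\t", index_label="family")
    return buf.getvalue()


@dataclass
class PairReport:
    """Consistency report for a (tree, matrix) pair."""

    missing_from_tree: list = field(default_factory=list)  # genomes not on the tree
    missing_from_matrix: list = field(default_factory=list)  # leaves without data

    @property
    def ok(self) -> bool:
        return not self.missing_from_tree and not self.missing_from_matrix


def validate_pair(
    tree: Phylogeny,
    matrix: PresenceMatrix,
    strict: bool = False,
    prune: bool = False,
):
    """Check that matrix genomes and tree leaves name the same set.

    Returns ``(tree, matrix, report)``.  With ``prune=True`` both sides are
    cut down to the intersection (unary nodes produced by leaf pruning are
    suppressed, their branch lengths summed).  With ``strict=True`` any
    mismatch raises.
    """
    leaf_set = set(tree.leaf_names)
    genome_set = set(matrix.genome_ids)
    report = PairReport(
        missing_from_tree=sorted(genome_set - leaf_set),
        missing_from_matrix=sorted(leaf_set - genome_set),
    )
    if report.ok:
        return tree, matrix.reorder_genomes(tree.leaf_names), report
    if strict:
        raise ValueError(
            "tree/matrix mismatch: "
            f"genomes absent from tree {report.missing_from_tree}; "
            f"leaves absent from matrix {report.missing_from_matrix}"
        )
    if prune:
        common = sorted(leaf_set & genome_set)
        if not common:
            raise ValueError("tree and matrix share no genomes")
        tree = prune_to_leaves(tree, common)
        keep = [g for g in matrix.genome_ids if g in set(common)]
        idx = [matrix.genome_ids.index(g) for g in keep]
        matrix = PresenceMatrix(list(matrix.family_ids), keep, matrix.values[:, idx])
        return tree, matrix.reorder_genomes(tree.leaf_names), report
    return tree, matrix, report


def prune_to_leaves(tree: Phylogeny, keep_names: Iterable) -> Phylogeny:
    """Restrict the tree to the given leaves, suppressing unary nodes.

    A suppressed node's branch length is added to its single child's branch.
    The root is never suppressed (its origin branch must survive), so a root
    left with one child keeps that child explicitly.
    """
    keep = set(keep_names)

    def build(i: int):
        # returns (name, retained children, branch length) or None
        if tree.is_leaf(i):
            if tree.names[i] in keep:
                return (tree.names[i], [], tree.branch_lengths[i])
            return None
        kids = [build(c) for c in tree.children[i]]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1 and i != tree.root:
            name, sub, bl = kids[0]
            mine = tree.branch_lengths[i]
            total = bl if np.isnan(mine) else (mine if np.isnan(bl) else mine + bl)
            return (name, sub, total)
        return (tree.names[i], kids, tree.branch_lengths[i])

    subtree = build(tree.root)
    if subtree is None:
        raise ValueError("pruning removed every leaf")

    names, parent, children, blens = [], [], [], []

    def emit(node, parent_id):
        name, kids, bl = node
        my_id = len(names)
        names.append(name)
        parent.append(parent_id)
        children.append([])
        blens.append(bl)
        if parent_id >= 0:
            children[parent_id].append(my_id)
        for k in kids:
            emit(k, my_id)

    emit(subtree, -1)
    out = Phylogeny(
        names=names,
        parent=np.asarray(parent, dtype=int),
        children=children,
        branch_lengths=np.asarray(blens, dtype=float),
    )
    out.validate()
    return out
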