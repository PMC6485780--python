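"""Neighbor-joining tree construction with nonparametric bootstrap supports.

Canonical Saitou-Nei NJ on a K2P distance matrix, with two behaviours
pinned down so runs are exactly reproducible: ties in the Q-criterion are
broken by lexicographic taxon order (a cluster is labelled by its smallest
leaf), and negative branch lengths are clamped to zero with the deficit
moved to the sibling branch. Bootstrap supports come from resampling the
columns of the (already coverage-filtered) alignment with replacement and
counting how often each internal bipartition of the original tree recurs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .msa import DistanceMatrix, MultipleAlignment, distance_matrix


class PhyloWarning(UserWarning):
    pass


@dataclass
class Node:
    name: str | None = None
    branch_length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted NJ tree represented with a trifurcating root."""

    root: Node

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def bipartitions(self) -> set[frozenset]:
        """Canonical internal bipartitions (the side not holding the
        lexicographically smallest taxon)."""
        all_leaves = set(self.leaf_names())
        anchor = min(all_leaves)
        out: set[frozenset] = set()

        def visit(node: Node) -> set[str]:
            if node.is_leaf:
                return {node.name}
            below: set[str] = set()
            for c in node.children:
                below |= visit(c)
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = below if anchor not in below else all_leaves - below
                out.add(frozenset(side))
            return below

        visit(self.root)
        return out

    def internal_nodes(self) -> list[Node]:
        out: list[Node] = []

        def visit(node: Node) -> None:
            if not node.is_leaf:
                if node is not self.root:
                    out.append(node)
                for c in node.children:
                    visit(c)

        visit(self.root)
        return out


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Requires >= 3 taxa and finite entries. Among pairs within 1e-9 of the
    minimal Q-criterion, the pair whose (sorted) cluster labels are
    lexicographically smallest is joined; a cluster's label is its
    smallest leaf name.
    """
    n0 = len(dm.taxa)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.isfinite(dm.values).all():
        raise ValueError("distance matrix contains non-finite entries")

    labels = list(dm.taxa)          # cluster label = smallest leaf inside
    nodes = [Node(name=t) for t in dm.taxa]
    d = dm.values.astype(float).copy()
    active = list(range(n0))

    def clamp(child_a: Node, child_b: Node) -> None:
        if not clamp_negative:
            return
        if child_a.branch_length < 0:
            child_b.branch_length += child_a.branch_length
            child_a.branch_length = 0.0
        if child_b.branch_length < 0:
            child_a.branch_length += child_b.branch_length
            child_b.branch_length = 0.0
        child_a.branch_length = max(child_a.branch_length, 0.0)
        child_b.branch_length = max(child_b.branch_length, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        best_q = None
        for ai in range(m):
            for bj in range(ai + 1, m):
                i, j = active[ai], active[bj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((labels[i], labels[j])))
                if best_q is None or q < best_q - 1e-9 or (
                        abs(q - best_q) <= 1e-9 and key < best[0]):
                    best_q = q
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        ni, nj = nodes[i], nodes[j]
        ni.branch_length, nj.branch_length = li, lj
        clamp(ni, nj)
        parent = Node(children=[ni, nj])
        # new distances to remaining clusters
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[i, k] = d[k, i] = dk
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.branch_length = max(ln, 0.0) if clamp_negative else ln
    order = sorted(((labels[x], x) for x in (i, j, k)))
    root = Node(children=[nodes[x] for _, x in order])
    return Tree(root)


def tree_distance_matrix(tree: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths on the tree (additivity check helper)."""
    taxa = sorted(tree.leaf_names())
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    d = np.zeros((n, n))

    def visit(node: Node) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        sides: list[dict[str, float]] = []
        for c in node.children:
            below = visit(c)
            sides.append({t: dist + c.branch_length for t, dist in below.items()})
        for a in range(len(sides)):
            for b in range(a + 1, len(sides)):
                for ta, da in sides[a].items():
                    for tb, db in sides[b].items():
                        d[index[ta], index[tb]] = d[index[tb], index[ta]] = da + db
        merged: dict[str, float] = {}
        for s in sides:
            merged.update(s)
        return merged

    visit(tree.root)
    return DistanceMatrix(taxa, d)


def bootstrap_supports(
    msa: MultipleAlignment,
    replicates: int = 500,
    seed: int = 0,
    min_coverage: float = 0.95,
) -> Tree:
    """NJ tree of the filtered alignment, internal nodes annotated with
    bootstrap support (% of column-resampled replicates containing the
    same bipartition).

    The coverage filter is applied once; replicates resample columns of
    the filtered alignment. A replicate whose distance matrix contains a
    saturated (infinite) pair is skipped with a warning and removed from
    the support denominator. ``replicates=0`` returns the plain tree.
    """
    from .msa import coverage_filter

    filtered = coverage_filter(msa, min_coverage)
    base_dm = distance_matrix(filtered, min_coverage=0.0)
    tree = neighbor_joining(base_dm)
    if replicates == 0:
        return tree

    rng = np.random.default_rng(seed)
    length = filtered.length
    mat = np.array([np.frombuffer(r.encode(), np.uint8)
                    for r in filtered.rows])
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    valid = 0
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        rows = [row.tobytes().decode() for row in mat[:, cols]]
        rep = MultipleAlignment(list(filtered.taxa), rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dm = distance_matrix(rep, min_coverage=0.0)
        if not np.isfinite(dm.values).all():
            warnings.warn("bootstrap replicate skipped: saturated pair",
                          PhyloWarning)
            continue
        valid += 1
        for bp in neighbor_joining(dm).bipartitions():
            if bp in counts:
                counts[bp] += 1

    if valid == 0:
        warnings.warn("no valid bootstrap replicates; supports unset",
                      PhyloWarning)
        return tree

    support_of = {bp: 100.0 * c / valid for bp, c in counts.items()}
    all_leaves = set(tree.leaf_names())
    anchor = min(all_leaves)
    for node in tree.internal_nodes():
        below = {leaf.name for leaf in node.leaves()}
        if not (2 <= len(below) <= len(all_leaves) - 2):
            continue
        side = below if anchor not in below else all_leaves - below
        node.support = support_of.get(frozenset(side))
    return tree


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(node: Node, with_length: bool = True) -> str:
    if node.is_leaf:
        s = _quote(node.name)
    else:
        s = "(" + ",".join(_newick_node(c, with_length)
                           for c in node.children) + ")"
        if node.support is not None:
            s += f"{node.support:.10g}"
    if with_length:
        s += f":{node.branch_length:.10g}"
    return s


def to_newick(tree: Tree) -> str:
    """Standard Newick: branch lengths, supports as internal labels, ';'."""
    inner = ",".join(_newick_node(c) for c in tree.root.children)
    return f"({inner});"
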