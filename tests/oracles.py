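"""Independent oracles used by the tests.

These deliberately avoid the package's own implementations: alignment
scores come from exhaustive enumeration of all alignments, tree path
lengths from a direct traversal, and topology checks from enumerating
every unrooted topology and solving its branch lengths by least squares.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_global_score(a: str, b: str, match: float, mismatch: float,
                             gap_open: float, gap_extend: float) -> float:
    """Maximum global alignment score by enumerating every alignment.

    Affine convention: a gap of length L costs gap_open + (L-1)*gap_extend
    (the first gap column pays the opening penalty). Feasible for
    sequences of length <= 6.
    """
    best = [float("-inf")]

    def rec(i: int, j: int, score: float, last: str) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):
            pen = gap_extend if last == "A" else gap_open
            rec(i + 1, j, score + pen, "A")
        if j < len(b):
            pen = gap_extend if last == "B" else gap_open
            rec(i, j + 1, score + pen, "B")

    rec(0, 0, 0.0, "M")
    return best[0]


def random_tree_edges(taxa: list[str], rng: np.random.Generator,
                      min_bl: float = 0.2, max_bl: float = 3.0):
    """A random unrooted binary tree as {edge: length}; edges are
    frozensets of node ids (taxa are leaf ids, ints are internal)."""
    edges: dict[frozenset, float] = {}
    internal = itertools.count()

    def bl() -> float:
        return float(rng.uniform(min_bl, max_bl))

    center = -1 - next(internal)
    for t in taxa[:3]:
        edges[frozenset((center, t))] = bl()
    for t in taxa[3:]:
        edge = list(edges)[rng.integers(0, len(edges))]
        u, v = tuple(edge)
        length = edges.pop(edge)
        w = -1 - next(internal)
        edges[frozenset((u, w))] = length / 2
        edges[frozenset((w, v))] = length / 2 + bl() * 0.1
        edges[frozenset((w, t))] = bl()
    return edges


def edges_to_matrix(taxa: list[str], edges: dict[frozenset, float]) -> np.ndarray:
    """Leaf-to-leaf path lengths of an edge-list tree (BFS per leaf)."""
    adj: dict[object, list[tuple[object, float]]] = {}
    for e, w in edges.items():
        u, v = tuple(e)
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    n = len(taxa)
    d = np.zeros((n, n))
    for i, src in enumerate(taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, t in enumerate(taxa):
            d[i, j] = dist[t]
    return d


def edges_bipartitions(taxa: list[str], edges: dict[frozenset, float]) -> set[frozenset]:
    """Canonical internal bipartitions of an edge-list tree."""
    adj: dict[object, set] = {}
    for e in edges:
        u, v = tuple(e)
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    anchor = min(taxa)
    out: set[frozenset] = set()
    for e in edges:
        u, v = tuple(e)
        # leaves reachable from v without crossing u
        seen = {u, v}
        stack = [v]
        side: set[str] = set()
        while stack:
            x = stack.pop()
            if isinstance(x, str):
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 2 <= len(side) <= len(taxa) - 2:
            canon = side if anchor not in side else set(taxa) - side
            out.add(frozenset(canon))
    return out


def nj_tree_leaf_distances(tree, taxa: list[str]) -> np.ndarray:
    """Independent leaf-to-leaf path lengths on a package Tree object
    (walks .children/.branch_length only)."""

    def collect(node):
        if not node.children:
            return {node.name: 0.0}
        merged = {}
        pairs = []
        sides = []
        for c in node.children:
            below = collect(c)
            sides.append({k: v + c.branch_length for k, v in below.items()})
        for a_i in range(len(sides)):
            for b_i in range(a_i + 1, len(sides)):
                for ta, da in sides[a_i].items():
                    for tb, db in sides[b_i].items():
                        pairs.append((ta, tb, da + db))
        for s in sides:
            merged.update(s)
        collect.pairs.extend(pairs)
        return merged

    collect.pairs = []
    collect(tree.root)
    n = len(taxa)
    idx = {t: i for i, t in enumerate(taxa)}
    d = np.zeros((n, n))
    for ta, tb, dist in collect.pairs:
        d[idx[ta], idx[tb]] = d[idx[tb], idx[ta]] = dist
    return d


def all_unrooted_topologies(taxa: list[str]):
    """Every unrooted binary topology on the taxa, as edge sets."""
    internal = [-1]
    first = [frozenset((-1, t)) for t in taxa[:3]]
    trees = [set(first)]
    next_internal = -2
    for t in taxa[3:]:
        new_trees = []
        for tr in trees:
            for edge in tr:
                u, v = tuple(edge)
                w = next_internal
                nt = set(tr)
                nt.remove(edge)
                nt.add(frozenset((u, w)))
                nt.add(frozenset((w, v)))
                nt.add(frozenset((w, t)))
                new_trees.append(nt)
        trees = new_trees
        next_internal -= 1
    return trees


def topology_fit_residual(taxa: list[str], topology: set[frozenset],
                          matrix: np.ndarray) -> float:
    """Least-squares residual of fitting branch lengths of a topology to a
    distance matrix; ~0 iff the matrix is additive on this topology."""
    edges = sorted(topology, key=lambda e: sorted(map(str, e)))
    adj: dict[object, list[tuple[object, int]]] = {}
    for k, e in enumerate(edges):
        u, v = tuple(e)
        adj.setdefault(u, []).append((v, k))
        adj.setdefault(v, []).append((u, k))
    rows = []
    y = []
    n = len(taxa)
    for i in range(n):
        for j in range(i + 1, n):
            # path edges between leaves taxa[i], taxa[j]
            src, dst = taxa[i], taxa[j]
            path = {src: []}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, k in adj[u]:
                    if v not in path:
                        path[v] = path[u] + [k]
                        stack.append(v)
            row = np.zeros(len(edges))
            row[path[dst]] = 1.0
            rows.append(row)
            y.append(matrix[i, j])
    A = np.array(rows)
    yv = np.array(y)
    sol, *_ = np.linalg.lstsq(A, yv, rcond=None)
    return float(np.abs(A @ sol - yv).max())
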