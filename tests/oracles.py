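"""Independent reference implementations used only as test oracles.

These deliberately avoid the library code paths they check: plain-Python
dynamic programming, direct base counting, and exhaustive tree enumeration.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Sequence, Tuple

import numpy as np

# ---------------------------------------------------------------------------
# Needleman-Wunsch score oracle (match +1, mismatch -1, affine open -2 / ext -1)


def nw_score(a: str, b: str, match=1.0, mismatch=-1.0, open_=-2.0, ext=-1.0) -> float:
    """Optimal global alignment score via Gotoh's three-matrix recursion."""
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + ext * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = open_ + ext * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + ext, Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + ext, X[i][j - 1] + open_)
    return max(M[n][m], X[n][m], Y[n][m])


# ---------------------------------------------------------------------------
# K2P by direct counting


_PURINES = {"A", "G"}


def k2p_by_counting(a: str, b: str) -> Tuple[float, float, float]:
    """(P, Q, k) by positional base counting + the closed form.

    Raises ValueError on saturation or when no comparable columns exist.
    """
    sites = ts = tv = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if sites == 0:
        raise ValueError("no sites")
    P, Q = ts / sites, tv / sites
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("saturation")
    return P, Q, -0.5 * math.log(w1) - 0.25 * math.log(w2)


# ---------------------------------------------------------------------------
# exact repeat scan (LTR-pair detection oracle for identical implants)


def exact_repeat_positions(seq: str, k: int) -> List[Tuple[int, int]]:
    """All position pairs (i < j) of identical k-mers, by brute hashing."""
    seen: Dict[str, List[int]] = {}
    for i in range(len(seq) - k + 1):
        seen.setdefault(seq[i : i + k], []).append(i)
    out = []
    for positions in seen.values():
        for i, j in itertools.combinations(positions, 2):
            out.append((i, j))
    return sorted(out)


# ---------------------------------------------------------------------------
# tree enumeration and least-squares fitting (NJ oracle)


def enumerate_topologies(labels: Sequence[str]) -> List[List[Tuple[int, int]]]:
    """All unrooted binary topologies over ``labels`` as edge lists.

    Nodes 0..n-1 are the leaves; internal nodes get indices from n upward.
    Built by inserting each leaf into every edge of every partial tree
    (1, 3, 15, 105 ... topologies for 3, 4, 5, 6 leaves).
    """
    n = len(labels)
    if n < 3:
        raise ValueError("need >= 3 leaves")
    base = [(0, n), (1, n), (2, n)]  # star over first three leaves
    trees = [(base, n + 1)]
    for leaf in range(3, n):
        nxt = []
        for edges, next_node in trees:
            for k in range(len(edges)):
                u, v = edges[k]
                mid = next_node
                new_edges = edges[:k] + edges[k + 1 :]
                new_edges = new_edges + [(u, mid), (v, mid), (leaf, mid)]
                nxt.append((new_edges, next_node + 1))
        trees = nxt
    return [sorted(t[0]) for t in trees]


def _leaf_paths(edges: List[Tuple[int, int]], n_leaves: int):
    """For each leaf pair, the set of edge indices on the connecting path."""
    adj: Dict[int, List[Tuple[int, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    paths = {}
    for src in range(n_leaves):
        stack = [(src, None, [])]
        seen = {src}
        while stack:
            node, _, path = stack.pop()
            if node < n_leaves and node != src:
                paths[(src, node)] = path
                continue
            for nb, eidx in adj.get(node, []):
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, node, path + [eidx]))
    return paths


def fit_topology(
    edges: List[Tuple[int, int]], d: np.ndarray
) -> Tuple[np.ndarray, float]:
    """Least-squares branch lengths for a topology against matrix ``d``;
    returns (lengths per edge, residual norm)."""
    n = d.shape[0]
    paths = _leaf_paths(edges, n)
    rows, rhs = [], []
    for i in range(n):
        for j in range(i + 1, n):
            row = np.zeros(len(edges))
            for eidx in paths[(i, j)]:
                row[eidx] = 1.0
            rows.append(row)
            rhs.append(d[i, j])
    A = np.array(rows)
    y = np.array(rhs)
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = float(np.linalg.norm(A @ x - y))
    return x, resid


def topology_splits(
    edges: List[Tuple[int, int]], labels: Sequence[str]
) -> frozenset:
    """Non-trivial bipartitions (as frozensets of label-frozensets) induced
    by the internal edges of a topology."""
    n = len(labels)
    adj: Dict[int, List[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    splits = set()
    for u, v in edges:
        # leaves on v's side when the edge u-v is cut
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node < n:
                side.add(labels[node])
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        other = frozenset(labels) - frozenset(side)
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset({frozenset(side), other}))
    return frozenset(splits)


def random_additive_matrix(
    labels: Sequence[str], rng: np.random.Generator
) -> Tuple[np.ndarray, frozenset]:
    """Additive distance matrix from a random binary tree with strictly
    positive branch lengths; returns (matrix, split set of the tree)."""
    n = len(labels)
    # build a random topology by sequential edge insertion
    edges = [(0, n), (1, n), (2, n)]
    next_node = n + 1
    for leaf in range(3, n):
        k = int(rng.integers(0, len(edges)))
        u, v = edges.pop(k)
        mid = next_node
        next_node += 1
        edges += [(u, mid), (v, mid), (leaf, mid)]
    sorted_edges = sorted(edges)
    lengths = rng.uniform(0.2, 1.0, size=len(sorted_edges))
    paths = _leaf_paths(sorted_edges, n)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = sum(lengths[e] for e in paths[(i, j)])
    return d, topology_splits(sorted_edges, labels)


def newick_splits(newick: str) -> frozenset:
    """Non-trivial bipartitions of a newick tree."""
    from io import StringIO

    from skbio import TreeNode

    tree = TreeNode.read(StringIO(newick), convert_underscores=False)
    all_leaves = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset({side, other}))
    return frozenset(splits)
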