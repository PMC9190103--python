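"""Family-level grouping of elements from RT-domain protein distances.

Pairwise global alignment (BLOSUM62, affine gaps) of reverse-transcriptase
domain proteins gives d(i,j) = 1 - identity; a canonical neighbor-joining
tree (Saitou-Nei Q-criterion) over that matrix groups elements into
families, and the Copia/Gypsy superfamilies should be separable by a single
edge. Distance-based NJ is used deliberately: family grouping, not branch
support, is the analysis goal.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from . import _align


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal over unique labels."""

    labels: Tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n < 2:
            raise ValueError("need at least 2 labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        d = np.asarray(self.d, dtype=float)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match {n} labels")
        if not np.allclose(d, d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("negative distances")
        object.__setattr__(self, "d", d)


def rt_distance_matrix(rt_proteins: Dict[str, str]) -> DistanceMatrix:
    """d(i,j) = 1 - identity of the pairwise global protein alignment,
    identity over all aligned columns including gap columns."""
    labels = tuple(rt_proteins)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = _align.global_protein(
                rt_proteins[labels[i]], rt_proteins[labels[j]]
            ).identity
            d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(matrix: DistanceMatrix) -> str:
    """Canonical neighbor-joining, serialized as an unrooted newick string.

    Ties on the Q-criterion break toward the lexicographically smallest
    label pair; negative branch lengths are clamped to zero with the deficit
    moved to the sister branch. Deterministic for identical input.
    """
    labels = list(matrix.labels)
    if len(labels) == 2:
        h = matrix.d[0, 1] / 2.0
        return f"({labels[0]}:{h:.10g},{labels[1]}:{h:.10g});"
    d = matrix.d.copy()
    nodes = list(labels)  # newick fragment per active node
    tie_keys = [(lab,) for lab in labels]  # lexicographic tie-break identity

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                if q[i, j] <= qmin + 1e-12:
                    key = tuple(sorted((min(tie_keys[i]), min(tie_keys[j]))))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        if li < 0:
            lj, li = d[i, j], 0.0
        if lj < 0:
            li, lj = d[i, j], 0.0
        merged = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(n) if x not in (i, j)]
        d2 = np.zeros((n - 1, n - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        merged_key = tuple(sorted(tie_keys[i] + tie_keys[j]))
        nodes = [nodes[x] for x in keep] + [merged]
        tie_keys = [tie_keys[x] for x in keep] + [merged_key]
        d = d2

    # final trifurcation via the three-point formulas
    a = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    b = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    c = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    a, b, c = (max(x, 0.0) for x in (a, b, c))
    return (
        f"({nodes[0]}:{a:.10g},{nodes[1]}:{b:.10g},{nodes[2]}:{c:.10g});"
    )


def tree_path_lengths(newick: str) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a newick tree (for round-trip
    checks against the input distances)."""
    from skbio import TreeNode

    tree = TreeNode.read(_stdio.StringIO(newick), convert_underscores=False)
    tips = sorted(tree.tips(), key=lambda t: t.name)
    labels = tuple(t.name for t in tips)
    skdm = tree.tip_tip_distances([t.name for t in tips])
    d = np.asarray(skdm.data)
    order = [list(skdm.ids).index(lab) for lab in labels]
    d = d[np.ix_(order, order)]
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# family purity


@dataclass(frozen=True)
class FamilyPurityReport:
    """Per-family clade purity and superfamily separability on an NJ tree."""

    purity: Dict[str, float]  # family -> fraction of members in its largest pure clade
    superfamily_separable: bool


def group_families(
    newick: str, element_families: Dict[str, str],
    superfamily_of: Dict[str, str] | None = None,
) -> FamilyPurityReport:
    """For each family, the fraction of its members inside its largest
    single-family clade (each edge's bipartition sides count as clades), and
    whether Copia and Gypsy leaves are separable by one edge.

    ``element_families`` maps every leaf label to a family name;
    ``superfamily_of`` maps family -> superfamily (separability is skipped
    as trivially true when absent or when only one superfamily occurs).
    """
    from skbio import TreeNode

    tree = TreeNode.read(_stdio.StringIO(newick), convert_underscores=False)
    leaves = [t.name for t in tree.tips()]
    missing = [l for l in leaves if l not in element_families]
    if missing:
        raise ValueError(f"leaves without family label: {missing}")
    all_leaves = frozenset(leaves)
    sides: List[frozenset] = []
    for node in tree.traverse(include_self=False):
        clade = frozenset(t.name for t in node.tips()) if not node.is_tip() \
            else frozenset([node.name])
        sides.append(clade)
        sides.append(all_leaves - clade)
    sides.append(all_leaves)  # the whole tree is itself a clade

    purity: Dict[str, float] = {}
    families = sorted(set(element_families[l] for l in leaves))
    for fam in families:
        members = frozenset(l for l in leaves if element_families[l] == fam)
        best = 1  # a single leaf is always a pure clade
        for side in sides:
            if side and side <= members and len(side) > best:
                best = len(side)
        purity[fam] = best / len(members)

    separable = True
    if superfamily_of:
        by_sf: Dict[str, set] = {}
        for l in leaves:
            sf = superfamily_of.get(element_families[l], "unknown")
            by_sf.setdefault(sf, set()).add(l)
        if len(by_sf) == 2:
            groups = [frozenset(v) for v in by_sf.values()]
            separable = any(side == groups[0] or side == groups[1] for side in sides)
    return FamilyPurityReport(purity=purity, superfamily_separable=separable)
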