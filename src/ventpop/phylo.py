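"""Genetic distances, neighbor-joining trees, bootstrap support, concordance.

Trees are :class:`skbio.TreeNode` objects with a trifurcating root
(unrooted convention) and branch lengths in substitutions per site.
Neighbor joining follows Saitou & Nei's Q-criterion with two documented
determinism rules: ties in the Q matrix are broken toward the
lexicographically smallest pair of representative leaf labels, and
negative intermediate branch lengths are clamped to zero with the deficit
moved to the sister edge.  NJ is exact on additive distance matrices.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode
from sklearn.metrics import adjusted_rand_score

from .errors import CrossReferenceError, SaturationError, UndefinedStatistic
from .popgen import _base_indices, _pair_diff_matrices
from .seqio import LocusAlignment, distance_matrix

__all__ = [
    "genetic_distance",
    "neighbor_joining",
    "bootstrap_support",
    "bipartitions",
    "monophyly_check",
    "cut_tree",
    "concordance",
]


def genetic_distance(aln: LocusAlignment, model: str = "p") -> DistanceMatrix:
    """Pairwise distance matrix: ``p`` (proportion of differing sites under
    pairwise deletion) or ``jc69`` (Jukes-Cantor correction -3/4 ln(1-4p/3))."""
    if aln.n < 2:
        raise UndefinedStatistic("need >= 2 sequences")
    b = _base_indices(aln)
    matches, compared = _pair_diff_matrices(b)
    if np.any(compared[np.triu_indices(aln.n, k=1)] == 0):
        raise UndefinedStatistic("a pair has no comparable sites")
    with np.errstate(invalid="ignore"):
        p = 1.0 - matches / np.where(compared > 0, compared, 1.0)
    np.fill_diagonal(p, 0.0)
    p = (p + p.T) / 2.0
    if model == "p":
        d = p
    elif model == "jc69":
        sat = p >= 0.75
        if sat.any():
            iu = np.triu_indices(aln.n, k=1)
            bad = [
                (aln.ids[i], aln.ids[j])
                for i, j in zip(*iu)
                if sat[i, j]
            ]
            raise SaturationError(f"jc69 saturated for pairs {bad}", bad)
        d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(f"unknown model {model!r}")
    return distance_matrix(d, aln.ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; deterministic, exact on additive input."""
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if np.any(dm.data < 0):
        raise ValueError("negative input distances")
    labels = list(dm.ids)
    D = dm.data.copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    reps = labels[:]  # smallest leaf label under each active node
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                if Q[ai, aj] <= qmin + 1e-12:
                    key = tuple(sorted((reps[active[ai]], reps[active[aj]])))
                    if best is None or key < best[0]:
                        best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        d_ij = sub[ai, aj]
        li = 0.5 * d_ij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = d_ij - li
        if li < 0:  # move deficit to the sister edge
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - d_ij)
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    nodes[a].length = max(0.0, 0.5 * (dab + dac - dbc))
    nodes[b].length = max(0.0, 0.5 * (dab + dbc - dac))
    nodes[c].length = max(0.0, 0.5 * (dac + dbc - dab))
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def _canonical(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Canonical form of a bipartition: the side not holding the smallest leaf."""
    return frozenset(all_leaves - side) if min(all_leaves) in side else frozenset(side)


def bipartitions(tree: TreeNode) -> set:
    """Non-trivial bipartitions of the (unrooted) tree, in canonical form."""
    all_leaves = frozenset(t.name for t in tree.tips())
    n = len(all_leaves)
    out = set()
    for node in tree.preorder(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= n - 2:
            out.add(_canonical(side, all_leaves))
    return out


def _resample_alignment(
    aln: LocusAlignment, rng: np.random.Generator
) -> LocusAlignment:
    arr = aln.as_array()
    cols = rng.integers(0, aln.length, size=aln.length)
    res = arr[:, cols]
    seqs = tuple(bytes(row).decode("ascii") for row in res)
    return LocusAlignment(aln.name, aln.ids, seqs)


def bootstrap_support(
    aln: LocusAlignment,
    model: str = "jc69",
    reps: int = 100,
    seed: int | None = None,
    builder=neighbor_joining,
):
    """Column-resampling bootstrap support (%) for the NJ tree's bipartitions.

    Returns ``(tree, support)`` where ``support`` maps each canonical
    bipartition of the main tree to its percent support, also written onto
    internal node names.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    tree = builder(genetic_distance(aln, model))
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        rep_tree = builder(genetic_distance(_resample_alignment(aln, rng), model))
        for bp in bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    support = {bp: 100.0 * c / reps for bp, c in counts.items()}
    all_leaves = frozenset(t.name for t in tree.tips())
    n = len(all_leaves)
    for node in tree.preorder(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= n - 2:
            node.name = f"{support[_canonical(side, all_leaves)]:.0f}"
    return tree, support


def monophyly_check(tree: TreeNode, label_subset) -> bool:
    """True iff the subset forms a clade on some rooting (bipartition test)."""
    all_leaves = frozenset(t.name for t in tree.tips())
    subset = frozenset(label_subset)
    if not subset <= all_leaves:
        raise CrossReferenceError(
            f"labels not in tree: {sorted(subset - all_leaves)}",
            sorted(subset - all_leaves),
        )
    if len(subset) in (1, len(all_leaves)):
        return True
    return _canonical(subset, all_leaves) in bipartitions(tree)


def cut_tree(tree: TreeNode, k: int = 2) -> dict:
    """Partition leaves into ``k`` groups by removing the k-1 longest
    internal edges (ties broken by leaf-name order); returns leaf -> group id."""
    edges = []
    for node in tree.preorder(include_self=False):
        if node.is_tip() or node.length is None:
            continue
        names = tuple(sorted(t.name for t in node.tips()))
        edges.append((node.length, names, node))
    edges.sort(key=lambda e: (-e[0], e[1]))
    cut_nodes = {id(e[2]) for e in edges[: max(k - 1, 0)]}
    partition = {}
    group_of_cut: dict[int, int] = {}
    next_id = 0
    for tip in tree.tips():
        cluster = None
        node = tip
        while node is not None:
            if id(node) in cut_nodes:
                cluster = id(node)
                break
            node = node.parent
        key = cluster if cluster is not None else -1
        if key not in group_of_cut:
            group_of_cut[key] = next_id
            next_id += 1
        partition[tip.name] = group_of_cut[key]
    return partition


def _partition_of(obj, k: int) -> dict:
    if isinstance(obj, TreeNode):
        return cut_tree(obj, k)
    if hasattr(obj, "cut"):  # maldi.Dendrogram
        return obj.cut(k)
    if isinstance(obj, dict):
        return obj
    raise TypeError(f"cannot derive a partition from {type(obj)!r}")


def concordance(a, b, k: int = 2) -> float:
    """Adjusted Rand index between the k-cut partitions of two trees/dendrograms."""
    pa = _partition_of(a, k)
    pb = _partition_of(b, k)
    if set(pa) != set(pb):
        raise CrossReferenceError(
            "leaf sets differ between the two trees",
            sorted(set(pa) ^ set(pb)),
        )
    labels = sorted(pa)
    return float(
        adjusted_rand_score([pa[l] for l in labels], [pb[l] for l in labels])
    )
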