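"""Distance trees, clade cutting, and clade/group concordance.

Neighbor joining (Saitou-Nei) is used throughout: it exactly recovers
additive distance matrices, and the downstream claims consumed here are
clade-membership claims, not branch-length or likelihood claims.  Trees are
dendropy objects, so Newick I/O and midpoint rooting come for free.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .align import DistanceMatrix

__all__ = [
    "CladePartition",
    "ConcordanceReport",
    "neighbor_joining",
    "cut_tree_clades",
    "clade_concordance",
    "tree_to_newick",
    "path_distance_matrix",
]


@dataclass
class CladePartition:
    """Mapping leaf label -> clade index in 1..k."""

    assignment: dict[str, int]

    @property
    def k(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, clade: int) -> list[str]:
        return sorted(l for l, c in self.assignment.items() if c == clade)


@dataclass
class ConcordanceReport:
    """Agreement between tree clades and leader-end groups."""

    purity: float
    adjusted_rand: float
    contingency: pd.DataFrame


def _validate(D: DistanceMatrix) -> np.ndarray:
    v = np.asarray(D.values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("distance matrix contains NaN or infinite entries")
    if not np.allclose(v, v.T):
        raise ValueError("distance matrix is not symmetric")
    return v


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Classical neighbor joining.

    Deterministic: ties in the Q criterion are broken by the
    lexicographically smallest (sorted) pair of representative leaf labels.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling edge.
    """
    d = _validate(D)
    labels = list(D.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 labels")

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
    # representative label per active node (min leaf label of its subtree)
    reps = list(labels)
    active = list(range(n))
    dist = d.copy()

    while len(active) > 2:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        pairs = np.argwhere(np.abs(q - qmin) <= 1e-12)
        best = min(
            ((tuple(sorted((reps[active[i]], reps[active[j]]))), i, j)
             for i, j in pairs if i < j),
        )
        _, ai, aj = best
        i_idx, j_idx = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i_idx])
        parent.add_child(nodes[j_idx])
        nodes[i_idx].edge.length = li
        nodes[j_idx].edge.length = lj
        # distances from the new node to the remaining ones
        new_row = np.zeros(dist.shape[0] + 1)
        for bk, k_idx in enumerate(active):
            if k_idx in (i_idx, j_idx):
                continue
            new_row[k_idx] = 0.5 * (sub[ai, bk] + sub[aj, bk] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, : len(new_row) - 1] = new_row[:-1]
        dist[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        reps.append(min(reps[i_idx], reps[j_idx]))
        active = [k for k in active if k not in (i_idx, j_idx)] + [len(nodes) - 1]

    # join the last two nodes by a single edge of length d(a, b)
    a, b = active
    dab = max(dist[a, b], 0.0)
    if nodes[b].is_leaf() and not nodes[a].is_leaf():
        a, b = b, a
    if nodes[b].is_leaf():  # n == 2: no internal node exists yet
        root = dendropy.Node()
        root.add_child(nodes[a])
        root.add_child(nodes[b])
        nodes[a].edge.length = dab
        nodes[b].edge.length = 0.0
    else:
        root = nodes[b]
        root.add_child(nodes[a])
        nodes[a].edge.length = dab
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def path_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels=labels, values=values)


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          real_value_format_specifier=".6g").strip()


def _leafset(node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def cut_tree_clades(tree: dendropy.Tree, k: int) -> CladePartition:
    """Cut a tree into k leaf clades by iterative longest-edge splitting.

    The tree is midpoint-rooted, then the cluster whose longest internal
    connecting edge is longest is split at that edge, until k clusters
    remain.  Ties go to the deeper edge, then to label order.
    """
    work = tree.clone(depth=1)
    leaves = [l.taxon.label for l in work.leaf_node_iter()]
    if not 1 <= k <= len(leaves):
        raise ValueError(f"k={k} out of range for {len(leaves)} leaves")
    work.is_rooted = True
    if len(leaves) > 2:
        work.reroot_at_midpoint(update_bipartitions=True)

    # candidate cut edges with (internal?, length, depth, leafset below)
    edges = []
    for node in work.preorder_node_iter():
        if node is work.seed_node:
            continue
        depth = 0
        p = node
        while p is not work.seed_node:
            p = p.parent_node
            depth += 1
        edges.append(
            (not node.is_leaf(), node.edge.length or 0.0, depth, _leafset(node))
        )

    clusters: list[frozenset[str]] = [frozenset(leaves)]
    while len(clusters) < k:
        best = None
        for ci, cluster in enumerate(clusters):
            for internal, length, depth, below in edges:
                inside = below & cluster
                if not inside or inside == cluster:
                    continue
                # internal connecting edges always outrank leaf edges:
                # outlier leaves surface in the concordance report instead
                # of being split off as singleton clades
                key = (internal, length, depth, tuple(sorted(inside)))
                if best is None or key > best[0]:
                    best = (key, ci, inside)
        if best is None:  # cannot split further (zero-length ties exhausted)
            raise RuntimeError("tree cannot be split into the requested clades")
        _, ci, inside = best
        cluster = clusters.pop(ci)
        clusters.extend([inside, cluster - inside])

    clusters.sort(key=lambda c: min(c))
    assignment = {
        leaf: idx + 1 for idx, cluster in enumerate(clusters) for leaf in cluster
    }
    return CladePartition(assignment=assignment)


def clade_concordance(
    partition: CladePartition, groups: dict[str, str]
) -> ConcordanceReport:
    """Purity and adjusted Rand index of clades against group labels."""
    part_leaves = set(partition.assignment)
    group_leaves = set(groups)
    if part_leaves != group_leaves:
        diff = sorted(part_leaves ^ group_leaves)
        raise ValueError(f"leaf sets differ; symmetric difference: {diff}")
    leaves = sorted(part_leaves)
    clade_labels = [partition.assignment[l] for l in leaves]
    group_labels = [groups[l] for l in leaves]
    contingency = pd.crosstab(
        pd.Series(clade_labels, name="clade"),
        pd.Series(group_labels, name="group"),
    )
    purity = float(contingency.max(axis=1).sum() / len(leaves))
    ari = float(adjusted_rand_score(group_labels, clade_labels))
    return ConcordanceReport(purity=purity, adjusted_rand=ari,
                             contingency=contingency)
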