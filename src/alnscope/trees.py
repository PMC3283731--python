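"""Neighbour-joining trees, bootstrap support, and OTU internal distances.

Trees are built from K2P distance matrices by classic neighbour joining
(Saitou-Nei) or BioNJ (Gascuel's variance-weighted variant) and held as
:class:`dendropy.Tree` objects, so newick I/O, rooting and traversal come
for free. Both agglomerators are exact on additive matrices.

The OTU internal distance is the maximum path length from the most recent
common ancestor (MRCA) of an OTU's members to any of those members. MRCA
is only meaningful on a rooted tree, so trees are midpoint-rooted by
default before the query; a distance-matrix fallback (half the maximum
within-OTU pairwise distance) is available where no tree is wanted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from alnscope.alignment import Alignment
from alnscope.distances import (
    DistanceMatrix,
    _all_pair_counts,
    _encode,
    _site_mask,
    k2p_matrix_from_counts,
)
from alnscope.otu import OTU


class SingletonDistanceError(ValueError):
    """Internal distance requested for a singleton OTU (undefined)."""


@dataclass(frozen=True)
class CladeSupport:
    """Bootstrap percentages keyed by canonical bipartition.

    A bipartition is canonicalized as the frozenset of leaf labels on the
    side *not* containing the alphabetically first label, so supports can
    be matched between unrooted trees regardless of orientation.
    """

    supports: dict[frozenset[str], float]
    replicates: int
    seed: int | None

    def support_for(self, labels: frozenset[str], all_labels: frozenset[str]) -> float | None:
        return self.supports.get(_canonical_split(labels, all_labels))


def _canonical_split(
    side: frozenset[str], all_labels: frozenset[str]
) -> frozenset[str]:
    anchor = min(all_labels)
    return frozenset(all_labels - side) if anchor in side else frozenset(side)


def _validate_matrix(dm: DistanceMatrix) -> None:
    if len(dm.labels) < 3:
        raise ValueError("need at least 3 taxa to build a tree")
    bad = sorted(dm.undefined_pairs)
    nan_pairs = [
        (dm.labels[i], dm.labels[j])
        for i, j in zip(*np.triu_indices(len(dm.labels), k=1))
        if math.isnan(dm.d[i, j])
    ]
    bad = sorted(set(bad) | set(nan_pairs))
    if bad:
        listing = "; ".join(f"{a}~{b}" for a, b in bad[:10])
        raise ValueError(f"undefined distances for pairs: {listing}")


def build_nj_tree(dm: DistanceMatrix, variant: str = "bionj") -> dendropy.Tree:
    """Agglomerate a distance matrix into an unrooted binary tree.

    ``bionj`` weights each reduction step to minimize the variance of the
    new distance estimates; ``classic_nj`` is the plain Saitou-Nei update
    (the two coincide on additive data). Ties in the Q criterion are broken
    by the lexicographically smallest pair of cluster representative
    labels. Negative branch-length estimates are clamped to zero with the
    deficit moved to the sibling edge, keeping path lengths unchanged.
    """
    if variant not in ("bionj", "classic_nj"):
        raise ValueError(f"unknown variant {variant!r}")
    _validate_matrix(dm)
    labels = list(dm.labels)
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)

    nodes: list[dendropy.Node] = []
    reps: list[str] = []  # representative label per active cluster (for ties)
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(lab)
        nodes.append(nd)
        reps.append(lab)
    D = dm.d.astype(float).copy()
    V = D.copy()  # BioNJ variance estimates; unused by classic update
    active = list(range(len(labels)))

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((reps[active[a]], reps[active[b]]))), a, b)
            for a, b in ties
            if a < b
        )
        ai, bi = best[1], best[2]
        i, j = active[ai], active[bi]
        dij = D[i, j]
        bi_len = 0.5 * dij + (R[ai] - R[bi]) / (2.0 * (r - 2))
        bj_len = dij - bi_len
        # clamp negatives, shifting the deficit onto the sibling edge
        if bi_len < 0:
            bj_len += bi_len
            bi_len = 0.0
        if bj_len < 0:
            bi_len += bj_len
            bj_len = 0.0

        others = [k for k in active if k not in (i, j)]
        if variant == "bionj" and V[i, j] > 0 and others:
            lam = 0.5 + (V[j, others].sum() - V[i, others].sum()) / (
                2.0 * (r - 2) * V[i, j]
            )
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = bi_len
        parent.add_child(nodes[j])
        nodes[j].edge.length = bj_len

        for k in others:
            D[i, k] = D[k, i] = (
                lam * (D[i, k] - bi_len) + (1.0 - lam) * (D[j, k] - bj_len)
            )
            V[i, k] = V[k, i] = (
                lam * V[i, k] + (1.0 - lam) * V[j, k] - lam * (1.0 - lam) * V[i, j]
            )
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    # final trifurcation via the three-point formulas
    x, y, z = active
    bx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    by = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    bz = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    for node_idx, blen in ((x, bx), (y, by), (z, bz)):
        tree.seed_node.add_child(nodes[node_idx])
        nodes[node_idx].edge.length = max(0.0, blen)
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def _rooted_clone(tree: dendropy.Tree, root_policy: str = "midpoint") -> dendropy.Tree:
    clone = tree.clone(depth=1)
    if root_policy == "midpoint":
        clone.reroot_at_midpoint(update_bipartitions=False)
        clone.is_rooted = True
    elif root_policy == "keep":
        clone.is_rooted = True
    else:
        raise ValueError(f"unknown root_policy {root_policy!r}")
    return clone


def mrca(
    tree: dendropy.Tree, labels: set[str] | frozenset[str], root_policy: str = "midpoint"
) -> dendropy.Node:
    """Most recent common ancestor of *labels* on the (midpoint-)rooted tree.

    Returns the node of a rooted clone; its ``leaf_nodes()`` and edge
    lengths can be queried directly.
    """
    labels = set(labels)
    if len(labels) < 2:
        raise ValueError("MRCA needs at least two labels")
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = labels - leaf_labels
    if unknown:
        raise KeyError(f"labels not on tree: {', '.join(sorted(unknown))}")
    rooted = _rooted_clone(tree, root_policy)
    node = rooted.mrca(taxon_labels=list(labels))
    if node is None:
        raise RuntimeError("MRCA query failed")
    return node


def otu_internal_distance(
    tree: dendropy.Tree, otu: OTU, root_policy: str = "midpoint"
) -> float:
    """Maximum path length from the OTU's MRCA down to any member leaf.

    Undefined (raises :class:`SingletonDistanceError`) for singletons;
    evaluates to 0 for quasi-singletons, whose members sit on zero-length
    branches below their common ancestor.
    """
    if otu.size < 2:
        raise SingletonDistanceError(
            f"internal distance undefined for singleton {otu.otu_id}"
        )
    anc = mrca(tree, set(otu.member_ids), root_policy)
    members = set(otu.member_ids)
    best = 0.0
    for leaf in anc.leaf_iter():
        if leaf.taxon.label not in members:
            continue
        dist = 0.0
        node = leaf
        while node is not anc:
            dist += node.edge.length or 0.0
            node = node.parent_node
        best = max(best, dist)
    return best


def otu_internal_distance_pairwise(dm: DistanceMatrix, otu: OTU) -> float:
    """Tree-free fallback: half the maximum within-OTU pairwise distance."""
    if otu.size < 2:
        raise SingletonDistanceError(
            f"internal distance undefined for singleton {otu.otu_id}"
        )
    idx = [dm.labels.index(m) for m in otu.member_ids]
    sub = dm.d[np.ix_(idx, idx)]
    return float(np.nanmax(sub)) / 2.0


def _tree_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(all_labels) - 1:
            splits.add(_canonical_split(side, all_labels))
    return splits


def bootstrap_supports(
    aln: Alignment,
    replicates: int = 100,
    seed: int | None = None,
    variant: str = "bionj",
    site_policy: str = "complete_deletion",
) -> CladeSupport:
    """Column-resampling bootstrap percentages for the NJ tree's splits.

    Columns are resampled with replacement per replicate, the K2P matrix
    and tree are rebuilt, and each original bipartition is scored by the
    fraction of replicate trees containing it. Replicates whose matrix has
    undefined distances are skipped (and still counted in the denominator).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    codes = _encode(aln)
    mask = _site_mask(aln, site_policy)
    s, v, sites = _all_pair_counts(codes, mask)
    original = build_nj_tree(k2p_matrix_from_counts(aln.ids, s, v, sites), variant)
    target_splits = _tree_splits(original)
    counts = {split: 0 for split in target_splits}
    n_cols = aln.column_count
    for _ in range(replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        rep_codes = codes[:, idx]
        rep_mask = mask[idx]
        rs, rv, rsites = _all_pair_counts(rep_codes, rep_mask)
        try:
            rep_tree = build_nj_tree(
                k2p_matrix_from_counts(aln.ids, rs, rv, rsites), variant
            )
        except ValueError:
            continue  # skipped replicate still counts toward the total
        rep_splits = _tree_splits(rep_tree)
        for split in target_splits & rep_splits:
            counts[split] += 1
    supports = {
        split: 100.0 * c / replicates for split, c in counts.items()
    }
    return CladeSupport(supports=supports, replicates=replicates, seed=seed)


@dataclass(frozen=True)
class GroupReport:
    group: str
    n_leaves: int
    monophyletic: bool
    mean_clade_support: float | None


@dataclass(frozen=True)
class MonophylyReport:
    groups: tuple[GroupReport, ...]
    tree_mean_support: float
    n_supports_over_49: int


def monophyly_report(
    tree: dendropy.Tree,
    supports: CladeSupport,
    grouping: dict[str, str],
    root_policy: str = "midpoint",
) -> MonophylyReport:
    """Check each label group for monophyly and average its clade supports.

    *grouping* maps leaf label -> group name. A group is monophyletic when
    its leaves are exactly the leaf set of their MRCA on the rooted tree.
    The clade support average runs over the internal splits inside (and
    including) the group's MRCA that carry a bootstrap value.
    """
    all_labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    by_group: dict[str, set[str]] = {}
    for label, group in grouping.items():
        by_group.setdefault(group, set()).add(label)
    reports = []
    rooted = _rooted_clone(tree, root_policy)
    for group in sorted(by_group):
        members = by_group[group] & all_labels
        if not members:
            raise ValueError(f"group {group!r} has no leaves on the tree")
        if len(members) == 1:
            reports.append(GroupReport(group, 1, True, None))
            continue
        anc = rooted.mrca(taxon_labels=list(members))
        clade_leaves = {lf.taxon.label for lf in anc.leaf_iter()}
        mono = clade_leaves == members
        vals = []
        for node in anc.preorder_iter():
            if node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            val = supports.support_for(side, all_labels)
            if val is not None:
                vals.append(val)
        mean_support = float(np.mean(vals)) if vals else None
        reports.append(GroupReport(group, len(members), mono, mean_support))
    all_vals = list(supports.supports.values())
    return MonophylyReport(
        groups=tuple(reports),
        tree_mean_support=float(np.mean(all_vals)) if all_vals else 0.0,
        n_supports_over_49=sum(1 for val in all_vals if val > 49.0),
    )
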