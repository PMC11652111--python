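"""Phylogeny handling, Faith's PD and phylogenetic endemism.

Faith's PD of a taxon set is the total branch length of the minimal subtree
spanning the set; by default the subtree is anchored at the root (the
dominant convention in community-phylogenetics software), so even a single
tip has positive PD (its root path).

Phylogenetic endemism (PE) down-weights each branch by its range size —
here the number of elevational belts occupied by the branch's descendants —
so narrowly distributed lineages contribute disproportionately. Because
every branch's length is split exactly across the belts occupying it, PE
summed over belts equals the PD of the pooled assemblage: an algebraic
identity this module preserves to floating-point accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .belts import BeltMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "load_tree",
    "tip_labels",
    "total_tree_length",
    "match_tree_matrix",
    "faith_pd",
    "phylogenetic_endemism",
    "patristic_distance_matrix",
]


def load_tree(path: str | Path) -> dendropy.Tree:
    """Load and validate a rooted Newick tree with branch lengths.

    Polytomies are allowed. Every branch except the root's subtending edge
    must carry a length; duplicate tip labels and trees with fewer than two
    tips are rejected.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"could not parse Newick file {path}: {exc}") from exc
    return validate_tree(tree)


def validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = tip_labels(tree)
    if len(labels) < 2:
        raise ValueError("tree must have at least 2 tips")
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    missing = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            tag = node.taxon.label if node.taxon else f"internal node (children: " + ",".join(
                c.taxon.label for c in node.leaf_iter() if c.taxon
            ) + ")"
            missing.append(tag)
    if missing:
        raise ValueError(f"branches lacking lengths: {missing}")
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def total_tree_length(tree: dendropy.Tree) -> float:
    return sum(
        node.edge.length or 0.0 for node in tree.preorder_node_iter() if node is not tree.seed_node
    )


@dataclass
class MatchReport:
    dropped_from_tree: list[str]
    dropped_from_matrix: list[str]
    n_shared: int


def match_tree_matrix(
    tree: dendropy.Tree, matrix: BeltMatrix
) -> tuple[dendropy.Tree, BeltMatrix, MatchReport]:
    """Prune tree and matrix down to their shared taxa.

    Returns a pruned copy of the tree (original untouched), the matrix
    restricted to shared taxa, and a report of what was dropped from each
    side. Fewer than two shared taxa is an error.
    """
    tree_taxa = set(tip_labels(tree))
    mat_taxa = set(matrix.taxa)
    shared = tree_taxa & mat_taxa
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} taxa shared between tree ({len(tree_taxa)}) "
            f"and matrix ({len(mat_taxa)})"
        )
    report = MatchReport(
        dropped_from_tree=sorted(tree_taxa - shared),
        dropped_from_matrix=sorted(mat_taxa - shared),
        n_shared=len(shared),
    )
    if report.dropped_from_tree or report.dropped_from_matrix:
        logger.info(
            "matched tree/matrix: %d shared, %d dropped from tree, %d from matrix",
            len(shared), len(report.dropped_from_tree), len(report.dropped_from_matrix),
        )
    if report.dropped_from_tree:
        pruned = tree.extract_tree_with_taxa_labels(labels=shared)
    else:
        pruned = tree.clone(depth=1)
    return pruned, matrix.restrict_taxa(shared), report


def _descendant_counts(tree: dendropy.Tree, targets: set[str]) -> dict:
    """Per node: number of target tips among its descendants (incl. itself)."""
    counts: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            counts[node] = 1 if node.taxon.label in targets else 0
        else:
            counts[node] = sum(counts[c] for c in node.child_nodes())
    return counts


def faith_pd(
    tree: dendropy.Tree, taxon_set: Iterable[str], include_root: bool = True
) -> float:
    """Faith's phylogenetic diversity of ``taxon_set``.

    Sum of branch lengths of the minimal spanning subtree. With
    ``include_root`` (default) the subtree is anchored at the root; without
    it, branches on which *all* selected tips hang together (the MRCA's root
    path) are excluded, so a single tip has PD 0.
    """
    targets = set(taxon_set)
    if not targets:
        raise ValueError("taxon_set is empty")
    present = set(tip_labels(tree))
    unknown = targets - present
    if unknown:
        raise KeyError(f"taxa not in tree: {sorted(unknown)}")
    counts = _descendant_counts(tree, targets)
    k = len(targets)
    total = 0.0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        c = counts[node]
        if c == 0:
            continue
        if not include_root and c == k:
            continue
        total += node.edge.length or 0.0
    return total


def phylogenetic_endemism(tree: dendropy.Tree, matrix: BeltMatrix) -> pd.Series:
    """Per-belt phylogenetic endemism.

    ``PE(belt) = sum over branches b occupied by the belt of len(b)/r(b)``
    where a belt occupies a branch iff at least one of the branch's
    descendant tips is present in the belt, and ``r(b)`` is the number of
    belts occupying the branch. Empty belts get PE 0 (with a warning).
    """
    labels = set(tip_labels(tree))
    if labels != set(matrix.taxa):
        raise ValueError("tree and matrix taxa differ; run match_tree_matrix first")
    pres = matrix.presence.to_numpy(dtype=bool)  # belts x taxa
    col = {t: j for j, t in enumerate(matrix.taxa)}
    n_belts = pres.shape[0]

    pe = np.zeros(n_belts)
    occ: dict = {}  # node -> boolean occupancy vector over belts
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            v = pres[:, col[node.taxon.label]].copy()
        else:
            v = np.zeros(n_belts, dtype=bool)
            for c in node.child_nodes():
                v |= occ[c]
        occ[node] = v
        if node is tree.seed_node:
            continue
        r = int(v.sum())
        if r > 0:
            pe[v] += (node.edge.length or 0.0) / r

    empty = [lo for lo, v in zip(matrix.grid.lower_bounds, ~pres.any(axis=1)) if v]
    if empty:
        logger.warning("belts with no taxa get PE 0: belt_lo=%s", empty)
    return pd.Series(pe, index=matrix.presence.index, name="PE")


def patristic_distance_matrix(
    tree: dendropy.Tree, labels: Sequence[str]
) -> np.ndarray:
    """Symmetric matrix of tip-to-tip path-length (patristic) distances.

    Computed in one post-order pass: at each internal node, tips in
    different child subtrees are joined through that node.
    """
    idx = {l: i for i, l in enumerate(labels)}
    if len(idx) != len(labels):
        raise ValueError("duplicate labels requested")
    n = len(labels)
    dm = np.zeros((n, n))
    # node -> (array of tip indices, array of distances from node to those tips)
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            if lab in idx:
                below[node] = ([idx[lab]], [0.0])
            else:
                below[node] = ([], [])
        else:
            groups = []
            for c in node.child_nodes():
                tips, dists = below.pop(c)
                bl = c.edge.length or 0.0
                groups.append(([t for t in tips], [d + bl for d in dists]))
            for a in range(len(groups)):
                ta, da = groups[a]
                for b in range(a + 1, len(groups)):
                    tb, db = groups[b]
                    for i, di in zip(ta, da):
                        for j, dj in zip(tb, db):
                            dm[i, j] = dm[j, i] = di + dj
            below[node] = (
                [t for g in groups for t in g[0]],
                [d for g in groups for d in g[1]],
            )
    found = set(below[tree.seed_node][0])
    missing = [l for l in labels if idx[l] not in found]
    if missing:
        raise KeyError(f"taxa not in tree: {missing}")
    return dm
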