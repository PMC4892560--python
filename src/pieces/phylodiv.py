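"""Evolutionary distinctiveness and set-level phylogenetic similarity.

Evolutionary distinctiveness (ED) is the fair-proportion partition of a
tree's branch length: each edge's length is divided equally among the
tips descending from it, and a tip's ED is the sum of its shares along
the root-to-tip path. ED therefore sums to the tree's total branch
length (root edge excluded). Polytomies inflate ED — an unresolved node
pretends its daughters are maximally distinct — so an optional
correction down-weights edges descending from polytomous nodes.

PhyloSor measures the branch length shared by two tip sets relative to
their total branch lengths; the Jaccard index is its purely taxonomic
counterpart.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from ._arrays import TreeArrays
from .errors import TreeStructureError

__all__ = [
    "fair_proportion",
    "ed_with_polytomy_correction",
    "phylosor",
    "jaccard_similarity",
]


def _check_lengths(tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise TreeStructureError(
                "branch lengths required (parse with a default_length to fill gaps)"
            )


def _ed_from_lengths(ta: TreeArrays, lengths: np.ndarray) -> pd.Series:
    ndesc = ta.n_descendant_tips()
    share = np.zeros(ta.n_nodes)
    share[1:] = lengths[1:] / ndesc[1:]  # root edge excluded
    acc = np.zeros(ta.n_nodes)
    for i in range(1, ta.n_nodes):  # preorder
        acc[i] = acc[ta.parent[i]] + share[i]
    ed = pd.Series(acc[ta.leaf_indices], index=ta.leaf_labels, name="ed")
    return ed.sort_index()


def fair_proportion(tree) -> pd.Series:
    """Fair-proportion ED per tip, indexed by tip label (sorted).

    ED(tip) = Σ over root-to-tip edges of edge length / number of tips
    below the edge. Σ over tips equals total branch length.
    """
    _check_lengths(tree)
    ta = TreeArrays(tree)
    if ta.n_tips < 2:
        raise TreeStructureError("ED requires at least 2 tips")
    return _ed_from_lengths(ta, ta.length)


def ed_with_polytomy_correction(tree, correction: bool = True) -> pd.Series:
    """ED with an optional polytomy (Isaac-style) down-weighting.

    When ``correction`` is true, each edge descending from a node with
    c > 2 children has its length multiplied by 2/c before the fair
    proportion is taken. The factor is 1 on bifurcating nodes, so the
    corrected ED equals :func:`fair_proportion` exactly on fully
    resolved trees, and daughters of polytomies can only lose ED.
    """
    if not correction:
        return fair_proportion(tree)
    _check_lengths(tree)
    ta = TreeArrays(tree)
    if ta.n_tips < 2:
        raise TreeStructureError("ED requires at least 2 tips")
    n_children = np.array([max(len(c), 1) for c in ta.children], dtype=float)
    factor = np.ones(ta.n_nodes)
    parents = ta.parent[1:]
    factor[1:] = np.minimum(1.0, 2.0 / n_children[parents])
    return _ed_from_lengths(ta, ta.length * factor)


def _spanning_edge_mask(ta: TreeArrays, labels: Iterable[str]) -> np.ndarray:
    """Nodes (≠ root) lying on the union of root-to-tip paths of ``labels``."""
    tip_mask = ta.leaf_mask(labels)
    if not tip_mask.any():
        raise TreeStructureError("tip set must be non-empty")
    in_span = np.zeros(ta.n_nodes, dtype=bool)
    in_span[ta.leaf_indices[tip_mask]] = True
    for i in ta.postorder:
        if in_span[i] and ta.parent[i] > 0:
            in_span[ta.parent[i]] = True
    in_span[0] = False
    return in_span


def phylosor(tree, set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """PhyloSor similarity of two tip sets: 2·BL_shared / (BL_a + BL_b).

    Spanning branch length is measured over the union of root-to-tip
    paths (root-spanning convention; the root edge itself is excluded),
    and the shared component over edges common to both spanning sets.
    Symmetric, 1 for identical sets, 0 for sets in different root
    subtrees.
    """
    _check_lengths(tree)
    ta = TreeArrays(tree)
    mask_a = _spanning_edge_mask(ta, set_a)
    mask_b = _spanning_edge_mask(ta, set_b)
    bl_a = float(ta.length[mask_a].sum())
    bl_b = float(ta.length[mask_b].sum())
    shared = float(ta.length[mask_a & mask_b].sum())
    if bl_a + bl_b == 0:
        raise TreeStructureError("both spanning sets have zero branch length")
    return 2.0 * shared / (bl_a + bl_b)


def jaccard_similarity(set_a: Iterable, set_b: Iterable) -> float:
    """|A ∩ B| / |A ∪ B| for two non-empty label sets."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("sets must be non-empty")
    return len(a & b) / len(a | b)
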