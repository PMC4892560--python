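"""Tree I/O and manipulation: Newick read/write, pruning, grafting,
resolution, and short-edge collapse.

Trees are represented as rooted :class:`dendropy.Tree` objects with
branch lengths in arbitrary (typically time) units; polytomies are
first-class throughout. The manipulation routines mirror the standard
workflow for assembling a supertree of a focal taxon set from a backbone
phylogeny: unsampled taxa are grafted at the crown node of their genus
(or family, when the genus is absent) with a terminal branch equal to the
crown depth, which keeps an ultrametric backbone ultrametric; non-target
tips are pruned; and short internal edges can be collapsed into
polytomies to probe the sensitivity of downstream statistics to
phylogenetic resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy

from ._arrays import TreeArrays
from .errors import GraftError, NewickError, TreeStructureError

__all__ = [
    "GraftAssignment",
    "read_newick",
    "write_newick",
    "tip_labels",
    "tip_depths",
    "is_ultrametric",
    "prune",
    "graft_taxa",
    "resolution",
    "collapse_short_edges",
    "total_branch_length",
]


@dataclass(frozen=True)
class GraftAssignment:
    """A taxon to add to the tree, with its genus and a family fallback."""

    new_taxon: str
    genus: str
    family: str | None = None


def read_newick(text: str, default_length: float = 0.0) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree.

    Quoted labels, internal-node labels and square-bracket comments are
    accepted; missing branch lengths are set to ``default_length``.
    Raises :class:`NewickError` on syntax errors (message includes the
    parser's position) and :class:`TreeStructureError` on duplicate tips.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        if "Duplicate taxon labels" in str(exc):
            raise TreeStructureError(f"duplicate tip label: {exc}") from exc
        raise NewickError(f"Newick parse error: {exc}") from exc
    seen: set[str] = set()
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else leaf.label
        if label is None:
            raise TreeStructureError("unlabeled tip in Newick input")
        if label in seen:
            raise TreeStructureError(f"duplicate tip label {label!r}")
        seen.add(label)
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = default_length
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a one-line Newick string (lengths preserved)."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in the tree's traversal order."""
    return [
        (leaf.taxon.label if leaf.taxon is not None else leaf.label)
        for leaf in tree.leaf_node_iter()
    ]


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length per tip (root edge included when present)."""
    ta = TreeArrays(tree)
    depths = ta.node_depths()
    return {lbl: float(depths[i]) for lbl, i in zip(ta.leaf_labels, ta.leaf_indices)}


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> bool:
    """True when all root-to-tip depths agree within ``tol``."""
    d = list(tip_depths(tree).values())
    return max(d) - min(d) <= tol


def total_branch_length(tree: dendropy.Tree, include_root_edge: bool = False) -> float:
    """Sum of branch lengths, excluding the root edge by default."""
    ta = TreeArrays(tree)
    total = float(ta.length.sum())
    if not include_root_edge:
        total -= float(ta.length[0])
    return total


def prune(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Restrict a tree to ``keep`` tips, suppressing degree-2 nodes.

    Suppressed nodes have their two incident branch lengths summed, so
    root-to-tip path lengths of retained tips are unchanged. Requires
    ``keep`` to be a subset of the tips with at least two members.
    """
    keep = set(keep)
    present = set(tip_labels(tree))
    unknown = keep - present
    if unknown:
        raise TreeStructureError(f"tips not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise TreeStructureError("prune requires at least 2 tips to keep")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(keep))
    return pruned


def _mrca(nodes: list[dendropy.Node]) -> dendropy.Node:
    """Most recent common ancestor by ancestor-path intersection."""
    paths = []
    for nd in nodes:
        path = []
        cur = nd
        while cur is not None:
            path.append(cur)
            cur = cur.parent_node
        paths.append(path)
    common = set(map(id, paths[0]))
    for path in paths[1:]:
        common &= set(map(id, path))
    for nd in paths[0]:  # first common ancestor walking rootward from nodes[0]
        if id(nd) in common:
            return nd
    raise TreeStructureError("nodes share no common ancestor (forest?)")


def graft_taxa(
    tree: dendropy.Tree,
    assignments: Iterable[GraftAssignment],
    genus_map: Mapping[str, str],
    family_map: Mapping[str, str] | None = None,
    singleton_policy: str = "split",
) -> dendropy.Tree:
    """Attach new taxa at the crown nodes of their genera (or families).

    Each new taxon is added as a child of the MRCA of its genus's tips,
    with terminal branch length equal to that node's crown depth, forming
    (or enlarging) a polytomy; an ultrametric tree therefore remains
    ultrametric. Taxa whose genus is absent fall back to the family
    crown. A genus represented by a single tip is handled per
    ``singleton_policy``: ``"split"`` bisects that tip's terminal edge to
    create a two-tip genus clade; ``"family"`` uses the family fallback.

    ``genus_map``/``family_map`` map existing *and* newly added tip
    labels to their genus/family; taxa grafted earlier in the call count
    as congeners for later assignments.
    """
    if singleton_policy not in ("split", "family"):
        raise ValueError("singleton_policy must be 'split' or 'family'")
    out = tree.clone(depth=1)
    genus_tips: dict[str, list[dendropy.Node]] = {}
    family_tips: dict[str, list[dendropy.Node]] = {}
    labels: set[str] = set()
    for leaf in out.leaf_node_iter():
        lbl = leaf.taxon.label if leaf.taxon is not None else leaf.label
        labels.add(lbl)
        if lbl in genus_map:
            genus_tips.setdefault(genus_map[lbl], []).append(leaf)
        if family_map and lbl in family_map:
            family_tips.setdefault(family_map[lbl], []).append(leaf)

    def _new_leaf(label: str) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = out.taxon_namespace.require_taxon(label=label)
        return node

    for asg in assignments:
        if asg.new_taxon in labels:
            raise GraftError(f"taxon {asg.new_taxon!r} already in tree")
        congeners = genus_tips.get(asg.genus, [])
        leaf = None
        if len(congeners) >= 2:
            crown = _mrca(congeners)
            leaf = _new_leaf(asg.new_taxon)
            crown.add_child(leaf)
            # crown depth measured over the pre-existing children only
            leaf.edge.length = max(_crown_depth_excluding(crown, leaf), 0.0)
        elif len(congeners) == 1 and singleton_policy == "split":
            tip = congeners[0]
            half = (tip.edge.length or 0.0) / 2.0
            parent = tip.parent_node
            if parent is None:
                raise GraftError(
                    f"cannot split terminal edge of root tip {asg.genus!r}"
                )
            joint = dendropy.Node()
            parent.remove_child(tip)
            parent.add_child(joint)
            joint.edge.length = half
            joint.add_child(tip)
            tip.edge.length = half
            leaf = _new_leaf(asg.new_taxon)
            joint.add_child(leaf)
            leaf.edge.length = half
        else:
            fam = asg.family
            relatives = family_tips.get(fam, []) if fam else []
            if len(relatives) >= 2:
                crown = _mrca(relatives)
                leaf = _new_leaf(asg.new_taxon)
                crown.add_child(leaf)
                leaf.edge.length = max(_crown_depth_excluding(crown, leaf), 0.0)
            else:
                raise GraftError(
                    f"cannot place {asg.new_taxon!r}: genus {asg.genus!r} "
                    f"and family {asg.family!r} both unresolvable"
                )
        labels.add(asg.new_taxon)
        genus_tips.setdefault(asg.genus, []).append(leaf)
        if family_map is not None and asg.family is not None:
            family_tips.setdefault(asg.family, []).append(leaf)
    return out


def _crown_depth_excluding(
    node: dendropy.Node, skip: dendropy.Node | None = None
) -> float:
    """Maximum node-to-descendant-tip distance — the crown depth, unique on
    ultrametric clades — ignoring the subtree rooted at ``skip``."""
    best = 0.0
    stack = [(node, 0.0)]
    while stack:
        nd, acc = stack.pop()
        for child in nd.child_nodes():
            if child is skip:
                continue
            d = acc + (child.edge.length or 0.0)
            if child.is_leaf():
                best = max(best, d)
            else:
                stack.append((child, d))
    return best


def resolution(tree: dendropy.Tree) -> float:
    """Phylogenetic resolution: internal nodes over the fully-resolved count.

    A fully bifurcating rooted tree on *n* tips has *n* − 1 internal
    nodes, so the ratio lies in (0, 1], reaching 1/(n−1) for a star.
    """
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    if n_tips < 3:
        raise TreeStructureError("resolution requires at least 3 tips")
    n_internal = sum(1 for nd in tree.preorder_node_iter() if not nd.is_leaf())
    return n_internal / (n_tips - 1)


def collapse_short_edges(tree: dendropy.Tree, threshold: float) -> dendropy.Tree:
    """Collapse internal edges shorter than ``threshold`` into polytomies.

    Strictly-shorter internal edges are removed and the child node's
    children reattached to its parent with their own lengths unchanged
    (di2multi semantics). Terminal edges are never touched, so no tip is
    lost; resolution is non-increasing in ``threshold`` and the
    operation is idempotent at a fixed threshold.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    out = tree.clone(depth=1)
    # children-before-parents so freshly reattached nodes are not revisited
    for node in out.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        if (node.edge.length or 0.0) < threshold:
            parent = node.parent_node
            for child in list(node.child_nodes()):
                node.remove_child(child)
                parent.add_child(child)
            parent.remove_child(node)
    return out
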