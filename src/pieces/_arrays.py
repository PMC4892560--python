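"""Flat array view of a dendropy tree.

The numeric kernels (fair proportion, sum of sister differences, Brownian
simulation, PhyloSor) all need the same things: a parent pointer per node,
edge lengths, child lists, and traversal orders. Building them once per
top-level call keeps the kernels vectorizable over many trait replicates
without touching dendropy's object graph in inner loops.
"""

from __future__ import annotations

import numpy as np

from .errors import TreeStructureError


class TreeArrays:
    """Immutable index-based snapshot of a rooted dendropy tree.

    Nodes are indexed in preorder (root = 0). ``parent[i]`` is -1 for the
    root; ``length[i]`` is the length of the edge above node ``i`` (0.0 when
    absent). ``postorder`` lists node indices children-before-parents.
    """

    def __init__(self, tree):
        nodes = list(tree.preorder_node_iter())
        self.n_nodes = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        self.length = np.zeros(self.n_nodes, dtype=float)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        is_leaf = np.zeros(self.n_nodes, dtype=bool)
        labels = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                if nd.edge.length is not None:
                    self.length[i] = float(nd.edge.length)
            if nd.is_leaf():
                is_leaf[i] = True
                labels.append(nd.taxon.label if nd.taxon is not None else nd.label)
        self.is_leaf = is_leaf
        self.leaf_indices = np.flatnonzero(is_leaf)
        if any(lbl is None for lbl in labels):
            raise TreeStructureError("every tip must carry a label")
        self.leaf_labels: list[str] = labels
        self.n_tips = len(labels)
        self.label_to_leaf_pos = {lbl: j for j, lbl in enumerate(labels)}
        if len(self.label_to_leaf_pos) != self.n_tips:
            raise TreeStructureError("duplicate tip labels in tree")
        # preorder == identity by construction; postorder by reversal works
        # because every parent precedes its children in preorder.
        self.preorder = np.arange(self.n_nodes, dtype=np.int64)
        self.postorder = self.preorder[::-1].copy()
        self.internal_postorder = [i for i in self.postorder if not is_leaf[i]]

    # ------------------------------------------------------------------
    def n_descendant_tips(self) -> np.ndarray:
        """Number of tips at or below each node."""
        counts = self.is_leaf.astype(np.int64).copy()
        for i in self.internal_postorder:
            counts[i] = sum(counts[c] for c in self.children[i])
        return counts

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length for every node (root edge included if set)."""
        depth = np.zeros(self.n_nodes)
        depth[0] = self.length[0]
        for i in range(1, self.n_nodes):
            depth[i] = depth[self.parent[i]] + self.length[i]
        return depth

    def tip_values_to_node_matrix(self, tip_matrix: np.ndarray) -> np.ndarray:
        """Scatter a (n_tips, m) matrix of tip values into a (n_nodes, m) one."""
        out = np.zeros((self.n_nodes,) + tip_matrix.shape[1:], dtype=float)
        out[self.leaf_indices] = tip_matrix
        return out

    def leaf_mask(self, labels) -> np.ndarray:
        """Boolean mask over leaf positions for a collection of tip labels."""
        mask = np.zeros(self.n_tips, dtype=bool)
        for lbl in labels:
            try:
                mask[self.label_to_leaf_pos[lbl]] = True
            except KeyError:
                raise TreeStructureError(f"tip {lbl!r} not in tree") from None
        return mask
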