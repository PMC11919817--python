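"""Rooted phylogenetic trees with branch lengths, backed by scikit-bio.

The UniFrac computations need, for every edge j, its length b_j and the set
of leaves descending through it. ``PhyloTree`` caches both as arrays: an
edge-length vector and a boolean (n_edges x n_leaves) descendant-leaf matrix,
so per-sample branch profiles reduce to a single matrix-vector product.
"""

from __future__ import annotations

import io
import warnings

import numpy as np
from skbio import TreeNode


class PhyloTree:
    """Rooted tree with finite non-negative branch lengths and unique leaf labels."""

    def __init__(self, tree: TreeNode, _validated: bool = False):
        self._tree = tree
        if not _validated:
            self._validate()
        self._build_edge_index()

    # ------------------------------------------------------------------ IO

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        """Parse a Newick string; midpoint-root unrooted (basal trifurcation) trees."""
        try:
            tree = TreeNode.read(io.StringIO(newick), format="newick")
        except Exception as exc:  # skbio raises NewickFormatError subclasses
            raise ValueError(f"unparseable Newick: {exc}") from exc
        if len(tree.children) > 2:
            warnings.warn(
                "input tree is unrooted (basal multifurcation); midpoint-rooting. "
                "UniFrac values depend on the root placement.",
                UserWarning,
                stacklevel=2,
            )
            tree = tree.root_at_midpoint()
        return cls(tree)

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        buf = io.StringIO()
        self._tree.write(buf, format="newick")
        return buf.getvalue().strip()

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------ validation

    def _validate(self) -> None:
        names = [t.name for t in self._tree.tips()]
        if any(n is None for n in names):
            raise ValueError("tree has unlabeled leaves")
        if len(set(names)) != len(names):
            raise ValueError("tree leaf labels are not unique")
        for node in self._tree.traverse(include_self=False):
            if node.length is None:
                raise ValueError(
                    f"edge above node {node.name or '<internal>'} has no branch length"
                )
            if not np.isfinite(node.length) or node.length < 0:
                raise ValueError(
                    f"edge above node {node.name or '<internal>'} has invalid "
                    f"branch length {node.length}"
                )

    def _build_edge_index(self) -> None:
        self.leaf_names: list[str] = [t.name for t in self._tree.tips()]
        leaf_pos = {n: i for i, n in enumerate(self.leaf_names)}
        edges = list(self._tree.traverse(include_self=False))
        self.n_edges = len(edges)
        self.branch_lengths = np.array([e.length for e in edges], dtype=float)
        # descendant-leaf incidence matrix: row j marks leaves below edge j
        desc = np.zeros((self.n_edges, len(self.leaf_names)), dtype=bool)
        for j, node in enumerate(edges):
            if node.is_tip():
                desc[j, leaf_pos[node.name]] = True
            else:
                for t in node.tips():
                    desc[j, leaf_pos[t.name]] = True
        self.descendants = desc

    # ------------------------------------------------------------- queries

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())

    def patristic_distances(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path-length matrix, in ``leaf_names`` order."""
        dm = self._tree.tip_tip_distances()
        ids = list(dm.ids)
        order = [ids.index(n) for n in self.leaf_names]
        return list(self.leaf_names), dm.data[np.ix_(order, order)]

    def shear(self, leaf_subset: list[str]) -> "PhyloTree":
        """Prune to a leaf subset, collapsing unbranched paths by summing lengths."""
        missing = set(leaf_subset) - set(self.leaf_names)
        if missing:
            raise ValueError(f"leaves not in tree: {sorted(missing)}")
        sub = self._tree.copy().shear(set(leaf_subset))
        sub.prune()
        return PhyloTree(sub)
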