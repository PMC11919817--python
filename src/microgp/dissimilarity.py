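"""Beta-diversity dissimilarities: Jaccard, Bray-Curtis, and both UniFrac variants.

For communities A and B with per-taxon abundances A_i, B_i:

* Jaccard           d = 1 - |A n B| / |A u B|           on presence sets
* Bray-Curtis       d = sum|A_i - B_i| / sum(A_i + B_i)
* unweighted UniFrac d = sum_j b_j |I(A_j>0) - I(B_j>0)| / denominator
* weighted UniFrac   d = sum_j b_j |A_j - B_j| / sum_j b_j (A_j + B_j)

where b_j is the length of branch j and A_j is the cumulative relative
abundance of the leaves descending through branch j. The unweighted UniFrac
denominator has two conventions: ``all_branches`` sums every branch of the
tree; ``union_branches`` (canonical UniFrac) sums only branches present in at
least one of the two communities. All four measures lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from microgp.containers import AbundanceTable, DistanceMatrix
from microgp.tree import PhyloTree

METRICS = ("jaccard", "bray_curtis", "unweighted_unifrac", "weighted_unifrac")


def _as_vec(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be a 1-D community vector")
    if np.any(a < 0) or not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must be finite and non-negative")
    return a


def jaccard(a, b) -> float:
    """Jaccard dissimilarity on presence sets (presence = entry > 0)."""
    a, b = _as_vec(a, "a"), _as_vec(b, "b")
    if a.shape != b.shape:
        raise ValueError("community vectors have different lengths")
    pa, pb = a > 0, b > 0
    union = np.count_nonzero(pa | pb)
    if union == 0:
        raise ValueError("both communities are empty; Jaccard undefined (0/0)")
    return 1.0 - np.count_nonzero(pa & pb) / union


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity on abundance vectors."""
    a, b = _as_vec(a, "a"), _as_vec(b, "b")
    if a.shape != b.shape:
        raise ValueError("community vectors have different lengths")
    denom = float(np.sum(a + b))
    if denom == 0:
        raise ValueError("both communities are empty; Bray-Curtis undefined")
    return float(np.sum(np.abs(a - b)) / denom)


@dataclass
class BranchProfile:
    """Per-branch view of one community: b_j, cumulative abundance A_j, presence."""

    branch_lengths: np.ndarray
    abundances: np.ndarray  # A_j: summed leaf abundance below branch j
    presence: np.ndarray  # I(A_j > 0)


def branch_profile(tree: PhyloTree, sample) -> BranchProfile:
    """Cumulative descendant abundance per branch for one community vector.

    The vector must be aligned with ``tree.leaf_names``.
    """
    sample = _as_vec(sample, "sample")
    if len(sample) != tree.n_leaves:
        raise ValueError(
            f"community vector length {len(sample)} != {tree.n_leaves} tree leaves"
        )
    cum = tree.descendants @ sample
    return BranchProfile(
        branch_lengths=tree.branch_lengths,
        abundances=cum,
        presence=cum > 0,
    )


def unweighted_unifrac(tree: PhyloTree, a, b, denominator: str = "all_branches") -> float:
    """Unweighted (presence-based) UniFrac between two communities."""
    if denominator not in ("all_branches", "union_branches"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    pa = branch_profile(tree, a).presence
    pb = branch_profile(tree, b).presence
    if not pa.any() and not pb.any():
        raise ValueError("both communities are empty; UniFrac undefined")
    bl = tree.branch_lengths
    num = float(bl[pa != pb].sum())
    if denominator == "all_branches":
        den = float(bl.sum())
    else:
        den = float(bl[pa | pb].sum())
    if den == 0:
        raise ValueError("total branch length is zero; UniFrac undefined")
    return num / den


def weighted_unifrac(tree: PhyloTree, a, b) -> float:
    """Normalized weighted (abundance-based) UniFrac between two communities."""
    prof_a = branch_profile(tree, a)
    prof_b = branch_profile(tree, b)
    aj, bj = prof_a.abundances, prof_b.abundances
    bl = tree.branch_lengths
    den = float(np.sum(bl * (aj + bj)))
    if den == 0:
        raise ValueError("both communities are empty; weighted UniFrac undefined")
    return float(np.sum(bl * np.abs(aj - bj)) / den)


def distance_matrix(
    table: AbundanceTable,
    metric: str,
    tree: PhyloTree | None = None,
    unifrac_denominator: str = "all_branches",
) -> DistanceMatrix:
    """All-pairs dissimilarity matrix for one metric over the table's samples.

    UniFrac metrics require ``tree``; its leaves must match the table's taxa
    exactly (align with :func:`microgp.io.align_tree_and_table` first).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    needs_tree = metric.endswith("unifrac")
    if needs_tree and tree is None:
        raise ValueError(f"metric {metric!r} requires a phylogenetic tree")

    values = table.values
    if needs_tree:
        if set(tree.leaf_names) != set(table.taxon_ids):
            raise ValueError("tree leaves and table taxa differ; align first")
        order = [table.taxon_ids.index(n) for n in tree.leaf_names]
        values = values[:, order]

    n = table.n_samples
    out = np.zeros((n, n))
    params: dict = {}
    if metric == "unweighted_unifrac":
        params["denominator"] = unifrac_denominator

    # branch profiles are shared across pairs; compute them once per sample
    if needs_tree:
        profiles = values @ tree.descendants.T.astype(float)  # n_samples x n_edges
        bl = tree.branch_lengths

    def pair(i: int, j: int) -> float:
        if metric == "jaccard":
            return jaccard(values[i], values[j])
        if metric == "bray_curtis":
            return bray_curtis(values[i], values[j])
        if metric == "unweighted_unifrac":
            pa, pb = profiles[i] > 0, profiles[j] > 0
            if not pa.any() and not pb.any():
                raise ValueError("both communities are empty; UniFrac undefined")
            num = float(bl[pa != pb].sum())
            den = float(bl.sum() if unifrac_denominator == "all_branches" else bl[pa | pb].sum())
            if den == 0:
                raise ValueError("total branch length is zero; UniFrac undefined")
            return num / den
        den = float(np.sum(bl * (profiles[i] + profiles[j])))
        if den == 0:
            raise ValueError("both communities are empty; weighted UniFrac undefined")
        return float(np.sum(bl * np.abs(profiles[i] - profiles[j])) / den)

    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = pair(i, j)
            except ValueError as exc:
                raise ValueError(
                    f"distance failed for pair ({table.sample_ids[i]!r}, "
                    f"{table.sample_ids[j]!r}): {exc}"
                ) from exc
            out[i, j] = out[j, i] = d
    return DistanceMatrix(
        sample_ids=list(table.sample_ids), values=out, metric=metric, metric_params=params
    )
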