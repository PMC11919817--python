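"""End-to-end plumbing shared by the CLI and the benchmark harness."""

from __future__ import annotations

from microgp.containers import AbundanceTable, DistanceMatrix
from microgp.dissimilarity import METRICS, distance_matrix
from microgp.io import align_tree_and_table, prevalence_filter, to_relative
from microgp.tree import PhyloTree

METRIC_ALIASES = {
    "jaccard": "jaccard",
    "braycurtis": "bray_curtis",
    "bray_curtis": "bray_curtis",
    "uunifrac": "unweighted_unifrac",
    "unweighted_unifrac": "unweighted_unifrac",
    "wunifrac": "weighted_unifrac",
    "weighted_unifrac": "weighted_unifrac",
}

DEFAULT_METRICS = list(METRICS)


def resolve_metric(name: str) -> str:
    try:
        return METRIC_ALIASES[name.lower()]
    except KeyError:
        raise ValueError(f"unknown metric {name!r}") from None


def prepare_distances(
    table: AbundanceTable,
    tree: PhyloTree | None,
    metrics: list[str],
    min_prevalence: float = 0.01,
    unifrac_denominator: str = "all_branches",
) -> tuple[dict[str, DistanceMatrix], AbundanceTable]:
    """Filter, normalize and compute one distance matrix per requested metric.

    Counts are prevalence-filtered, the tree (if any) is intersected with the
    surviving taxa, counts are converted to relative abundances, and all
    pairwise dissimilarities are computed once over the full sample set.
    """
    metrics = [resolve_metric(m) for m in metrics]
    if not table.is_relative:
        table = prevalence_filter(table, min_prevalence)
    needs_tree = any(m.endswith("unifrac") for m in metrics)
    if needs_tree:
        if tree is None:
            raise ValueError("UniFrac metrics require a phylogenetic tree")
        tree, table = align_tree_and_table(tree, table, mode="intersect")
    if not table.is_relative:
        table = to_relative(table)
    distances = {
        m: distance_matrix(
            table,
            m,
            tree=tree if m.endswith("unifrac") else None,
            unifrac_denominator=unifrac_denominator,
        )
        for m in metrics
    }
    return distances, table
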