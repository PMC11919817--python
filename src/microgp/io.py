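"""Reading, writing and preprocessing of tables, targets, trees and distances.

File dialects
-------------
* Abundance TSV: header ``sample_id\\t<taxon1>\\t<taxon2>...``, one row per sample.
* Target TSV: two columns ``sample_id\\tvalue``, header required.
* Tree: Newick with branch lengths, trailing semicolon.
* Distance TSV: square symmetric matrix with sample IDs on both axes, zero diagonal.

Preprocessing follows the standard amplicon workflow: taxa observed in fewer
than a given fraction of samples (1% by default) are removed, and counts are
converted to relative abundances by dividing each count by its sample total.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from microgp.containers import AbundanceTable, DistanceMatrix, TargetVector
from microgp.tree import PhyloTree


# --------------------------------------------------------------- abundance


def read_abundance_table(path) -> AbundanceTable:
    """Read a samples x taxa count table from TSV (counts preserved as parsed)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample ID: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate taxon ID: {dup!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in abundance table: {exc}") from exc
    return AbundanceTable(
        sample_ids=[str(s) for s in df.index],
        taxon_ids=[str(t) for t in df.columns],
        values=values,
        is_relative=False,
    )


def write_abundance_table(table: AbundanceTable, path) -> None:
    df = table.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each count by the total count per sample."""
    if table.is_relative:
        raise ValueError("table is already relative")
    sums = table.values.sum(axis=1)
    zero = np.where(sums <= 0)[0]
    if zero.size:
        raise ValueError(
            f"sample {table.sample_ids[zero[0]]!r} has zero total count; "
            "relative abundance undefined"
        )
    return AbundanceTable(
        sample_ids=list(table.sample_ids),
        taxon_ids=list(table.taxon_ids),
        values=table.values / sums[:, None],
        is_relative=True,
    )


def prevalence_filter(table: AbundanceTable, min_prevalence: float = 0.01) -> AbundanceTable:
    """Drop taxa present (value > 0) in strictly fewer than ``min_prevalence * n`` samples."""
    if not 0 <= min_prevalence <= 1:
        raise ValueError("min_prevalence must lie in [0, 1]")
    if table.n_samples < 1:
        raise ValueError("table has no samples")
    counts = (table.values > 0).sum(axis=0)
    keep = counts >= min_prevalence * table.n_samples
    if not keep.any():
        raise ValueError("prevalence filter removed every taxon")
    return AbundanceTable(
        sample_ids=list(table.sample_ids),
        taxon_ids=[t for t, k in zip(table.taxon_ids, keep) if k],
        values=table.values[:, keep],
        is_relative=table.is_relative,
    )


# ----------------------------------------------------------------- targets


def read_targets(path, units: str = "") -> TargetVector:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] != 2:
        raise ValueError("target TSV must have exactly two columns: sample_id, value")
    return TargetVector(
        sample_ids=[str(s) for s in df.iloc[:, 0]],
        y=df.iloc[:, 1].to_numpy(dtype=float),
        units=units,
    )


def write_targets(targets: TargetVector, path) -> None:
    pd.DataFrame({"sample_id": targets.sample_ids, "value": targets.y}).to_csv(
        path, sep="\t", index=False
    )


# -------------------------------------------------------------------- tree


def read_tree(path) -> PhyloTree:
    """Read a Newick tree; unrooted inputs are midpoint-rooted with a warning."""
    return PhyloTree.read(path)


def align_tree_and_table(
    tree: PhyloTree, table: AbundanceTable, mode: str = "intersect"
) -> tuple[PhyloTree, AbundanceTable]:
    """Reconcile tree leaves with table taxa.

    ``intersect`` prunes the tree to the shared taxa (summing lengths along
    collapsed paths, which conserves patristic distances) and drops unshared
    table columns; ``strict`` requires the two label sets to match exactly.
    """
    if mode not in ("intersect", "strict"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    leaves = set(tree.leaf_names)
    taxa = set(table.taxon_ids)
    shared = leaves & taxa
    if not shared:
        raise ValueError("tree leaves and table taxa have an empty intersection")
    if mode == "strict":
        if leaves != taxa:
            raise ValueError(
                f"strict alignment failed; tree-only: {sorted(leaves - taxa)}, "
                f"table-only: {sorted(taxa - leaves)}"
            )
        return tree, table
    kept = [t for t in table.taxon_ids if t in shared]
    new_table = table.select_taxa(kept)
    new_tree = tree if leaves == shared else tree.shear(kept)
    return new_tree, new_table


# ------------------------------------------------------------- distances


def read_distance_matrix(path, metric: str = "") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    ids = [str(s) for s in df.index]
    if ids != [str(s) for s in df.columns]:
        raise ValueError("distance matrix row and column IDs differ")
    return DistanceMatrix(sample_ids=ids, values=df.to_numpy(dtype=float), metric=metric)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.values, index=dm.sample_ids, columns=dm.sample_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ----------------------------------------------------------- predictions


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "mean", "sd"):
        if col not in df.columns:
            raise ValueError(f"predictions TSV missing column {col!r}")
    return df


def write_predictions(sample_ids, means, sds, path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "mean": means, "sd": sds}).to_csv(
        path, sep="\t", index=False
    )
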