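"""Synthetic phylogenies, sparse compositional count tables and GP targets.

The generator emulates the pathologies of 16S amplicon data — phylogenetic
correlation between taxa, high sparsity, compositionality — without modeling
any particular cohort:

* trees: random sequential-join rooted binary topologies with i.i.d.
  exponential(mean 1) branch lengths;
* abundances: per-sample log-normal taxon intensities whose correlation
  decays with patristic distance (exp(-patristic/tau), tau = tree height / 2),
  thinned to zero by independent Bernoulli draws, normalized, and converted
  to counts with a multinomial at fixed sequencing depth;
* targets: a function drawn from a GP whose covariance is the dissimilarity
  kernel sigma^2 exp(-d^2/(2 l^2)) on a supplied distance matrix, plus
  i.i.d. Gaussian observation noise.

All randomness flows from numpy SeedSequence spawning, so draws are
deterministic per seed and independent across the three generators.
"""

from __future__ import annotations

import numpy as np

from microgp.containers import AbundanceTable, DistanceMatrix, TargetVector
from microgp.kernels import distance_kernel, psd_repair
from microgp.tree import PhyloTree


def simulate_tree(n_taxa: int, seed: int = 0) -> PhyloTree:
    """Random rooted binary tree with exponential branch lengths, leaves t1..tn."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa for a tree")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    subtrees = [f"t{i + 1}" for i in range(n_taxa)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        bi, bj = rng.exponential(1.0, size=2)
        merged = f"({subtrees[i]}:{bi:.10g},{subtrees[j]}:{bj:.10g})"
        subtrees = (
            subtrees[:i] + subtrees[i + 1 : j] + subtrees[j + 1 :] + [merged]
        )
    return PhyloTree.from_newick(subtrees[0] + ";")


def simulate_abundance(
    n_samples: int,
    tree: PhyloTree,
    sparsity: float = 0.7,
    depth: int = 10_000,
    seed: int = 0,
) -> AbundanceTable:
    """Sparse compositional counts with phylogenetically correlated intensities.

    ``sparsity`` is the expected fraction of entries zeroed by thinning;
    ``depth`` is the (fixed) number of reads per sample. Samples that lose
    every taxon to thinning are redrawn, up to 100 attempts each.
    """
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must lie in [0, 1)")
    if depth < 100:
        raise ValueError("sequencing depth must be at least 100")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    leaf_names, pat = tree.patristic_distances()
    height = float(pat.max()) / 2.0  # max tip-tip path ~ 2x tree height
    tau = max(height / 2.0, 1e-12)
    corr = np.exp(-pat / tau)
    L = np.linalg.cholesky(psd_repair(corr, mode="jitter", tol=1e-10).matrix)

    n_taxa = len(leaf_names)
    counts = np.zeros((n_samples, n_taxa))
    for i in range(n_samples):
        for attempt in range(100):
            z = L @ rng.standard_normal(n_taxa)
            intensity = np.exp(z)
            keep = rng.random(n_taxa) >= sparsity
            intensity = intensity * keep
            if intensity.sum() > 0:
                break
        else:
            raise ValueError(
                f"sample {i} zeroed out after 100 resamples; sparsity too high"
            )
        p = intensity / intensity.sum()
        counts[i] = rng.multinomial(depth, p)
        if counts[i].sum() == 0:  # pragma: no cover - multinomial preserves depth
            counts[i, int(np.argmax(p))] = depth
    return AbundanceTable(
        sample_ids=[f"s{i + 1}" for i in range(n_samples)],
        taxon_ids=leaf_names,
        values=counts,
        is_relative=False,
    )


def simulate_targets(
    D: DistanceMatrix,
    length_scale: float,
    output_scale: float,
    noise_scale: float,
    seed: int = 0,
) -> tuple[TargetVector, dict]:
    """Draw y = f + eps with f ~ N(0, K) from the dissimilarity kernel on D.

    Returns the targets and a record of the generating truth, including the
    PSD-repair correction applied to the truth kernel.
    """
    for name, v in (("length_scale", length_scale), ("output_scale", output_scale),
                    ("noise_scale", noise_scale)):
        if v <= 0 or not np.isfinite(v):
            raise ValueError(f"{name} must be strictly positive and finite")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    K = distance_kernel(D.values, length_scale, output_scale)
    rep = psd_repair(K, mode="jitter", tol=1e-10)
    L = np.linalg.cholesky(rep.matrix)
    n = D.n_samples
    f = L @ rng.standard_normal(n)
    y = f + noise_scale * rng.standard_normal(n)
    truth = {
        "metric": D.metric,
        "length_scale": length_scale,
        "output_scale": output_scale,
        "noise_scale": noise_scale,
        "seed": seed,
        "psd_correction": rep.correction,
    }
    return TargetVector(sample_ids=list(D.sample_ids), y=y), truth
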