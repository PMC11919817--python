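"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: trees are parsed with
dendropy (the package uses scikit-bio), per-branch abundances are recomputed
by walking every root-to-leaf path, and GP posteriors use explicit dense
inverses and determinants (the package uses Cholesky solves only).
"""

from __future__ import annotations

import dendropy
import numpy as np


def unifrac_oracle(
    newick: str,
    abund_a: dict[str, float],
    abund_b: dict[str, float],
    weighted: bool = False,
    denominator: str = "all_branches",
) -> float:
    """UniFrac by explicit leaf-descendant enumeration on a dendropy tree."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True
    )
    # edge -> set of leaves whose root-to-leaf path uses it
    edge_leaves: dict[int, tuple[float, set]] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        node = leaf
        while node.parent_node is not None:
            length, leaves = edge_leaves.setdefault(
                id(node.edge), (float(node.edge.length), set())
            )
            leaves.add(label)
            node = node.parent_node

    num = 0.0
    union_len = 0.0
    total_len = 0.0
    wden = 0.0
    for length, leaves in edge_leaves.values():
        A = sum(abund_a.get(l, 0.0) for l in leaves)
        B = sum(abund_b.get(l, 0.0) for l in leaves)
        total_len += length
        if weighted:
            num += length * abs(A - B)
            wden += length * (A + B)
        else:
            ia, ib = int(A > 0), int(B > 0)
            num += length * abs(ia - ib)
            if ia or ib:
                union_len += length
    if weighted:
        return num / wden
    den = total_len if denominator == "all_branches" else union_len
    return num / den


def gp_posterior_oracle(
    K: np.ndarray,
    y: np.ndarray,
    noise_variance: float,
    K_cross: np.ndarray,
    k_diag: np.ndarray,
):
    """Posterior mean/variance and log marginal likelihood via dense inverses."""
    n = len(y)
    K_y = K + noise_variance * np.eye(n)
    K_inv = np.linalg.inv(K_y)
    mu = K_cross @ K_inv @ y
    var = k_diag + noise_variance - np.einsum("ij,jk,ik->i", K_cross, K_inv, K_cross)
    sign, logdet = np.linalg.slogdet(K_y)
    assert sign > 0
    lml = -0.5 * y @ K_inv @ y - 0.5 * logdet - 0.5 * n * np.log(2 * np.pi)
    return mu, var, float(lml)
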