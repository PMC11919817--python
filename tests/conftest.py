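import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from microgp import pipeline, simulate as sim
from microgp.containers import AbundanceTable
from microgp.tree import PhyloTree

WORKED_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def worked_tree() -> PhyloTree:
    """The 3-leaf tree whose UniFrac values are worked out by hand in the tests."""
    return PhyloTree.from_newick(WORKED_NEWICK)


@pytest.fixture
def toy_table() -> AbundanceTable:
    return AbundanceTable(
        sample_ids=["s1", "s2", "s3"],
        taxon_ids=["A", "B", "C"],
        values=np.array([[5.0, 0.0, 1.0], [1.0, 4.0, 0.0], [0.0, 2.0, 2.0]]),
    )


@pytest.fixture(scope="session")
def synthetic_dataset():
    """One moderate synthetic dataset shared by GP-level tests (n=60)."""
    tree = sim.simulate_tree(40, seed=11)
    table = sim.simulate_abundance(60, tree, sparsity=0.6, depth=5000, seed=11)
    dms, rel = pipeline.prepare_distances(
        table, tree, ["jaccard", "bray_curtis", "unweighted_unifrac", "weighted_unifrac"],
        min_prevalence=0.01,
    )
    return {"tree": tree, "table": table, "relative": rel, "distances": dms}
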