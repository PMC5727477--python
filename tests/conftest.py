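import numpy as np
import pandas as pd
import pytest

import assemblage as A

FOUR_TIP_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def four_tip_tree() -> A.PhyloTree:
    return A.PhyloTree.from_newick(FOUR_TIP_NEWICK)


@pytest.fixture
def four_tip_dmat(four_tip_tree) -> pd.DataFrame:
    return A.patristic_distances(four_tip_tree)


def community(rows: dict, taxa) -> pd.DataFrame:
    """Small helper: build a samples × taxa frame from {sample: vector}."""
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(taxa)).astype(float)


@pytest.fixture
def small_neutral_dataset():
    """32-tip tree with 6 neutral communities; taxa aligned to tips."""
    tree = A.simulate_tree(32, rng_seed=5)
    traits = A.evolve_trait(tree, rng_seed=6)
    cfg = A.SimulationConfig(n_tips=32, scenario="neutral", n_samples=6,
                             n_individuals=300, rng_seed=7)
    cm, md, truth = A.assemble_communities(tree, traits, cfg)
    return tree, cm, md


def random_instance(rng, n_taxa=None, n_samples=None):
    """A random tree + community pair for oracle comparisons."""
    n_taxa = n_taxa or int(rng.integers(4, 21))
    n_samples = n_samples or int(rng.integers(2, 9))
    tree = A.simulate_tree(n_taxa, rng_seed=int(rng.integers(2**31)))
    X = rng.integers(0, 20, size=(n_samples, n_taxa)).astype(float)
    for s in range(n_samples):  # every sample non-empty
        if X[s].sum() == 0:
            X[s, rng.integers(n_taxa)] = 1
    cm = pd.DataFrame(X, index=[f"S{i}" for i in range(n_samples)],
                      columns=tree.tip_labels)
    return tree, cm
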