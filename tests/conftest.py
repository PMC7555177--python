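import numpy as np
import pandas as pd
import pytest

from cohortpath import synthetic
from cohortpath.expression_io import ExpressionDataset


@pytest.fixture
def small_dataset():
    """A tiny hand-checkable log2 dataset: 4 genes, 2v2 plus one carrier."""
    values = pd.DataFrame(
        {
            "A1": [2.0, 5.0, 1.0, 8.0],
            "A2": [2.0, 5.5, 1.5, 8.0],
            "C1": [1.0, 5.0, 3.0, 8.0],
            "C2": [1.0, 4.5, 2.5, 8.0],
            "K1": [9.0, 9.0, 9.0, 9.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    groups = {"A1": "affected", "A2": "affected", "C1": "control",
              "C2": "control", "K1": "carrier"}
    return ExpressionDataset(values=values, groups=groups, is_log2=True, name="tiny")


@pytest.fixture(scope="session")
def standard_cohort():
    """The standard perturbed cohort: effect +1.0 on 50 genes, sd 0.5, 10v10."""
    universe = synthetic.gene_universe(1000)
    members = universe[:50]
    spec = synthetic.CohortSpec(
        n_datasets=3, n_genes=1000, n_affected=10, n_control=10,
        perturbed_sets={"PWUP": 1.0}, set_members={"PWUP": members},
        noise_sd=0.5, seed=11,
    )
    datasets, truth = synthetic.generate_cohort(spec)
    return spec, datasets, truth


@pytest.fixture(scope="session")
def pathway_world():
    """An overlap-rich 60-pathway collection and its shared-gene network."""
    universe = synthetic.gene_universe(1500)
    coll = synthetic.generate_pathways(
        60, (15, 30), universe, overlap_fraction=0.15, seed=3
    )
    net = synthetic.generate_pathway_network(coll, min_shared=1, seed=3)
    return coll, net
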