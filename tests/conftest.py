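import numpy as np
import pandas as pd
import pytest

from metcouple import synthetic
from metcouple.network import load_network


@pytest.fixture()
def toy_network():
    """Three reactions, hand-written: covers multi-gene reactions, shared
    metabolites across reactions and a non-cytosolic metabolite."""
    table = pd.DataFrame([
        {"reaction_id": "R1", "genes": "g1;g2", "substrates": "a[c]",
         "products": "b[c]", "reversible": 1, "delta_g0": "-12.5",
         "pathway": "glycolysis"},
        {"reaction_id": "R2", "genes": "g2", "substrates": "b[c];c[c]",
         "products": "d[e]", "reversible": 0, "delta_g0": "3.0",
         "pathway": "transport"},
        {"reaction_id": "R3", "genes": "g3", "substrates": "a[c]",
         "products": "c[c]", "reversible": 0, "delta_g0": "7.25",
         "pathway": "glycolysis"},
    ])
    return load_network(table)


@pytest.fixture(scope="session")
def medium_network():
    return synthetic.generate_network(50, 40, 30, 5, seed=7)


@pytest.fixture(scope="session")
def medium_cohort(medium_network):
    """Small two-condition cohort with cancer-only couplings; shared by
    tests that only read it."""
    return synthetic.generate_omics(
        medium_network, n_samples_per_condition=30,
        coupling_fraction_by_condition={"noncancerous": 0.0, "cancer": 0.4},
        strength_range=(0.7, 0.7), seed=13)


def stratum_matrices(cohort, stratum):
    cols = cohort.samples[cohort.sample_mask(stratum)]
    return cohort.expression[cols], cohort.metabolites[cols]
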