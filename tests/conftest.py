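import numpy as np
import pytest

import tosgkit as tk


@pytest.fixture(scope="session")
def tiny_spec():
    """Smallest nondegenerate world: 12 transcripts onto 6 proteins."""
    return tk.SyntheticSpec(
        n_transcripts=12,
        n_proteins=6,
        n_samples=20,
        n_communities=2,
        intra_edge_prob=0.8,
        inter_edge_prob=0.1,
        n_donors=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_spec):
    catalog = tk.make_catalog(tiny_spec)
    topo = tk.make_ppi(tiny_spec, catalog)
    cohort = tk.make_cohort(tiny_spec, topo, catalog)
    return tiny_spec, catalog, topo, cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
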