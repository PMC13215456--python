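import numpy as np
import pytest

from ptmls import synthetic as syn


# planted 10-gene GRN: hub gene 2 regulates 0,1,3,4,5; two isolated pairs
HUB = 2
HUB_TARGETS = (0, 1, 3, 4, 5)
SEM_EDGES = [(HUB, j, 0.6 if j % 2 else -0.6) for j in HUB_TARGETS] + \
    [(6, 7, 0.5), (8, 9, -0.5)]


@pytest.fixture(scope="session")
def slide():
    return syn.make_slide(512, 512, n_nuclei=20, tissue_coverage=0.7, seed=11)


@pytest.fixture(scope="session")
def cohort():
    return syn.make_cohort(n=400, k=4, beta_true=[1.1, 0, 0, 0],
                           noise_sd=0.2, censor_rate=0.3, seed=5)


@pytest.fixture(scope="session")
def sc_data():
    return syn.make_sc(n_genes=10, n_cells=500, grn_spec=SEM_EDGES, seed=3,
                       n_mito_genes=0)
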