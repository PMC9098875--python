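import warnings

import numpy as np
import pytest

import condenseq as cq

warnings.filterwarnings("ignore", category=UserWarning, module="anndata")


@pytest.fixture(scope="session")
def small_pool():
    """A 300-transcript pool with 10% planted motif pairs (seeded)."""
    return cq.generate_pool(n_transcripts=300, frac_enriched=0.1, seed=7)


@pytest.fixture(scope="session")
def small_matrix(small_pool):
    """96 simulated condensates from the small pool, TPM attached."""
    adata = cq.simulate_condensates(small_pool, n_condensates=96, seed=7)
    adata = cq.add_tpm(adata)
    adata, _ = cq.filter_matrix(adata)
    return adata


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
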