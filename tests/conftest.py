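import logging

import numpy as np
import pytest

from cmtarget.connectivity import RankedQuery
from cmtarget.fileio import build_signature_library
from cmtarget.simulate import (
    SimulationConfig,
    generate_query,
    generate_signature_library,
)

# coverage/zero-direction warnings are expected noise in randomized suites
logging.getLogger("cmtarget").setLevel(logging.ERROR)


@pytest.fixture
def toy_query() -> RankedQuery:
    """Ten genes ranked g01 (highest metric) .. g10 (lowest)."""
    genes = [f"g{i:02d}" for i in range(1, 11)]
    return RankedQuery("toy", genes, np.arange(10, 0, -1, dtype=float))


@pytest.fixture(scope="session")
def small_library():
    """5-target planted library (400 genes, 3 replicates) plus its truth."""
    config = SimulationConfig(
        n_genes=400, n_targets=5, replicates_per_target=3, signature_size=10,
        seed=7,
    )
    signatures, truth = generate_signature_library(config)
    library, profiles = build_signature_library(signatures, config.signature_size)
    return config, signatures, truth, library, profiles


@pytest.fixture(scope="session")
def small_scored(small_library):
    """The small library scored for a query activating T1 (+) and T2 (−)."""
    from cmtarget.connectivity import score_query

    config, _signatures, truth, library, _profiles = small_library
    query = generate_query(
        truth, [("T1", +1), ("T2", -1)], seed=3, label="drug"
    )
    results = score_query(query, library, n_perm=300, seed=5)
    return truth, query, results
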