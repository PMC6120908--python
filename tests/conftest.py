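import numpy as np
import pandas as pd
import pytest

import episnp as e


@pytest.fixture(scope="session")
def toy():
    """Session-wide toy dataset: 400 samples, 300 SNPs, planted signals."""
    return e.make_toy_fixture(seed=7)


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(5)
    dosage = rng.integers(0, 3, size=(12, 8), dtype=np.int8)
    sample_ids = tuple(f"s{i}" for i in range(12))
    snp_ids = tuple(f"rs{i}" for i in range(8))
    return e.GenotypeMatrix(sample_ids, snp_ids, dosage)


@pytest.fixture()
def small_pheno(small_matrix):
    status = [1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0]
    return e.PhenotypeTable(
        pd.DataFrame(
            {
                "sample_id": list(small_matrix.sample_ids),
                "status": status,
                "er_status": ["positive" if s else "unknown" for s in status],
                "cohort": "A",
            }
        )
    )
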