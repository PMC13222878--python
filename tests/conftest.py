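import numpy as np
import pandas as pd
import pytest

from rhizonet.datatypes import AbundanceTable


def make_table(counts, sample_ids=None, taxa=None, site="non_urban",
               compartment="rhizosphere", treatment="untreated",
               taxonomy=None) -> AbundanceTable:
    """Small helper: wrap a raw count matrix into a valid AbundanceTable."""
    counts = np.asarray(counts)
    n, k = counts.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    taxa = taxa or [f"t{j}" for j in range(k)]
    metadata = pd.DataFrame(
        {
            "site": site,
            "compartment": compartment,
            "treatment": treatment,
            "rhizobox_id": [f"box_{i}" for i in range(n)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return AbundanceTable(
        counts=pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"),
                            columns=taxa),
        metadata=metadata,
        taxonomy=taxonomy,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    return make_table(rng.integers(0, 50, size=(8, 6)))
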