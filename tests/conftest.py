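import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from vgwas import MISSING, GenotypeMatrix, PhenotypeTable, groups_from_calls  # noqa: E402


@pytest.fixture
def toy_groups():
    """Two balanced genotype classes of three lines each."""
    return groups_from_calls([0, 0, 0, 2, 2, 2])


@pytest.fixture
def small_genotypes():
    """2 markers x 3 accessions, one missing call."""
    return GenotypeMatrix(
        marker_ids=["m1", "m2"],
        chrom=["1", "2"],
        pos=[100, 250],
        allele_a=["A", "C"],
        allele_b=["G", "T"],
        calls=np.array([[0, 2, 2], [2, 0, MISSING]], dtype=np.int8),
        accession_ids=["acc1", "acc2", "acc3"],
    )


@pytest.fixture
def small_phenotypes():
    frame = pd.DataFrame(
        {"flowering": [1.0, 2.0, np.nan], "height": [10.0, 12.0, 9.0]},
        index=pd.Index(["acc1", "acc2", "acc3"], name="accession_id"),
    )
    return PhenotypeTable(frame)


@pytest.fixture(scope="session")
def example_data():
    from vgwas.datasets import load_example

    return load_example()
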