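import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, database=None)
settings.load_profile("ci")

from seedtrace.genotype_io import GenotypeMatrix, MISSING


def make_matrix(
    dosages,
    positions=None,
    scaffolds=None,
    annotations=None,
    genotype_depth=None,
    individual_ids=None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain dosage array for tests."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, j = dosages.shape
    if positions is None:
        positions = np.arange(1, j + 1) * 100
    if scaffolds is None:
        scaffolds = np.asarray(["chr1"] * j, dtype=object)
    else:
        scaffolds = np.asarray(scaffolds, dtype=object)
    return GenotypeMatrix(
        dosages=dosages,
        individual_ids=individual_ids or [f"s{i}" for i in range(n)],
        scaffolds=scaffolds,
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.full(j, "A", dtype=object),
        alt=np.full(j, "T", dtype=object),
        site_annotations=annotations or {},
        genotype_depth=genotype_depth,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    return make_matrix([[0, 1, 2], [1, MISSING, 2]])
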