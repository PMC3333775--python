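import numpy as np
import pandas as pd
import pytest

from omicsets.datamodel import (
    GenomicMatrix,
    PhenotypeVector,
    build_study,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_matrix(platform_id, genes, samples, rng, missing=()):
    vals = rng.standard_normal((len(genes), len(samples)))
    m = GenomicMatrix.from_arrays(platform_id, genes, samples, vals)
    for g in missing:
        m.values.loc[g, m.sample_ids[0]] = np.nan
    return m


@pytest.fixture
def toy_study(rng):
    """Two platforms, 30 genes each with partial overlap, 40 samples."""
    samples = [f"s{i}" for i in range(40)]
    genes_a = [f"g{i:03d}" for i in range(0, 30)]
    genes_b = [f"g{i:03d}" for i in range(10, 40)]
    m1 = make_matrix("E1", genes_a, samples, rng)
    m2 = make_matrix("C1", genes_b, samples, rng)
    labels = pd.Series(([0, 1] * 20), index=pd.Index(samples))
    return build_study([m1, m2], PhenotypeVector.binary(labels))


@pytest.fixture
def binary_labels(rng):
    y = np.zeros(60, dtype=np.int8)
    y[:30] = 1
    rng.shuffle(y)
    return y
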