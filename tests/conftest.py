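import numpy as np
import pytest

from milletmarkers import GenotypeMatrix


@pytest.fixture
def small_matrix() -> GenotypeMatrix:
    """Six samples x three loci with one missing call and two groups."""
    calls = [
        [("A", "A"), ("C", "C"), ("G", "T")],
        [("A", "A"), ("C", "C"), ("G", "G")],
        [("A", "G"), ("C", "C"), ("T", "T")],
        [("G", "G"), ("C", "C"), ("G", "T")],
        [("G", "G"), ("C", "C"), None],
        [("A", "G"), ("C", "C"), ("G", "G")],
    ]
    sample_ids = [f"s{i}" for i in range(1, 7)]
    groups = {s: ("wild" if i < 3 else "cultivated")
              for i, s in enumerate(sample_ids)}
    return GenotypeMatrix(sample_ids=sample_ids, locus_ids=["L1", "L2", "L3"],
                          calls=calls, groups=groups)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20161607)
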