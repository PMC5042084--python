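import numpy as np
import pytest

from metacontact.msa_io import Alignment
from metacontact.weighting import WeightedAlignment


def make_alignment(rows, ids=None):
    return Alignment(ids=ids or [f"s{k}" for k in range(len(rows))], rows=list(rows))


@pytest.fixture
def toy_alignment():
    return make_alignment(["ACDE", "ACDE", "ACKE", "GCDE"])


@pytest.fixture
def correlated_two_column():
    """Two perfectly correlated binary columns: joint {AA: 1/2, CC: 1/2}."""
    return make_alignment(["AA", "AA", "CC", "CC"])


def uniform_weighted(alignment):
    """Weight every sequence 1 with neff = N (no redundancy collapsing)."""
    return WeightedAlignment(
        alignment=alignment,
        weights=np.ones(alignment.N),
        neff=alignment.N,
    )
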