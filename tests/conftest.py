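import numpy as np
import pytest

from fieldcomp import (HarmonicIndexing, KCoefficients, PhaseData, ProbeArray,
                       evaluate_basis)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def probe_cloud(rng):
    """40 random probe positions within a 14-cm box."""
    return ProbeArray(rng.uniform(-0.14, 0.14, size=(40, 3)))


@pytest.fixture
def order3_system(rng, probe_cloud):
    """Overdetermined 3rd-order system: probing matrix + random k truth."""
    P = evaluate_basis(probe_cloud, 3)
    t = np.arange(60) * 1e-5
    k = KCoefficients(k=rng.normal(size=(16, 60)), indexing=P.indexing, time=t)
    return P, k


def make_k(max_order, n_t, rng, segment_labels=None):
    indexing = HarmonicIndexing(max_order)
    return KCoefficients(k=rng.normal(size=(indexing.count, n_t)),
                         indexing=indexing, time=np.arange(n_t) * 1e-5,
                         segment_labels=segment_labels)
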