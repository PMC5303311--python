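import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture(scope="session")
def small_truth():
    """p=30 scale-free truth shared by cheap unit tests."""
    from dwglasso import build_precision_matrix, generate_scale_free_graph

    adj = generate_scale_free_graph(30, seed=11)
    return build_precision_matrix(adj)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_spd(rng, p, jitter=0.5):
    """Random well-conditioned correlation-like SPD matrix."""
    A = rng.normal(size=(p, p))
    S = A @ A.T / p + jitter * np.eye(p)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)
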