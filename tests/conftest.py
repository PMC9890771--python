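import numpy as np
import pytest

from ppddp.model import DDPInstance
from ppddp.ophi import NoiseBudget, encrypt_instance, keygen


@pytest.fixture
def toy_instance() -> DDPInstance:
    """Smallest interesting instance: p = q = 2, unique solution pair."""
    return DDPInstance(A=[1, 4], B=[2, 3], C=[1, 1, 3])


@pytest.fixture
def toy_encrypted(toy_instance):
    rng = np.random.default_rng(42)
    key = keygen(3, rng=rng)
    return key, encrypt_instance(key, toy_instance, rng=rng)


@pytest.fixture
def forced_key():
    """The small hand-checkable key used in exact-arithmetic tests."""
    from ppddp.ophi import KeyVector

    # R_bound chosen large enough to admit the hand-picked noise vectors
    return KeyVector(k=(2.0, 3.0, 5.0)), NoiseBudget(p_min=1.0, L_max=2, R_bound=1.0)
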