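import numpy as np
import pytest


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2^31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


@pytest.fixture
def seeds50():
    return spawn_seeds(0, 50)
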