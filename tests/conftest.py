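import numpy as np
import pytest

from endstate import ChainSelection, EnsembleSpec, gen_multimer_ensemble, gen_toy_multimer


@pytest.fixture(scope="session")
def toy_multimer():
    """Static 4-chain toy assembly with topology and manifest."""
    return gen_toy_multimer(EnsembleSpec(n_frames=1, seed=2))


@pytest.fixture(scope="session")
def multimer_ensemble():
    """Small jittered ensemble of the toy tetramer (4 frames)."""
    return gen_multimer_ensemble(EnsembleSpec(n_frames=4, seed=2))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def sel_dimers():
    return [ChainSelection(["A", "B"]), ChainSelection(["C", "D"])]
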