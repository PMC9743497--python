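import numpy as np
import pytest

from cagetss.synthetic import SimulationConfig, simulate

BASES = "ACGT"


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """A small synthetic fixture shared by I/O and pipeline tests."""
    out = tmp_path_factory.mktemp("fixture") / "small"
    config = SimulationConfig(seed=5, n_true_tss=30, n_noise_clusters=30)
    truth = simulate(config, str(out))
    return str(out), config, truth
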