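import numpy as np
import pytest

from protonflux import PAPER_CONDITIONS, SHStackSpec, gen_sh_stack


@pytest.fixture(scope="session")
def paper_conditions():
    """Bath conditions of the acidification experiment (pH 4.1/7.3, Cl 61/50 mM)."""
    return PAPER_CONDITIONS


@pytest.fixture(scope="session")
def small_spec():
    """A small, fast synthetic acquisition used by imaging/pipeline tests."""
    return SHStackSpec(seed=3, field_size=22.5, n_frames=240, frame_period=30.0,
                      birth_rate=25.0)


@pytest.fixture(scope="session")
def small_stack(small_spec):
    """(stack, ground truth) for the small spec; generated once per session."""
    return gen_sh_stack(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
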