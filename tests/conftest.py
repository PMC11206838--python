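import numpy as np
import pytest

from balancefb import model as mdl
from balancefb import synthetic as syn
from balancefb.preprocess import ComKinematics


@pytest.fixture(scope="session")
def level2():
    """Default level-2 kinematics: (t, ComKinematics, ankle_change)."""
    return syn.level_kinematics(2)


@pytest.fixture(scope="session")
def td_gains():
    return syn.archetype_gains("TD_like")


@pytest.fixture(scope="session")
def cp_gains():
    return syn.archetype_gains("CP_like")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def model_config():
    return mdl.ModelConfig()


def make_com(t, d, v, a, a_init=None):
    """Hand-built ComKinematics (no internal-consistency requirements)."""
    z = np.zeros_like(t)
    return ComKinematics(
        t=t,
        d=np.asarray(d, float),
        v=np.asarray(v, float),
        a=np.asarray(a, float),
        a_init=z if a_init is None else np.asarray(a_init, float),
    )
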