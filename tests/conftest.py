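import numpy as np
import pytest

from tscmdyn import (
    BodyWaterParams,
    ExplicitModelParams,
    ImplicitModelParams,
    TelomereParams,
)
from tscmdyn.synth import StudyDesign, default_truth


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture
def water():
    return BodyWaterParams(f_r=0.02, delta_w=0.06, beta_s=0.001, tau=49.0)


@pytest.fixture
def implicit_params():
    """Study-like one-pool kinetics: ~2%/day bulk replacement, k=5."""
    return ImplicitModelParams(p_n=5e-4, p_s=0.01, Delta=0.01 / 32, k=5, c=4.0, ds_star=0.03)


@pytest.fixture
def homogeneous_params():
    return ImplicitModelParams(p_n=5e-4, p_s=0.01, Delta=0.01 / 32, k=5, c=4.0)


@pytest.fixture
def explicit_params(truth):
    return truth.kinetics


def random_implicit(rng, k=None) -> ImplicitModelParams:
    """Random one-pool parameter draw in the physiological range."""
    return ImplicitModelParams(
        p_n=10 ** rng.uniform(-4, -2.5),
        p_s=10 ** rng.uniform(-3, -1.5),
        Delta=10 ** rng.uniform(-5, -3),
        k=int(rng.integers(0, 11)),
        c=rng.uniform(1.0, 5.0),
        ds_star=10 ** rng.uniform(-2.5, -1),
    )


def random_explicit(rng, k=None) -> ExplicitModelParams:
    k = int(rng.integers(0, 11)) if k is None else k
    p_s1 = 10 ** rng.uniform(-2.2, -1.6)
    p_s2 = 10 ** rng.uniform(-3.0, -2.4)
    return ExplicitModelParams(
        p_n=10 ** rng.uniform(-4, -3),
        p_s1=p_s1,
        d_s1=p_s1 + 10 ** rng.uniform(-2.6, -2.0),
        p_s2=p_s2,
        d_s2=p_s2 + 10 ** rng.uniform(-3.8, -3.2),
        f=rng.uniform(0.02, 0.3),
        Delta=1e-5,
        k=k,
        c=rng.uniform(1.0, 5.0),
    )


@pytest.fixture
def telo():
    return TelomereParams(delta_bp=50.0, C=2.0)


@pytest.fixture
def label_times():
    return np.array([7, 14, 21, 28, 35, 42, 49, 63, 91, 140, 210, 280], dtype=float)
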