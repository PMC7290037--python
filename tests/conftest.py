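import numpy as np
import pytest

from nvctf import (
    SimConfig,
    TFParams,
    UniformSeries,
    cut_trial,
    make_trial,
)

STANDARD = TFParams(1.3, 0.5, 0.27, 0.19)


@pytest.fixture(scope="session")
def standard_params() -> TFParams:
    """The fitted capillary-pathway kernel used as a worked reference."""
    return STANDARD


@pytest.fixture(scope="session")
def noiseless_trial():
    """A window-cut noiseless trial generated from the standard kernel."""
    return cut_trial(make_trial(SimConfig(), seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240117)


def random_valid_params(rng: np.random.Generator) -> TFParams:
    """A random admissible kernel (p1 > 1) inside the default bounds."""
    return TFParams(
        p1=rng.uniform(1.1, 8.0),
        p2=rng.uniform(0.1, 5.0),
        p3=rng.uniform(0.0, 2.0),
        p4=rng.uniform(0.05, 5.0),
    )


def series(values, t0=0.0, dt=1.0) -> UniformSeries:
    return UniformSeries(t0, dt, np.asarray(values, dtype=float))
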