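import numpy as np
import pytest

from lipocharge import (
    BindingConstants,
    Electrolyte,
    Medium,
    Membrane,
    SyntheticSpec,
    generate_titration,
    reference_constants,
)

SALTS = ["NaCl", "NaBr", "NaNO3", "NaI"]


@pytest.fixture(scope="session")
def medium():
    return Medium()


@pytest.fixture(scope="session")
def membrane():
    return Membrane()


@pytest.fixture(scope="session")
def constants_table():
    """Published association constants for the four study salts (SI units)."""
    return reference_constants()


@pytest.fixture(scope="session")
def nacl():
    return Electrolyte(salt="NaCl", concentration=155.0)


def noiseless_curve(salt, pH_grid=None, **kwargs):
    spec = SyntheticSpec.for_salt(salt, noise_sd=0.0, **kwargs)
    if pH_grid is not None:
        spec.pH_grid = np.asarray(pH_grid, dtype=float)
    return generate_titration(spec)


def random_constants(rng):
    """Constants drawn log-uniformly around the magnitudes seen on PC
    membranes, restricted to the strong protolytic-association regime
    (K_AH K_BOH K_W > (1+K_BX a_X)(1+K_ANa a_Na) at 155 mol m^-3)."""
    while True:
        k = BindingConstants(
            K_AH=10 ** rng.uniform(1.0, 3.5),
            K_ANa=10 ** rng.uniform(-1.5, 0.0),
            K_BOH=10 ** rng.uniform(8.5, 10.5),
            K_BX=10 ** rng.uniform(-1.5, 0.0),
        )
        uv = k.K_AH * k.K_BOH * 1e-8
        if uv > 2.0 * (1 + k.K_BX * 155.0) * (1 + k.K_ANa * 155.0):
            return k
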