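import numpy as np
import pytest

from solufus import (
    BinaryInteraction,
    ComponentParameters,
    ParameterSet,
    SigmaModel,
    load_default_melting,
    load_default_parameters,
)


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    """The shipped aqueous glycine / l-alanine parameter set."""
    return load_default_parameters()


@pytest.fixture(scope="session")
def melting():
    """Shipped calorimetric melting properties."""
    return load_default_melting()


@pytest.fixture(scope="session")
def sphere_params() -> ParameterSet:
    """A single non-associating one-segment component (hard-sphere oracle)."""
    return ParameterSet(
        (
            ComponentParameters(
                id="sphere", molar_mass=40.0, m_seg=1.0, sigma=SigmaModel(3.0), u_k=150.0
            ),
        )
    )


@pytest.fixture(scope="session")
def chain_params() -> ParameterSet:
    """A non-associating chain fluid plus a light gas, kij = 0."""
    return ParameterSet(
        (
            ComponentParameters(
                id="chain", molar_mass=86.0, m_seg=3.06, sigma=SigmaModel(3.80), u_k=236.8
            ),
            ComponentParameters(
                id="gas", molar_mass=16.0, m_seg=1.0, sigma=SigmaModel(3.70), u_k=150.0
            ),
        )
    )


@pytest.fixture(scope="session")
def assoc_params() -> ParameterSet:
    """Two distinct 2B associating components (alcohol-like and water-like)."""
    return ParameterSet(
        (
            ComponentParameters(
                id="alcohol",
                molar_mass=32.0,
                m_seg=1.5255,
                sigma=SigmaModel(3.23),
                u_k=188.9,
                eps_assoc_k=2899.5,
                kappa_assoc=0.035176,
                n_sites="2B",
            ),
            ComponentParameters(
                id="aqua",
                molar_mass=18.015,
                m_seg=1.2047,
                sigma=SigmaModel(2.7927),
                u_k=353.94,
                eps_assoc_k=2425.67,
                kappa_assoc=0.0451,
                n_sites="2B",
            ),
        ),
        (BinaryInteraction(("alcohol", "aqua"), -0.02),),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
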