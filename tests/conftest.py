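import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from carbonfba import (
    Compartment,
    Metabolite,
    PhototrophParams,
    Reaction,
    StoichiometricNetwork,
    make_toy_phototroph,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def chain_network():
    """Linear pathway: R1 imports A, R2 converts A->B, R3 secretes B."""
    mets = [
        Metabolite("A", compartment=Compartment.CYTOSOL),
        Metabolite("B", compartment=Compartment.CYTOSOL),
    ]
    rxns = [
        Reaction("R1", {"A": 1.0}),
        Reaction("R2", {"A": -1.0, "B": 1.0}),
        Reaction("R3", {"B": -1.0}),
    ]
    return StoichiometricNetwork(mets, rxns, name="chain")


@pytest.fixture
def toy_phototroph():
    return make_toy_phototroph(PhototrophParams())


def sample_phototroph_params(rng: np.random.Generator) -> PhototrophParams:
    """Random but well-posed toy parameters: maintenance below the energy
    supply, carbon cap never binding."""
    y_E = rng.uniform(0.05, 0.5)
    v_light = rng.uniform(50.0, 1000.0)
    return PhototrophParams(
        n_N=rng.uniform(1.0, 10.0),
        n_C=rng.uniform(5.0, 50.0),
        n_E=rng.uniform(20.0, 200.0),
        y_E=y_E,
        m_ATP=rng.uniform(0.1, 0.9 * y_E * v_light),
        k_car=rng.uniform(10.0, 100.0),
        k_car_c=rng.uniform(5.0, 50.0),
        v_light_max=v_light,
        v_N_max=rng.uniform(0.001, 0.5),
    )
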