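import numpy as np
import pytest
from hypothesis import settings

from denitkin import KineticParams, OrganicsPool, SystemState

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture
def default_params() -> KineticParams:
    return KineticParams()


@pytest.fixture
def insitu_state() -> SystemState:
    """Flow-cell composition at the first post-injection sample."""
    return SystemState(
        t=0.0,
        pools=(OrganicsPool("plasticizer", 0.190), OrganicsPool("biomass_derived", 0.0)),
        sNO3=0.125,
        xB=1.22e-3,
    )


def random_scenario(rng: np.random.Generator) -> tuple[SystemState, KineticParams]:
    """A random valid scenario: pools, state and parameters in sane ranges."""
    labels = ["plasticizer", "biomass_derived"]
    if rng.random() < 0.5:
        labels.append("glucose")
    if rng.random() < 0.5:
        labels.append("humic")
    k3 = {lab: float(rng.uniform(0.001, 0.5)) for lab in labels}
    p = KineticParams(
        k3_per_pool=k3,
        bH=float(rng.uniform(0.0, 0.02)),
        KsS_per_pool={lab: float(rng.uniform(0.005, 0.05)) for lab in labels},
        KsNO3=float(rng.uniform(0.0005, 0.005)),
        x_yield=float(rng.uniform(0.3, 1.0)),
        z_nc=float(rng.uniform(0.5, 2.0)),
        f_recycle=float(rng.uniform(0.0, 1.0)),
    )
    pools = tuple(OrganicsPool(lab, float(rng.uniform(0.0, 0.5))) for lab in labels)
    state = SystemState(
        t=0.0,
        pools=pools,
        sNO3=float(rng.uniform(0.01, 0.5)),
        xB=float(rng.uniform(1e-4, 0.1)),
    )
    return state, p
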