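import numpy as np
import pytest

from microshift import (
    FeedingPhase,
    FeedingSchedule,
    ReactorState,
    Scenario,
    StrainParameters,
    load_preset,
)

#: strain constants of the E. coli W3110 column, used across the suite
W3110_KW = dict(
    vG=0.82, kG=0.005, etaG=0.69, vRP=0.09, kRP=0.02, etaRP=0.76,
    vF=0.46, kF=0.08, etaFA=0.12, etaFP=0.94, vRA=0.25, kRA=0.86,
    etaRA=0.94, vA=0.2, kA=0.05, etaA=0.93, r_max=0.3, delta=0.1,
    tau=0.6, rho=0.003, sigma_I=1.0, sigma_A=2.71, c=0.01,
    a1=3.0e-4, b1=35.5, a2=0.051, b2=4.9,
)


@pytest.fixture(scope="session")
def w3110_params() -> StrainParameters:
    return StrainParameters(**W3110_KW)


@pytest.fixture(scope="session")
def w3110_preset():
    return load_preset("ecoli_W3110")


def batch_scenario(
    params: StrainParameters,
    G0: float = 5.0,
    C_M0: float = 0.2,
    P0: float = 5e-5,
    t_end: float = 5.0,
    V0: float = 1.0,
    t_lag: float = 0.0,
) -> Scenario:
    """Plain batch culture: one batch phase, no feeding, no pulses."""
    return Scenario(
        initial_state=ReactorState(G=G0, P=P0, A=0.0, C_M=C_M0, R=0.0,
                                   I=0.0, D=0.0, V=V0),
        schedule=FeedingSchedule(
            phases=(FeedingPhase("batch", 0.0),), V0=V0, t_end=t_end
        ),
        params=params,
        t_lag=t_lag,
    )


@pytest.fixture(scope="session")
def w3110_batch(w3110_params) -> Scenario:
    return batch_scenario(w3110_params)


@pytest.fixture(scope="session")
def w3110_trajectory(w3110_preset):
    from microshift import simulate

    return simulate(w3110_preset.scenario)
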