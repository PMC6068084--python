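import numpy as np
import pytest

from fabthermo import InjectionProtocol, KineticParams

#: the five standard assay temperatures, K
TEMPS = np.array([283.15, 288.15, 293.15, 298.15, 303.15])

#: kinetic constants of the panel wild type at 25 degC
WT_KON = 2.48e6
WT_KOFF = 5.49e-4


@pytest.fixture
def wt_params() -> KineticParams:
    return KineticParams(kon=WT_KON, koff=WT_KOFF, rmax=100.0, temperature=298.15)


@pytest.fixture
def protocol() -> InjectionProtocol:
    return InjectionProtocol(t_assoc_start=0.0, t_assoc_end=120.0, t_end=720.0, concentration=5e-9)


def concentration_series(params: KineticParams, concentrations=(1.25e-9, 2.5e-9, 5e-9, 10e-9),
                         noise_sd: float = 0.0, seed=None):
    """Simulate the default 4-concentration series for one parameter set."""
    from fabthermo import simulate_sensorgram

    rng = np.random.default_rng(seed)
    return [
        simulate_sensorgram(
            params,
            InjectionProtocol(0.0, 120.0, 720.0, c),
            noise_sd=noise_sd,
            seed=rng,
        )
        for c in concentrations
    ]
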