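import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from enzkin.mechanisms import Condition, KineticParameters, Mechanism, rate_law
from enzkin.rates import VelocityObservation
from enzkin.simulate import (
    NoiseModel,
    PlateDesign,
    protocol_design,
    reference_truth,
    simulate_plate,
)

settings.register_profile(
    "default", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


def make_observations(mech, params, substrates, inhibitors, replicates=3,
                      noise_sd=0.0, seed=0):
    """Velocity observations straight from the rate law (+ optional noise)."""
    rng = np.random.default_rng(seed)
    obs = []
    for S in substrates:
        for I in inhibitors:
            v = float(rate_law(params.vmax, params.km, params.kic, params.kiu, S, I))
            for rep in range(1, replicates + 1):
                vv = v + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                obs.append(
                    VelocityObservation(
                        cond=Condition(S=S, I=I), replicate=rep,
                        v=max(vv, 0.0), slope=vv, r_squared=1.0,
                    )
                )
    return obs


@pytest.fixture
def b4_params():
    return KineticParameters(vmax=12.0, km=1.2, kic=132.0)


@pytest.fixture
def competitive_noiseless_obs(b4_params):
    return make_observations(
        Mechanism.COMPETITIVE, b4_params,
        substrates=(0.25, 0.5, 1.0), inhibitors=(0.0, 50.0, 100.0, 200.0),
    )


@pytest.fixture
def b4_plate():
    mech, truth = reference_truth("B4")
    return simulate_plate(
        protocol_design("B4"), mech, truth, NoiseModel(seed=1)
    )


@pytest.fixture
def noiseless_plate(b4_params):
    design = PlateDesign(
        substrate_levels=(0.25, 0.5, 1.0),
        inhibitor_levels=(0.0, 50.0, 200.0),
        replicates=2,
    )
    return simulate_plate(
        design, Mechanism.COMPETITIVE, b4_params,
        NoiseModel(absorbance_sd=0.0, baseline_range=(0.05, 0.05), seed=0),
    )
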