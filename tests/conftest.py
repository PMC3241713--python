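import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mgbsim import MembraneParams, StimulusSpec, SynapseParams


@pytest.fixture(scope="session")
def mp() -> MembraneParams:
    """Default (calibrated) membrane parameters, shared across tests."""
    return MembraneParams()


@pytest.fixture(scope="session")
def bias60(mp):
    """Bias current holding the default membrane at -60 mV (cached)."""
    from mgbsim import calibrate_bias
    return calibrate_bias(mp, -60.0)


@pytest.fixture()
def stim100() -> StimulusSpec:
    return StimulusSpec(ici=100.0, duration=500.0, onset=200.0, seed=0)


@pytest.fixture()
def syn_none() -> SynapseParams:
    return SynapseParams(plasticity_mode="None")


def pooled_metrics(results, ici, onset=200.0, duration=500.0):
    from mgbsim.metrics import condition_metrics
    return condition_metrics(
        [r.spike_times for r in results],
        [[s.spike_times for s in r.input_streams] for r in results],
        ici, onset, duration)
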