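import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pigeonvis.session_synth import NeuronProfile, TaskConfig, generate_session


def planted_population(n_neurons=77, target_si=0.5, stim_gain=2.0, seed=0,
                       baseline=10.0, n_groupings=5):
    """Excitatory units with preferred groupings assigned round-robin."""
    return [
        NeuronProfile(
            neuron_id=f"n{i:03d}",
            response_class="excitatory",
            baseline_rate_hz=baseline,
            stim_gain=stim_gain,
            preferred_grouping=i % n_groupings if target_si > 0 else None,
            target_si=target_si,
        )
        for i in range(n_neurons)
    ]


def untuned_population(n_neurons=20, seed=0, baseline=10.0):
    """Information-free units: identical rate law for every grouping."""
    return [
        NeuronProfile(neuron_id=f"u{i:03d}", baseline_rate_hz=baseline)
        for i in range(n_neurons)
    ]


@pytest.fixture
def default_task():
    return TaskConfig(rng_seed=11)


@pytest.fixture
def small_session(default_task):
    """One excitatory, one inhibitory, one nonresponsive unit."""
    neurons = [
        NeuronProfile(neuron_id="exc", response_class="excitatory",
                      baseline_rate_hz=5.0, stim_gain=4.0),
        NeuronProfile(neuron_id="inh", response_class="inhibitory",
                      baseline_rate_hz=20.0, stim_gain=0.25),
        NeuronProfile(neuron_id="non", baseline_rate_hz=10.0),
    ]
    return generate_session(default_task, neurons)
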