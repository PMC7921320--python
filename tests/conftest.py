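import numpy as np
import pytest

import stimdecode as sd


@pytest.fixture(scope="session")
def protocol():
    """Standard surrogate 8-pattern protocol, 100 trials per pattern."""
    return sd.generate_protocol(seed=1)


@pytest.fixture(scope="session")
def small_protocol():
    """Cheap protocol for pipeline tests: 8 patterns x 12 trials."""
    return sd.generate_protocol(seed=2, repetitions=12)


@pytest.fixture(scope="session")
def small_config():
    """Reduced decoding configuration for fast pipeline tests."""
    return sd.DecodingConfig(n_bootstrap_per_pattern=20, n_iterations=4, seed=5)


@pytest.fixture(scope="session")
def noise_neuron(protocol):
    """Separability-0 neuron: identical response statistics for all patterns."""
    model = sd.NeuronModel(baseline_rate_hz=10.0, separability=0.0, seed=11)
    return sd.simulate_neuron(protocol, model)


@pytest.fixture(scope="session")
def separable_neuron(protocol):
    """Strongly separable neuron: distinct pattern-locked evoked responses."""
    model = sd.NeuronModel(
        baseline_rate_hz=10.0, separability=8.0, response_gain=5.0, seed=12
    )
    return sd.simulate_neuron(protocol, model)


@pytest.fixture(scope="session")
def small_noise_neuron(small_protocol):
    model = sd.NeuronModel(baseline_rate_hz=10.0, separability=0.0, seed=21)
    return sd.simulate_neuron(small_protocol, model)


@pytest.fixture(scope="session")
def small_separable_neuron(small_protocol):
    model = sd.NeuronModel(
        baseline_rate_hz=10.0, separability=6.0, response_gain=4.0, seed=22
    )
    return sd.simulate_neuron(small_protocol, model)


def triangle_trace(
    peak_mv: float = 4.0,
    rise_ms: float = 0.2,
    fall_ms: float = 0.2,
    baseline_ms: float = 0.3,
    sampling_rate_hz: float = 100_000.0,
) -> np.ndarray:
    """Symmetric-by-default triangular spike on a flat baseline."""
    dt = 1000.0 / sampling_rate_hz
    t = np.arange(0.0, baseline_ms + rise_ms + fall_ms + baseline_ms, dt)
    v = np.zeros_like(t)
    up = (t >= baseline_ms) & (t <= baseline_ms + rise_ms)
    v[up] = peak_mv * (t[up] - baseline_ms) / rise_ms
    down = (t > baseline_ms + rise_ms) & (t <= baseline_ms + rise_ms + fall_ms)
    v[down] = peak_mv * (1 - (t[down] - baseline_ms - rise_ms) / fall_ms)
    return v
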