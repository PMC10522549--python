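import numpy as np
import pytest

import tmsflow as tf


@pytest.fixture(scope="session")
def schedule():
    return tf.build_default_schedule()


@pytest.fixture(scope="session")
def bolus_aif(schedule):
    """Deterministic (jitter-free) bolus arterial input."""
    return tf.generate_aif(tf.AifParams(profile="bolus_50"), schedule)


@pytest.fixture(scope="session")
def slow_aif(schedule):
    return tf.generate_aif(tf.AifParams(profile="slow_20"), schedule)


@pytest.fixture(scope="session")
def clean_study():
    """Noiseless phantom scan (all stochastic perturbations off)."""
    spec = tf.random_phantom_spec(7, noise_level=0.0, flow_jitter_sd=0.0)
    return tf.simulate_phantom(spec)[0]


@pytest.fixture(scope="session")
def noisy_studies():
    """Three rest scans of one phantom under the default noise conditions."""
    spec = tf.random_phantom_spec(5)
    return tf.simulate_phantom(spec)
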