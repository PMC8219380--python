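import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.RandomState(1234)


@pytest.fixture(scope="session")
def small_kp_dataset():
    """Two-experiment noisy KP potency dataset with its ground truth."""
    from tcrpower import kp_inference, synthetic

    truth = synthetic.default_kp_truth(2, seed=3, sigma_log=0.1)
    table, truth_dict = synthetic.generate_kp_potency_dataset(truth, seed=4)
    data = kp_inference.potency_data_from_table(table)
    return truth, table, data
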