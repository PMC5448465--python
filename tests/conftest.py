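import warnings

import pytest

import iodintake as it


@pytest.fixture(scope="session")
def survey_data():
    """Survey-like synthetic dataset: 300 subjects, 2 recall days each."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return it.simulate_dataset(n=300, seed=7)


@pytest.fixture(scope="session")
def recovery_data():
    """Parameter-recovery dataset: identity transform, f=150, sigma_b=20, sigma_w=30."""
    return it.simulate_dataset(n=2000, seed=11, preset="recovery")


@pytest.fixture
def three_subjects():
    return [
        it.Subject("a", 30, "male", 1.0),
        it.Subject("b", 45, "female", 2.0),
        it.Subject("c", 60, "male", 3.0),
    ]
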