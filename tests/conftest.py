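import dataclasses

import pytest

import infotrans as it


@pytest.fixture(scope="session")
def stimulus_set():
    """Default five-text synthetic stimulus set with profiles."""
    return it.generate_stimulus_set(it.StimulusGenConfig(seed=0))


@pytest.fixture(scope="session")
def profiles(stimulus_set):
    return stimulus_set[1]


@pytest.fixture(scope="session")
def linear_cohort(profiles):
    """A cohort whose generative response matches the fitted linear model,
    with ground truth attached — the parameter-recovery workhorse."""
    cfg = dataclasses.replace(it.CohortGenConfig(), response_shape="linear", seed=0)
    parts = it.generate_participants(cfg)
    filled, prov = it.generate_ratings(parts, profiles, cfg)
    return filled, prov, cfg


@pytest.fixture(scope="session")
def default_two_cohorts():
    """Default control (n=142) + clinical (n=19) dataset, shared stimuli."""
    return it.generate_two_cohorts()
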