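import numpy as np
import pytest
from hypothesis import settings

import gogomarkov as gm
from gogomarkov import synthetic_data as sd

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def defaults():
    """Study-default generator settings (seed 0)."""
    return sd.study_defaults(seed=0)


@pytest.fixture(scope="session")
def default_cohort(defaults):
    """One full study-default cohort: 22 participants x 3 environments x 120 trials."""
    config, kernels, rt_model = defaults
    trials, profiles = sd.generate_cohort(config, kernels, rt_model)
    return trials, profiles


@pytest.fixture(scope="session")
def filtered_cohort(default_cohort):
    trials, profiles = default_cohort
    kept, report = gm.filter_rt(trials)
    return kept, profiles, report


def small_config(seed=0, **overrides):
    """A fast 4-participant configuration for structural tests."""
    kwargs = dict(n_participants=4, n_female=2, trials_per_block=30, seed=seed)
    kwargs.update(overrides)
    return sd.GeneratorConfig(**kwargs)


@pytest.fixture
def small_cohort():
    config = small_config()
    kernels = {env: sd.AccuracyKernel.constant(0.85) for env in config.environments}
    rt_model = sd.RTModel(baseline_mean_ms={"2D": 450.0, "3D": 520.0, "AR": 620.0}, anticipatory_rate=0.0)
    trials, profiles = sd.generate_cohort(config, kernels, rt_model)
    return config, kernels, rt_model, trials, profiles


def rng_sequence(rng, n, p=0.5, participant="px", environment="2D"):
    """Random binary OutcomeSequence helper for oracle tests."""
    return gm.OutcomeSequence(
        participant_id=participant,
        environment=environment,
        outcomes=(rng.random(n) < p).astype(int),
    )
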