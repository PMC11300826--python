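import numpy as np
import pytest

from cogdrive import simulator as sim
from cogdrive.data import extract_snippets, standardize_factors


@pytest.fixture(scope="session")
def small_course():
    return sim.CourseSpec(n_lights_per_lap=4, n_yellow_per_lap=2,
                          light_spacing=250.0)


@pytest.fixture(scope="session")
def tiny_bundle(small_course):
    """10-subject separable study on a short course; shared by fast tests."""
    cfg = sim.separable_config(
        "bas_fun_seeking", effect_scale=2.0, cruise_slope=3.0,
        n_subjects=10, course=small_course)
    return sim.generate_dataset(cfg, seed=7)


@pytest.fixture(scope="session")
def tiny_snippets(tiny_bundle):
    snips, _ = extract_snippets(tiny_bundle.logs[~tiny_bundle.logs["is_practice"]],
                                window=20)
    return snips


@pytest.fixture(scope="session")
def tiny_profiles(tiny_bundle):
    profiles, _ = standardize_factors(tiny_bundle.subjects, ["bas_fun_seeking"])
    return profiles


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
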