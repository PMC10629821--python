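import warnings
from dataclasses import replace

import numpy as np
import pytest

import centrotrace as ct
from centrotrace.layout import FixtureConfig

warnings.filterwarnings("ignore", message="dropping regions")


@pytest.fixture(scope="session")
def annotation():
    return ct.CorticalUnitAnnotation(
        centre=(256.0, 256.0), lumen_radius=40.0, vz_thickness=60.0, tissue_radius=150.0
    )


@pytest.fixture(scope="session")
def fixture_config():
    """The standard synthetic scene bundle configuration (isolated puncta)."""
    return FixtureConfig()


@pytest.fixture(scope="session")
def noisefree_fixture_config(fixture_config):
    render = replace(fixture_config.render, poisson_noise=False, read_noise_sd=0.0)
    return replace(fixture_config, render=render)


@pytest.fixture(scope="session")
def standard_scene(fixture_config):
    """One rendered noisy scene with its ground truth (unit 0 of the fixture)."""
    cohort = ct.simulate_cohort(fixture_config.sim)
    rng = np.random.default_rng(fixture_config.sim.seed + 1)
    positioned = ct.layout_cohort(cohort, fixture_config.annotation, rng, fixture_config.layout)
    truth = positioned[positioned["unit_id"] == 0]
    img, _ = ct.render_image(truth, fixture_config.render, rng=np.random.default_rng(7))
    return img, truth
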