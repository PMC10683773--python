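"""Shared fixtures: one small synthetic study and its two hierarchical fits.

The expensive objects (study generation, MCMC fits) are session-scoped and
reused across test modules; everything is seeded so the suite is
deterministic.
"""

import warnings

import numpy as np
import pytest

from maculasum.hierarchical_fit import (
    HierarchicalModelSpec,
    McmcSettings,
    fit_hierarchical,
    posterior_predict,
)
from maculasum.structural_rgc import load_profiles
from maculasum.summation_template import DEFAULT_TEMPLATE
from maculasum.synthetic_cohort import (
    StudyConfig,
    attach_stimulus_columns,
    generate_study,
)

SMALL_STUDY_SEED = 42
FIT_MCMC = McmcSettings(chains=2, warmup=300, samples=300)


@pytest.fixture(scope="session")
def profiles():
    return load_profiles()


@pytest.fixture(scope="session")
def small_study(profiles):
    """8-eye study (1 young, 1 control, 2 per glaucoma stage), H1 truth."""
    cfg = StudyConfig(
        n_young=1, n_controls=1, n_per_glaucoma_stage=2, seed=SMALL_STUDY_SEED
    )
    truths, obs = generate_study(cfg, profiles)
    fitted = attach_stimulus_columns(obs, cfg.protocol, profiles)
    return {"config": cfg, "truths": truths, "observations": obs, "fitted": fitted}


@pytest.fixture(scope="session")
def h1_fit(small_study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_hierarchical(
            small_study["fitted"],
            HierarchicalModelSpec("horizontal", DEFAULT_TEMPLATE),
            FIT_MCMC,
            seed=11,
        )


@pytest.fixture(scope="session")
def h2_fit(small_study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_hierarchical(
            small_study["fitted"],
            HierarchicalModelSpec("vertical", DEFAULT_TEMPLATE),
            FIT_MCMC,
            seed=12,
        )


@pytest.fixture(scope="session")
def h1_predictions(small_study, h1_fit):
    return posterior_predict(h1_fit, small_study["fitted"])


@pytest.fixture(scope="session")
def h2_predictions(small_study, h2_fit):
    return posterior_predict(h2_fit, small_study["fitted"])


@pytest.fixture(scope="session")
def noise_free_young(profiles):
    """Noise-free young-healthy observations with exact retinal inputs."""
    from maculasum.synthetic_cohort import NoiseConfig, attach_retinal_input

    cfg = StudyConfig(
        n_young=5,
        n_controls=1,
        n_per_glaucoma_stage=1,
        noise=NoiseConfig(0.0, 0.0, 0.0),
        seed=7,
    )
    truths, obs = generate_study(cfg, profiles)
    young = obs[obs["cohort"] == "young"]
    young_truths = [t for t in truths if t.cohort == "young"]
    return attach_retinal_input(
        young, young_truths, cfg.protocol, profiles, density_source="latent"
    )
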