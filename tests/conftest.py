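"""Shared fixtures: a compact synthetic estuary, its environmental
series, one simulated survey rich enough to fit against, and a fitted
density model.  Session-scoped — the generators are deterministic, so
every test sees identical objects."""

import warnings

import pytest

from sawdens import (
    DensityGAM,
    EnvFieldSeries,
    EstuaryConfig,
    ModelSpec,
    SurveyDesign,
    generate_scene,
    simulate_survey,
)
from sawdens.experiments import RECOVERY_SMOOTHS, recovery_true_model

warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", category=UserWarning)


SMALL_CONFIG = EstuaryConfig(
    nx=20, ny=16, mouth_row=6,
    river_cols={"A": 3, "B": 10, "C": 16},
    river_halfwidth={"A": 1, "B": 1, "C": 1},
    sub_factor=6,
)


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(SMALL_CONFIG, seed=42)


@pytest.fixture(scope="session")
def small_env(small_scene):
    return EnvFieldSeries(small_scene, seed=42)


@pytest.fixture(scope="session")
def truth():
    return recovery_true_model()


@pytest.fixture(scope="session")
def small_survey(small_scene, small_env, truth):
    design = SurveyDesign(years=(2010, 2013),
                          sets_per_month={"A": 5, "B": 3, "C": 5})
    return simulate_survey(small_scene, small_env, truth, design, seed=42)


@pytest.fixture(scope="session")
def fitted(small_survey):
    spec = ModelSpec(smooths=RECOVERY_SMOOTHS, factors=("developed_sl",))
    return DensityGAM(small_survey, spec).fit(power=1.5, alpha=[100.0] * 3)
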