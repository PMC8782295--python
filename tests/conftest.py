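import numpy as np
import pytest

from atollcarbon.report import RunConfig, run_pipeline
from atollcarbon.synthetic_atoll import SceneConfig, SoilTruth, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A compact synthetic scene shared by fast structural tests."""
    config = SceneConfig(
        n_islets=4, islet_area_range_ha=(0.3, 2.0), cell_size=2.0, seed=7
    )
    scene, truth = generate_scene(config)
    return scene, truth


@pytest.fixture(scope="session")
def default_report():
    """One full-size pipeline run (the study-condition scene) shared by the
    recovery and reporting tests."""
    return run_pipeline(RunConfig(seed=1))


@pytest.fixture()
def soil_truth():
    return SoilTruth()
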