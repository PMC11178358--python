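import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from saberspot.pipeline import run_pipeline
from saberspot.synth import SceneParams

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_scene_params(seed=3, **overrides):
    """A fast, fully exercised scene for unit and determinism tests."""
    base = dict(
        image_shape=(12, 320, 320),
        n_nuclei=6,
        nucleus_radius_px=14.0,
        nucleus_z_extent=6.0,
        min_center_distance=90.0,
        edge_margin=48.0,
        puncta_scatter_radius=35.0,
        puncta_edge_margin=12.0,
        expression_rate={g: 6.0 for g in ("Sox10", "Wnt1", "Sp5", "Pak3", "Dlc1")},
        n_debris=4,
        rng_seed=seed,
    )
    base.update(overrides)
    return SceneParams(**base)


@pytest.fixture(scope="session")
def default_run():
    """The full default scene pushed through the entire pipeline once.

    This is the frozen study condition (20 nuclei, 5 genes at 30
    transcripts per cell, 20 broadband debris at 10x amplitude, known
    inter-round transform) shared by the recovery tests.
    """
    return run_pipeline(SceneParams(rng_seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
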