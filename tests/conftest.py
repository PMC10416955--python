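import pytest

from feedtrack import Circle, Polygon, SceneConfig, SimParams, TrackerParams, default_scene, simulate


@pytest.fixture
def scene() -> SceneConfig:
    return default_scene()


@pytest.fixture
def unit_square() -> Polygon:
    return Polygon([(0.0, 0.0), (2.0, 0.0), (2.0, 2.0), (0.0, 2.0)])


@pytest.fixture
def noiseless_scenario(scene):
    """Small deterministic flock with clean detections."""
    return simulate(SimParams(n_birds=3, n_frames=300, seed=7), scene)


@pytest.fixture
def noisy_scenario(scene):
    return simulate(
        SimParams(n_birds=5, n_frames=600, seed=3, sigma=2.0, p_miss=0.05, fp_rate=0.1),
        scene,
    )
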