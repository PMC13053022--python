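import numpy as np
import pytest

from metasearch import MetaMDPParams, Scene, SceneGeneratorConfig, generate_scene


@pytest.fixture
def small_config():
    return SceneGeneratorConfig(
        n_objects_min=8, n_objects_max=8, n_features=2, max_objects=8
    )


@pytest.fixture
def small_scene(small_config):
    return generate_scene(small_config, 3)


@pytest.fixture
def small_params():
    return MetaMDPParams(theta=0.9)


@pytest.fixture
def two_object_scene():
    """Minimal scene: one target, one distractor, far apart on the sphere."""
    return Scene(
        object_ids=["target", "distractor"],
        locations=np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0]]),
        features=np.array([[1.0], [-1.0]]),
        target_index=0,
        phantom_mask=np.array([False, False]),
    )


def make_scene(features, target_index=0, spread_deg=40.0, phantom_mask=None):
    """Scene with given features and objects spread along an arc."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    angles = np.deg2rad(np.linspace(-spread_deg, spread_deg, n))
    locs = np.stack([np.sin(angles), np.zeros(n), np.cos(angles)], axis=1)
    mask = np.zeros(n, dtype=bool) if phantom_mask is None else np.asarray(phantom_mask)
    locs[mask] = [0.0, 0.0, 1.0]
    features = features.copy()
    features[mask] = 0.0
    return Scene(
        object_ids=[f"o{i}" for i in range(n)],
        locations=locs,
        features=features,
        target_index=target_index,
        phantom_mask=mask,
    )
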