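import numpy as np
import pytest

import patmap


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def default_scene():
    """One default phantom scene (grid markers), shared across the session."""
    return patmap.make_phantom(seed=0)


@pytest.fixture(scope="session")
def prepared_model(default_scene):
    """Surface model of the default scene at the selected parameters."""
    return patmap.prepare_surface_model(
        default_scene.bone, default_scene.skin, default_scene.true_lcs,
        target_edge=3.0, thickness_range=(0.0, 20.0),
    )


@pytest.fixture(scope="session")
def coarse_model(default_scene):
    """Coarser, cheaper model for optimizer-heavy tests."""
    return patmap.prepare_surface_model(
        default_scene.bone, default_scene.skin, default_scene.true_lcs,
        target_edge=4.0, thickness_range=(0.0, 20.0),
    )


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return patmap.RigidTransform(R.as_matrix(), rng.uniform(-50, 50, 3))
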