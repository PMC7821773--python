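import numpy as np
import pytest

import morphodist as md


@pytest.fixture(scope="session")
def claw_params():
    """A modest-resolution claw used across the suite (16x12 rings = 194 verts)."""
    return md.ClawParams(n_rings=16, n_theta=12)


@pytest.fixture(scope="session")
def claw(claw_params):
    return md.make_claw(claw_params)


@pytest.fixture(scope="session")
def landmark_indices(claw_params):
    return md.default_landmark_indices(claw_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def random_mesh(rng, n_vertices=12, n_faces=8):
    """A small random (not necessarily manifold) but valid triangle mesh."""
    vertices = rng.normal(size=(n_vertices, 3))
    faces = np.array(
        [rng.choice(n_vertices, size=3, replace=False) for _ in range(n_faces)]
    )
    return md.TriangleMesh(vertices, faces)
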