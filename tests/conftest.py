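import numpy as np
import pytest
import trimesh

import chondrometry as cm


@pytest.fixture()
def rng():
    return np.random.default_rng(20240987)


@pytest.fixture()
def unit_square_patch():
    """Two-triangle planar patch in z = 0 spanning [0, 1]^2."""
    v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    f = np.array([[0, 1, 2], [0, 2, 3]])
    return cm.TriangleMesh(v, f)


@pytest.fixture()
def small_sphere_mesh():
    tm = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
    return cm.TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces))


@pytest.fixture(scope="session")
def bicondylar():
    """Noiseless default bicondylar phantom, shared across tests (read-only)."""
    return cm.make_bicondylar_phantom()


@pytest.fixture(scope="session")
def bicondylar_with_markers():
    return cm.add_markers(cm.make_bicondylar_phantom())


def random_rotation(rng) -> np.ndarray:
    """Uniform random rotation from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    q0, qx, qy, qz = q
    return np.array(
        [
            [q0**2 + qx**2 - qy**2 - qz**2, 2 * (qx * qy - q0 * qz), 2 * (qx * qz + q0 * qy)],
            [2 * (qy * qx + q0 * qz), q0**2 - qx**2 + qy**2 - qz**2, 2 * (qy * qz - q0 * qx)],
            [2 * (qz * qx - q0 * qy), 2 * (qz * qy + q0 * qx), q0**2 - qx**2 - qy**2 + qz**2],
        ]
    )
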