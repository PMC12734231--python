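import numpy as np
import pytest

from lvmech.synthetic_cohort import (
    VentricleSpec,
    generate_ventricle_sequence,
    _spheroid_template,
)


@pytest.fixture(scope="session")
def default_spec():
    return VentricleSpec()


@pytest.fixture(scope="session")
def default_sequence(default_spec):
    """One default ventricle cycle (mesh sequence, landmarks, ground truth)."""
    return generate_ventricle_sequence(default_spec)


@pytest.fixture(scope="session")
def spheroid_mesh(default_spec):
    """Static reference half-spheroid (points, triangles)."""
    verts, tris, _, _, _, _ = _spheroid_template(default_spec)
    return verts, tris


@pytest.fixture(scope="session")
def unit_sphere():
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    return np.asarray(m.vertices, float), np.asarray(m.faces, np.int64)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
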