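import numpy as np
import pytest

from ibfelv.constitutive import MaterialParams
from ibfelv.mesh import LVGeometrySpec, assign_fibers, generate_fixture, generate_lv_mesh


@pytest.fixture(scope="session")
def params() -> MaterialParams:
    return MaterialParams.healthy_human()


@pytest.fixture(scope="session")
def iso_params() -> MaterialParams:
    """Isotropic reduction (fiber/sheet/coupling moduli zero)."""
    return MaterialParams(a=2362.0, b=10.81, a_f=0.0, b_f=1.0, a_s=0.0,
                          b_s=1.0, a_fs=0.0, b_fs=1.0, beta_s=5.0e6)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def cube2():
    return generate_fixture("unit_cube", 2)


@pytest.fixture(scope="session")
def lv_small():
    """Coarse synthetic LV with the standard fiber rule."""
    spec = LVGeometrySpec(n_transmural=2, n_circumferential=16, n_longitudinal=6)
    mesh = generate_lv_mesh(spec)
    assign_fibers(mesh)
    return mesh


def random_admissible_F(rng: np.random.Generator, n: int, scale: float = 0.15):
    """Random deformation gradients with guaranteed positive determinant."""
    F = np.eye(3) + scale * rng.standard_normal((n, 3, 3))
    det = np.linalg.det(F)
    bad = det <= 0.05
    while np.any(bad):
        F[bad] = np.eye(3) + scale * rng.standard_normal((int(bad.sum()), 3, 3))
        det = np.linalg.det(F)
        bad = det <= 0.05
    return F


def random_frame(rng: np.random.Generator, n: int):
    """Random orthonormal (f0, s0) pairs."""
    f0 = rng.standard_normal((n, 3))
    f0 /= np.linalg.norm(f0, axis=1, keepdims=True)
    s0 = rng.standard_normal((n, 3))
    s0 -= np.sum(s0 * f0, axis=1, keepdims=True) * f0
    s0 /= np.linalg.norm(s0, axis=1, keepdims=True)
    return f0, s0
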