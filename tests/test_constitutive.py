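"""Holzapfel-Ogden law: invariants, energy, stress variants and conversions."""

import numpy as np
import pytest

from ibfelv.constitutive import (InvertedElementError, MaterialParams, VARIANTS,
                                 cauchy_stress, compute_invariants, fiber_stress,
                                 first_pk_stress, strain_energy)
from ibfelv.units import kpa

from conftest import random_admissible_F, random_frame

F0 = np.array([1.0, 0.0, 0.0])
S0 = np.array([0.0, 1.0, 0.0])


def fd_stress(F, f0, s0, p, variant, eps=1e-6):
    out = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += eps
            Fm[i, j] -= eps
            Wp = strain_energy(compute_invariants(Fp, f0, s0), p, variant)
            Wm = strain_energy(compute_invariants(Fm, f0, s0), p, variant)
            out[i, j] = (Wp - Wm) / (2 * eps)
    return out


@pytest.mark.parametrize("F, expected", [
    (np.eye(3), dict(I1=3.0, I4f=1.0, I4s=1.0, I8fs=0.0, J=1.0)),
    (np.eye(3) + 0.5 * np.outer(F0, S0),
     dict(I1=3.25, I4f=1.0, I4s=1.25, I8fs=0.5, J=1.0)),
    (np.diag([1.2, 1 / np.sqrt(1.2), 1 / np.sqrt(1.2)]),
     dict(I1=1.44 + 2 / 1.2, I4f=1.44, I4s=1 / 1.2, J=1.0)),
])
def test_invariants_reference_cases(F, expected):
    kin = compute_invariants(F, F0, S0)
    for name, val in expected.items():
        assert getattr(kin, name) == pytest.approx(val, abs=1e-12)


def test_inverted_state_raises():
    with pytest.raises(InvertedElementError):
        compute_invariants(np.diag([1.0, 1.0, -1.0]), F0, S0)


def test_energy_identity_is_isotropic_floor(params):
    kin = compute_invariants(np.eye(3), F0, S0)
    assert strain_energy(kin, params) == pytest.approx(params.a / (2 * params.b))


def test_fiber_term_silent_in_compression(params):
    """Fiber/sheet families carry no energy or stress in compression."""
    lam = 0.8
    F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])   # I4f = 0.64
    kin = compute_invariants(F, F0, S0)
    iso = MaterialParams(params.a, params.b, 0.0, 1.0, params.a_s, params.b_s,
                         params.a_fs, params.b_fs)
    kin_iso = compute_invariants(F, F0, S0)
    # removing the fiber modulus changes nothing when the fiber is shortened
    assert strain_energy(kin, params) == pytest.approx(
        strain_energy(kin_iso, iso), rel=1e-14)
    P = first_pk_stress(kin, params, "raw")
    P_iso = first_pk_stress(kin_iso, iso, "raw")
    np.testing.assert_allclose(P, P_iso, rtol=1e-13)


def test_simple_shear_energy_closed_form(params):
    gamma = 0.5
    F = np.eye(3) + gamma * np.outer(F0, S0)
    kin = compute_invariants(F, F0, S0)
    p = params
    expected = (p.a / (2 * p.b) * np.exp(p.b * (3.25 - 3))
                + p.a_s / (2 * p.b_s) * (np.exp(p.b_s * 0.25 ** 2) - 1)
                + p.a_fs / (2 * p.b_fs) * (np.exp(p.b_fs * 0.25) - 1))
    assert strain_energy(kin, params) == pytest.approx(expected, rel=1e-12)


def test_raw_stress_at_identity_is_isotropic(params):
    kin = compute_invariants(np.eye(3), F0, S0)
    np.testing.assert_allclose(first_pk_stress(kin, params, "raw"),
                               kpa(0.2362) * np.eye(3), rtol=1e-12)


def test_normalized_stress_vanishes_at_reference(params):
    kin = compute_invariants(np.eye(3), F0, S0)
    np.testing.assert_allclose(
        first_pk_stress(kin, params, "pressure_normalized"), 0.0, atol=1e-12)
    np.testing.assert_allclose(
        first_pk_stress(kin, params, "penalized"), 0.0, atol=1e-10)


def test_unknown_variant_rejected(params):
    kin = compute_invariants(np.eye(3), F0, S0)
    with pytest.raises(ValueError):
        first_pk_stress(kin, params, "bogus")
    with pytest.raises(ValueError):
        strain_energy(kin, params, "bogus")


def test_all_variants_are_energy_gradients(params, rng):
    """P = dW/dF for every variant over random admissible states."""
    n = 100
    F = random_admissible_F(rng, n)
    f0, s0 = random_frame(rng, n)
    kin = compute_invariants(F, f0, s0)
    for variant in VARIANTS:
        P = first_pk_stress(kin, params, variant)
        scale = np.abs(P).max(axis=(1, 2))
        for k in range(0, n, 7):        # spot-check FD on a subsample
            Pfd = fd_stress(F[k], f0[k], s0[k], params, variant)
            assert np.abs(P[k] - Pfd).max() / scale[k] < 1e-5


def test_gradient_consistency_full_sample(params, rng):
    """Directional-derivative check on all 100 states for every variant."""
    n = 100
    F = random_admissible_F(rng, n)
    f0, s0 = random_frame(rng, n)
    dF = rng.standard_normal((n, 3, 3))
    dF /= np.linalg.norm(dF, axis=(1, 2), keepdims=True)
    eps = 1e-6
    for variant in VARIANTS:
        kin = compute_invariants(F, f0, s0)
        P = first_pk_stress(kin, params, variant)
        Wp = strain_energy(compute_invariants(F + eps * dF, f0, s0), params, variant)
        Wm = strain_energy(compute_invariants(F - eps * dF, f0, s0), params, variant)
        directional = (Wp - Wm) / (2 * eps)
        predicted = np.einsum("nij,nij->n", P, dF)
        scale = np.abs(P).max(axis=(1, 2)) + 1.0
        assert np.max(np.abs(directional - predicted) / scale) < 1e-5


def test_frame_indifference(params, rng):
    from scipy.spatial.transform import Rotation
    F = random_admissible_F(rng, 20)
    f0, s0 = random_frame(rng, 20)
    Q = Rotation.random(20, random_state=7).as_matrix()
    W = strain_energy(compute_invariants(F, f0, s0), params)
    WQ = strain_energy(compute_invariants(Q @ F, f0, s0), params)
    np.testing.assert_allclose(W, WQ, rtol=1e-12)


def test_material_symmetry_under_axis_flip(params, rng):
    F = random_admissible_F(rng, 20)
    f0, s0 = random_frame(rng, 20)
    W = strain_energy(compute_invariants(F, f0, s0), params)
    np.testing.assert_allclose(
        W, strain_energy(compute_invariants(F, -f0, s0), params), rtol=1e-13)
    np.testing.assert_allclose(
        W, strain_energy(compute_invariants(F, f0, -s0), params), rtol=1e-13)


def test_tension_compression_switch_is_exact(params, rng):
    """dW/dI4f = 0 exactly whenever I4f <= 1 (and likewise for I4s)."""
    lam = 0.9
    F = np.diag([lam, 1.0, 1 / lam])
    kin = compute_invariants(F, F0, S0)
    assert kin.I4f < 1
    stiff = MaterialParams(params.a, params.b, 10 * params.a_f, params.b_f,
                           params.a_s, params.b_s, params.a_fs, params.b_fs)
    np.testing.assert_allclose(first_pk_stress(kin, params, "raw"),
                               first_pk_stress(kin, stiff, "raw"), rtol=1e-14)


def test_variants_differ_by_pure_pressure(params, rng):
    """pressure_normalized minus raw is a multiple of J F^{-T}, componentwise."""
    F = random_admissible_F(rng, 30)
    f0, s0 = random_frame(rng, 30)
    kin = compute_invariants(F, f0, s0)
    diff = (first_pk_stress(kin, params, "pressure_normalized")
            - first_pk_stress(kin, params, "raw"))
    JFinvT = kin.J[:, None, None] * np.swapaxes(np.linalg.inv(F), -1, -2)
    scale = np.abs(first_pk_stress(kin, params, "raw")).max()
    np.testing.assert_allclose(diff, -params.a * JFinvT,
                               atol=1e-9 * scale, rtol=1e-9)


def test_cauchy_stress_conversion(params, rng):
    F = random_admissible_F(rng, 1)[0]
    assert np.allclose(cauchy_stress(np.zeros((3, 3)), F), 0.0)
    P = rng.standard_normal((3, 3))
    np.testing.assert_allclose(cauchy_stress(P, np.eye(3)), P)
    # objectivity of W forces a symmetric Cauchy stress
    f0, s0 = random_frame(rng, 10)
    Fb = random_admissible_F(rng, 10)
    kin = compute_invariants(Fb, f0, s0)
    sig = cauchy_stress(first_pk_stress(kin, params, "pressure_normalized"), Fb)
    asym = np.abs(sig - np.swapaxes(sig, -1, -2)).max()
    assert asym / np.abs(sig).max() < 1e-10


def test_fiber_stress_cases(params, rng):
    F = random_admissible_F(rng, 1)[0]
    assert fiber_stress(np.zeros((3, 3)), F, F0) == 0.0
    p_iso = 3.7
    assert fiber_stress(p_iso * np.eye(3), F, F0) == pytest.approx(p_iso)


def test_fiber_stress_uniaxial_closed_form(params):
    """sigma_ff under incompressible fiber stretch matches the 1D law."""
    lam = 1.2
    F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
    kin = compute_invariants(F, F0, S0)
    sig = cauchy_stress(first_pk_stress(kin, params, "raw"), F)
    p = params
    # closed form: sigma_ff - sigma_iso contribution along the fiber
    I1, I4f = kin.I1, kin.I4f
    dW1 = 0.5 * p.a * np.exp(p.b * (I1 - 3))
    dW4 = p.a_f * (I4f - 1) * np.exp(p.b_f * (I4f - 1) ** 2)
    expected = 2 * dW1 * lam ** 2 + 2 * dW4 * lam ** 2
    assert fiber_stress(sig, F, F0) == pytest.approx(expected, rel=1e-12)


def test_exponential_overflow_clamped(params):
    F = np.diag([3.0, 3.0, 3.0])    # enormous I1
    kin = compute_invariants(F, F0, S0)
    with pytest.warns(RuntimeWarning, match="clamped"):
        W = strain_energy(kin, params)
    assert np.isfinite(W)


def test_parameter_validation():
    with pytest.raises(ValueError):
        MaterialParams(a=-1.0, b=1, a_f=1, b_f=1, a_s=1, b_s=1, a_fs=1, b_fs=1)
    with pytest.raises(ValueError):
        MaterialParams(a=1.0, b=1, a_f=1, b_f=1, a_s=1, b_s=1, a_fs=1, b_fs=1,
                       beta_s=-5.0)
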