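"""Lagrangian FE machinery: kinematics, mass matrix, force projection, loads."""

import numpy as np
import pytest

from ibfelv.constitutive import compute_invariants, strain_energy
from ibfelv.fem import (FemOperators, assemble_force_density, assemble_mass_matrix,
                        basal_penalty_force, deformation_gradient,
                        endocardial_pressure_force, full_rule, reduced_rule,
                        project_qp_to_nodes, _stress_rhs)
from ibfelv.mesh import generate_fixture
from ibfelv.units import mmhg


def test_quadrature_rules_weights():
    assert full_rule().weights.sum() == pytest.approx(8.0)
    assert reduced_rule().weights.sum() == pytest.approx(8.0)


def test_deformation_gradient_reference_and_affine(cube2, rng):
    F = deformation_gradient(cube2, cube2.nodes.copy())
    np.testing.assert_allclose(F, np.broadcast_to(np.eye(3), F.shape), atol=1e-14)
    A = np.array([[1.1, 0.2, 0.0], [0.0, 0.95, 0.05], [0.02, 0.0, 1.02]])
    chi = cube2.nodes @ A.T + np.array([0.3, -0.1, 0.2])
    F = deformation_gradient(cube2, chi)
    np.testing.assert_allclose(F, np.broadcast_to(A, F.shape), atol=1e-13)


def test_deformation_gradient_matches_finite_difference(cube2, rng):
    from ibfelv.fem import shape_values
    chi = cube2.nodes + 0.05 * rng.standard_normal(cube2.nodes.shape)
    rule = full_rule()
    F = deformation_gradient(cube2, chi, rule)
    # directional FD of the interpolated map at the first quadrature point
    e, q = 3, 2
    Xe = cube2.nodes[cube2.elements[e]]
    xe = chi[cube2.elements[e]]
    xi0 = rule.points[q]
    # central difference in physical space via the reference map
    eps = 1e-6
    for d in range(3):
        dxi = np.zeros(3)
        dxi[d] = eps
        xp = shape_values((xi0 + dxi)[None])[0] @ xe
        xm = shape_values((xi0 - dxi)[None])[0] @ xe
        Xp = shape_values((xi0 + dxi)[None])[0] @ Xe
        Xm = shape_values((xi0 - dxi)[None])[0] @ Xe
        dX = Xp - Xm
        # F maps reference increments to physical increments
        np.testing.assert_allclose(F[e, q] @ dX, xp - xm, rtol=1e-6,
                                   atol=1e-14)


def test_mass_matrix_properties(cube2):
    M = assemble_mass_matrix(cube2)
    assert M.sum() == pytest.approx(1.0)                      # total volume
    assert np.abs((M - M.T)).max() < 1e-14
    w = np.linalg.eigvalsh(M.toarray())
    assert w.min() > 0


def test_force_density_zero_at_reference(cube2, params):
    """Pressure-normalized stress produces identically zero force density in
    the reference configuration."""
    ops = FemOperators(cube2)
    for var in ("pressure_normalized", "penalized"):
        F = assemble_force_density(cube2, cube2.nodes.copy(), params,
                                   variant=var, ops=ops)
        assert np.abs(F).max() < 1e-6


def test_total_force_balance_on_traction_free_body(cube2, params, rng):
    """Partition of unity implies sum_m (M F)_m = 0 for interior stresses."""
    ops = FemOperators(cube2)
    chi = cube2.nodes + 0.05 * rng.standard_normal(cube2.nodes.shape)
    rhs = _stress_rhs(cube2, chi, params, "penalized", ops)
    scale = np.abs(rhs).max()
    assert np.abs(rhs.sum(axis=0)).max() < 1e-9 * scale


def test_patch_test_constant_stress(cube2, params):
    """Affine deformation: F constant; uniform P has zero interior residual."""
    A = np.eye(3) + np.array([[0.05, 0.02, 0.0], [0.0, -0.03, 0.01],
                              [0.0, 0.0, 0.04]])
    chi = cube2.nodes @ A.T
    F = deformation_gradient(cube2, chi)
    assert np.abs(F - F[0, 0]).max() < 1e-13
    ops = FemOperators(cube2)
    rhs = _stress_rhs(cube2, chi, params, "raw", ops)
    interior = np.setdiff1d(np.arange(cube2.n_nodes),
                            np.unique(np.concatenate(
                                [v for v in cube2.node_sets.values()])))
    assert interior.size > 0
    assert np.abs(rhs[interior]).max() < 1e-8 * np.abs(rhs).max()


def test_penalty_force_restores_volume(params):
    """Uniform compression with beta_s > 0 produces an outward volumetric
    force matching the analytic beta_s log(J) F^{-T} term on one element."""
    cube = generate_fixture("unit_cube", 1)
    ops = FemOperators(cube)
    s = 0.95
    chi = s * cube.nodes
    rhs_pen = _stress_rhs(cube, chi, params, "penalized_no_ps", ops)
    rhs_raw = _stress_rhs(cube, chi, params, "raw", ops)
    pen = rhs_pen - rhs_raw
    # hand assembly: P_vol = beta_s log(s^3) (1/s) I; r_l = -P_vol . int grad(phi_l)
    coef = params.beta_s * np.log(s ** 3) / s
    gradN = ops.geo["reduced"]["gradN"][0, 0]               # (8, 3) at center
    wdetJ = ops.geo["reduced"]["wdetJ"][0, 0]
    expected = -coef * gradN * wdetJ
    np.testing.assert_allclose(pen[cube.elements[0]], expected, rtol=1e-10)
    # compression (log J < 0) pushes corner nodes outward
    outward = cube.nodes[cube.elements[0]] - 0.5
    assert np.all(np.einsum("li,li->l", pen[cube.elements[0]], outward) > 0)


def test_energy_consistency_virtual_work(cube2, params, rng):
    """sum (rhs . dchi) = -directional derivative of int W dX."""
    ops = FemOperators(cube2)
    chi = cube2.nodes + 0.03 * rng.standard_normal(cube2.nodes.shape)
    dchi = rng.standard_normal(chi.shape)
    dchi /= np.linalg.norm(dchi)
    for variant in ("raw", "penalized"):
        rhs = _stress_rhs(cube2, chi, params, variant, ops)
        work = float(np.sum(rhs * dchi))

        def total_energy(x):
            F = deformation_gradient(cube2, x, ops=ops)
            kin = compute_invariants(F, cube2.fiber_f0, cube2.fiber_s0)
            W = strain_energy(kin, params, "raw")
            E = float(np.sum(W * ops.geo["full"]["wdetJ"]))
            if variant != "raw":
                Fr = deformation_gradient(cube2, x, ops=ops, key="reduced")
                kinr = compute_invariants(Fr, cube2.fiber_f0[:, :1],
                                          cube2.fiber_s0[:, :1])
                Wmod = strain_energy(kinr, params, variant) \
                    - strain_energy(kinr, params, "raw")
                E += float(np.sum(Wmod * ops.geo["reduced"]["wdetJ"]))
            return E

        eps = 1e-6
        dE = (total_energy(chi + eps * dchi) - total_energy(chi - eps * dchi)) / (2 * eps)
        assert work == pytest.approx(-dE, rel=1e-5)


def test_reduced_penalty_avoids_volumetric_locking(iso_params):
    """Near-incompressible cantilever bending: the selectively reduced
    penalty yields a larger (unlocked) tip displacement than integrating
    the penalty with the full rule."""
    from ibfelv.static import StaticBCs, solve_static
    slab = generate_fixture("slab", 2)
    t_tip = 20.0
    bcs = StaticBCs(basal_cylindrical=False,
                    fixed={"xmin": (0, 1, 2)},
                    tractions={"xmax": np.array([0.0, 0.0, t_tip])})
    tips = {}
    for rule in ("reduced", "full"):
        sol = solve_static(slab, iso_params, p_endo=0.0, bcs=bcs,
                           variant="penalized", increments=4,
                           penalty_quadrature=rule)
        tips[rule] = sol.displacement[slab.node_sets["xmax"], 2].mean()
    assert tips["reduced"] > tips["full"] > 0


def test_endocardial_pressure_single_face():
    cube = generate_fixture("unit_cube", 1)
    p = 1.0e4
    rhs = endocardial_pressure_force(cube, cube.nodes.copy(), p, face_set="xmax")
    total = rhs.sum(axis=0)
    np.testing.assert_allclose(total, [-p, 0.0, 0.0], atol=1e-9 * p)


def test_endocardial_pressure_closed_surface_balances():
    sh = generate_fixture("spherical_shell", 6)
    p = mmhg(7.5)
    rhs = endocardial_pressure_force(sh, sh.nodes.copy(), p, face_set="inner")
    area = 4 * np.pi * 1.0 ** 2
    assert np.linalg.norm(rhs.sum(axis=0)) < 1e-10 * p * area


def test_endocardial_pressure_open_surface_vector_area(lv_small):
    """Net force on the truncated endocardium equals p times the vector area
    of the basal opening (pointing along -z: the opening faces +z)."""
    p = mmhg(7.5)
    rhs = endocardial_pressure_force(lv_small, lv_small.nodes.copy(), p)
    ring = lv_small.nodes[lv_small.node_sets["basal_ring_endo"]]
    # polygon vector area of the basal opening
    area = 0.0
    c = ring.mean(axis=0)
    for i in range(ring.shape[0]):
        a, b = ring[i], ring[(i + 1) % ring.shape[0]]
        area += np.cross(a - c, b - c)[2] / 2
    total = rhs.sum(axis=0)
    # the cavity pressure pushes the wall apex-ward: net force -p * A_cap e_z
    assert total[2] == pytest.approx(-p * abs(area), rel=1e-10)
    assert np.hypot(total[0], total[1]) < 1e-9 * p * abs(area)


def test_pressure_missing_face_set(cube2):
    with pytest.raises(ValueError):
        endocardial_pressure_force(cube2, cube2.nodes.copy(), 1.0,
                                   face_set="endocardium")


def test_basal_penalty_directions(lv_small):
    kappa = 1.0e7
    ids = lv_small.node_sets["basal_plane"]
    X = lv_small.nodes
    axis = X[ids, :2].mean(axis=0)

    # pure radial displacement of basal nodes -> no penalty
    chi = X.copy()
    rad = np.zeros_like(X)
    rel = X[ids, :2] - axis
    rel /= np.linalg.norm(rel, axis=1, keepdims=True)
    chi[ids, :2] += 0.1 * rel
    f = basal_penalty_force(lv_small, chi, kappa)
    assert np.abs(f).max() < 1e-6 * kappa * 0.1

    # axial displacement -> restoring force -kappa * delta * e_z
    delta = 0.05
    chi = X.copy()
    chi[ids, 2] += delta
    f = basal_penalty_force(lv_small, chi, kappa)
    np.testing.assert_allclose(f[ids, 2], -kappa * delta, rtol=1e-12)
    # non-basal nodes never contribute
    others = np.setdiff1d(np.arange(lv_small.n_nodes), ids)
    assert np.abs(f[others]).max() == 0.0


def test_project_qp_to_nodes_reproduces_constants_and_linears(cube2):
    ops = FemOperators(cube2)
    const = np.full((cube2.n_elements, 8), 2.5)
    np.testing.assert_allclose(project_qp_to_nodes(cube2, const, ops), 2.5)
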