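"""Quasi-static nonlinear FE reference solver.

Solves the equilibrium of the penalized hyperelastic weak form on the same
hexahedral mesh, material and loading as the coupled IB/FE model, but with
displacement boundary conditions imposed *exactly*: circumferential and
longitudinal displacement of the basal plane are eliminated in cylindrical
components (radial motion stays free), and the endocardial pressure is a
follower load.  This solver is the in-repository stand-in for a commercial
nonlinear FE benchmark and provides the reference fields for all
verification comparisons.

Newton's method with load continuation; the tangent is assembled by central
finite differences of the element (and pressure-face) force vectors, which
is exact to O(eps^2) and keeps the residual and the tangent trivially
consistent, trading speed for robustness at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import (InvertedElementError, MaterialParams, cauchy_stress,
                           compute_invariants, det3, first_pk_stress, inv3)
from .fem import (FemOperators, element_stress_forces, surface_traction_force,
                  _face_pressure_rhs, _modifier_coefficient, _quad_shape, _Q2D)
from .mesh import HexMesh

__all__ = ["StaticBCs", "StaticSolution", "solve_static"]


@dataclass
class StaticBCs:
    """Exact displacement constraints and extra loads for the static solve.

    ``basal_cylindrical``: eliminate circumferential+longitudinal dofs of the
    ``basal_plane`` node set (radial free).  ``fixed``: {node_set: dirs} with
    dirs a tuple of cartesian components to fix (e.g. symmetry planes).
    ``pins``: explicit (node_id, component) fixes (e.g. rigid-mode removal).
    ``tractions``: {face_set: 3-vector} dead nominal tractions.
    """

    basal_cylindrical: bool = True
    fixed: dict = field(default_factory=dict)
    pins: tuple = ()
    tractions: dict = field(default_factory=dict)


@dataclass
class StaticSolution:
    chi: np.ndarray
    displacement: np.ndarray
    F: np.ndarray                 # (ne, nq, 3, 3) full rule
    J: np.ndarray
    sigma_ff: np.ndarray          # (ne, nq) fiber Cauchy stress, dyn/cm^2
    log_lambda_f: np.ndarray      # (ne, nq)
    convergence: list             # residual-norm history per load increment

    @property
    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.displacement, axis=1).max())


def _constraint_transform(mesh: HexMesh, bcs: StaticBCs) -> sp.csr_matrix:
    """Sparse T with u_full = T q: unit columns for free cartesian dofs and
    radial-direction columns for basal nodes."""
    n = mesh.n_nodes
    fixed_dirs = [set() for _ in range(n)]
    for sname, dirs in bcs.fixed.items():
        for i in mesh.node_sets[sname]:
            fixed_dirs[i].update(dirs)
    for (i, d) in bcs.pins:
        fixed_dirs[i].add(d)
    basal = set()
    if bcs.basal_cylindrical:
        if "basal_plane" not in mesh.node_sets:
            raise ValueError("mesh lacks basal_plane node set")
        basal = set(int(i) for i in mesh.node_sets["basal_plane"])

    axis_xy = (mesh.nodes[sorted(basal), :2].mean(axis=0)
               if basal else np.zeros(2))
    rows, cols, vals = [], [], []
    ncol = 0
    for i in range(n):
        if i in basal:
            x, y = mesh.nodes[i, :2] - axis_xy
            r = np.hypot(x, y)
            if r < 1e-10:
                raise ValueError(f"basal node {i} on the long axis")
            rows += [3 * i, 3 * i + 1]
            cols += [ncol, ncol]
            vals += [x / r, y / r]
            ncol += 1
            continue
        for d in range(3):
            if d in fixed_dirs[i]:
                continue
            rows.append(3 * i + d)
            cols.append(ncol)
            vals.append(1.0)
            ncol += 1
    return sp.csr_matrix((vals, (rows, cols)), shape=(3 * n, ncol))


def _residual(mesh, ops, params, variant, chi, p_endo, bcs,
              penalty_quadrature="reduced", lam=1.0) -> np.ndarray:
    """Equilibrium residual at load factor ``lam`` (scales pressure and
    tractions alike for continuation)."""
    re = element_stress_forces(mesh, ops, params, variant, chi[mesh.elements],
                               penalty_quadrature=penalty_quadrature)
    rhs = np.zeros((mesh.n_nodes, 3))
    np.add.at(rhs, mesh.elements.ravel(), re.reshape(-1, 3))
    if lam * p_endo != 0.0:
        fs = "endocardium" if "endocardium" in mesh.face_sets else "inner"
        rhs += _face_pressure_rhs(mesh.face_sets[fs], chi, lam * p_endo,
                                  mesh.n_nodes)
    for fset, t in bcs.tractions.items():
        rhs += surface_traction_force(mesh, lam * np.asarray(t), fset)
    return rhs.ravel()


def _batched_elem_forces(mesh, ops, params, variant, xe_b,
                         penalty_quadrature="reduced"):
    """Element stress forces for a batch of nodal configurations.

    xe_b has shape (B, ne, 8, 3); returns (B, ne, 8, 3).  Used by the
    finite-difference tangent so all dof perturbations are evaluated in a
    single set of vectorized tensor contractions.
    """
    geo = ops.geo["full"]
    F = np.einsum("beld,eqlr->beqdr", xe_b, geo["gradN"], optimize=True)
    kin = compute_invariants(F, mesh.fiber_f0, mesh.fiber_s0)
    P = first_pk_stress(kin, params, variant="raw")
    if variant != "raw" and penalty_quadrature == "full":
        c = _modifier_coefficient(kin.J, params, variant)
        P = P + c[..., None, None] * np.swapaxes(inv3(F, kin.J), -1, -2)
        return -np.einsum("eq,beqdk,eqlk->beld", geo["wdetJ"], P,
                          geo["gradN"], optimize=True)
    with_ps = variant in ("pressure_normalized", "penalized")
    if with_ps:
        P = P - params.a * np.eye(3)
    re = -np.einsum("eq,beqdk,eqlk->beld", geo["wdetJ"], P, geo["gradN"],
                    optimize=True)
    if variant != "raw":
        geo_r = ops.geo["reduced"]
        Fr = np.einsum("beld,eqlr->beqdr", xe_b, geo_r["gradN"], optimize=True)
        Jr = det3(Fr)
        c = _modifier_coefficient(Jr, params, variant)
        Pmod = c[..., None, None] * np.swapaxes(inv3(Fr, Jr), -1, -2)
        if with_ps:
            Pmod = Pmod + params.a * np.eye(3)
        re = re - np.einsum("eq,beqdk,eqlk->beld", geo_r["wdetJ"], Pmod,
                            geo_r["gradN"], optimize=True)
    return re


def _tangent(mesh, ops, params, variant, chi, p_endo, bcs,
             eps: float = 1e-6, penalty_quadrature="reduced") -> sp.csr_matrix:
    """d(residual)/d(chi) by batched central differences at element/face
    level; central (not forward) differences are required because the
    forward O(beta_s * eps) truncation exceeds the stiffness of the softest
    hourglass modes near the reference state and can make K indefinite.
    """
    conn = mesh.elements
    ne = conn.shape[0]
    xe = chi[conn]
    # central differences: forward-difference truncation (~beta_s * eps) is
    # larger than the stiffness of the softest hourglass modes at low strain
    # and can render the tangent indefinite
    xb = np.broadcast_to(xe, (48,) + xe.shape).copy()
    for j in range(24):
        l, d = divmod(j, 3)
        xb[2 * j, :, l, d] += eps
        xb[2 * j + 1, :, l, d] -= eps
    fb = _batched_elem_forces(mesh, ops, params, variant, xb,
                              penalty_quadrature).reshape(48, ne, 24)
    Ke = np.transpose((fb[0::2] - fb[1::2]) / (2 * eps), (1, 2, 0))
    dof = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(ne, 24)
    rows = np.repeat(dof, 24, axis=1).ravel()
    cols = np.tile(dof, (1, 24)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                      shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes)).tocsr()

    if p_endo != 0.0:
        fs = "endocardium" if "endocardium" in mesh.face_sets else "inner"
        faces = mesh.face_sets[fs]
        nf = faces.shape[0]
        xf = chi[faces]                                 # (nf, 4, 3)
        Kf = np.zeros((nf, 12, 12))
        for j in range(12):
            l, d = divmod(j, 3)
            xp = xf.copy()
            xp[:, l, d] += eps
            xm = xf.copy()
            xm[:, l, d] -= eps
            fp = _face_force(xp, p_endo).reshape(nf, 12)
            fm = _face_force(xm, p_endo).reshape(nf, 12)
            Kf[:, :, j] = (fp - fm) / (2 * eps)
        dof = (3 * faces[:, :, None] + np.arange(3)[None, None, :]).reshape(nf, 12)
        rows = np.repeat(dof, 12, axis=1).ravel()
        cols = np.tile(dof, (1, 12)).ravel()
        K = K + sp.coo_matrix((Kf.ravel(), (rows, cols)), shape=K.shape).tocsr()
    return K


def _face_force(xq, p):
    """Follower-pressure face force for given face node positions (nf,4,3)."""
    N, dN = _quad_shape(_Q2D)
    a1 = np.einsum("fld,gl->fgd", xq, dN[:, :, 0])
    a2 = np.einsum("fld,gl->fgd", xq, dN[:, :, 1])
    nvec = np.cross(a1, a2)
    return -p * np.einsum("gl,fgd->fld", N, nvec)


def solve_static(mesh: HexMesh, params: MaterialParams, p_endo: float,
                 bcs: StaticBCs | None = None, variant: str = "penalized",
                 increments: int = 10, rtol: float = 1e-9,
                 max_newton: int = 30, verbose: bool = False,
                 penalty_quadrature: str = "reduced") -> StaticSolution:
    """Newton solve of the penalized weak form with load continuation.

    The pressure is applied in ``increments`` uniform steps (halved
    adaptively on Newton divergence).  Residual convergence is measured in
    the reduced (constrained) dof space against the applied-load scale.
    """
    if p_endo < 0:
        raise ValueError("p_endo must be non-negative")
    bcs = bcs or StaticBCs()
    ops = FemOperators(mesh)
    T = _constraint_transform(mesh, bcs)
    chi = mesh.nodes.copy()

    # load scale for the convergence test: the applied load vector itself
    load = np.zeros((mesh.n_nodes, 3))
    if p_endo > 0:
        fs = "endocardium" if "endocardium" in mesh.face_sets else "inner"
        load += _face_pressure_rhs(mesh.face_sets[fs], chi, p_endo, mesh.n_nodes)
    for fset, t in bcs.tractions.items():
        load += surface_traction_force(mesh, t, fset)
    scale = max(float(np.abs(load).max()), params.a)
    tol = rtol * scale
    # Newton trust region: cap nodal position updates at half the smallest
    # reference edge length (the exponential material punishes overshoot)
    xe0 = mesh.element_nodes()
    edges = [(0, 1), (3, 2), (4, 5), (7, 6), (0, 3), (1, 2), (4, 7), (5, 6),
             (0, 4), (1, 5), (2, 6), (3, 7)]
    h_min = min(float(np.min(np.linalg.norm(xe0[:, b] - xe0[:, a], axis=1)))
                for a, b in edges)
    step_cap = 0.5 * h_min

    # unified continuation: a global load factor lam in [0, 1] scales the
    # endocardial pressure and all dead tractions together
    loaded = (p_endo > 0) or bool(bcs.tractions)
    history = []
    lam_applied = 0.0
    dlam = 1.0 / increments if loaded else 1.0
    dlam_last = None
    dchi_last = None
    guard = 0
    while lam_applied < 1.0 or guard == 0:
        guard += 1
        lam_try = min(lam_applied + dlam, 1.0) if loaded else 0.0
        chi_inc = chi.copy()
        if dlam_last and dchi_last is not None:
            # secant predictor from the previous increment
            chi_inc = chi + ((lam_try - lam_applied) / dlam_last) * dchi_last
        res_hist = []
        ok = True
        lu = None
        rn2_prev = None
        for it in range(max_newton):
            try:
                R = _residual(mesh, ops, params, variant, chi_inc, p_endo,
                              bcs, penalty_quadrature, lam_try)
            except InvertedElementError:
                ok = False
                break
            Rr = T.T @ R
            rn = float(np.abs(Rr).max())
            rn2 = float(np.linalg.norm(Rr))
            res_hist.append(rn)
            if verbose:
                print(f"  lam={lam_try:6.3f}  it={it}  |R|={rn:.3e}", flush=True)
            if rn < tol:
                break
            # modified Newton: refresh the tangent only when progress slows
            if lu is None or rn2_prev is None or rn2 > 0.25 * rn2_prev:
                K = _tangent(mesh, ops, params, variant, chi_inc,
                             lam_try * p_endo, bcs,
                             penalty_quadrature=penalty_quadrature)
                Kr = (T.T @ K @ T).tocsc()
                try:
                    lu = spla.splu(Kr, permc_spec="MMD_ATA")
                except RuntimeError:
                    ok = False
                    break
            rn2_prev = rn2
            dq = lu.solve(-Rr)
            # trust-region cap plus strictly monotone backtracking on ||R||_2
            step = float(np.abs(T @ dq).max())
            t = min(1.0, step_cap / max(step, 1e-30))
            for _ in range(10):
                trial = chi_inc + t * (T @ dq).reshape(-1, 3)
                try:
                    Rt = _residual(mesh, ops, params, variant, trial, p_endo,
                                   bcs, penalty_quadrature, lam_try)
                except InvertedElementError:
                    t *= 0.5
                    continue
                if float(np.linalg.norm(T.T @ Rt)) < rn2 * (1 - 1e-4 * t):
                    chi_inc = trial
                    break
                t *= 0.5
            else:
                ok = False
                break
        else:
            ok = False
        if ok and res_hist and res_hist[-1] < tol:
            dchi_last = chi_inc - chi
            dlam_last = lam_try - lam_applied
            chi = chi_inc
            lam_applied = lam_try
            history.append(np.asarray(res_hist))
            if len(res_hist) <= 8:
                dlam = min(2.0 * dlam, 1.0 / 3.0)
            if not loaded:
                break
        else:
            dlam *= 0.5
            dchi_last = None
            dlam_last = None
            if not loaded or dlam < 1.0 / (increments * 256):
                raise RuntimeError(
                    f"Newton diverged at load factor {lam_try:.4f} "
                    f"(last residual {res_hist[-1] if res_hist else np.nan:.3e})")

    # derived fields at full quadrature
    geo = ops.geo["full"]
    F = np.einsum("eld,eqlr->eqdr", chi[mesh.elements], geo["gradN"])
    kin = compute_invariants(F, mesh.fiber_f0, mesh.fiber_s0)
    P = first_pk_stress(kin, params, variant=variant)
    sig = cauchy_stress(P, F)
    Ff = np.einsum("eqij,eqj->eqi", F, mesh.fiber_f0)
    fhat = Ff / np.linalg.norm(Ff, axis=-1, keepdims=True)
    sigma_ff = np.einsum("eqi,eqij,eqj->eq", fhat, sig, fhat)
    return StaticSolution(
        chi=chi, displacement=chi - mesh.nodes, F=F, J=kin.J,
        sigma_ff=sigma_ff, log_lambda_f=0.5 * np.log(kin.I4f),
        convergence=history,
    )
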