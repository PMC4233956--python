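"""Lagrangian finite-element machinery on hexahedral meshes.

Trilinear (8-node) elements with Gaussian quadrature.  The elastic force
density F is defined weakly through the FE mass matrix,

    sum_l M_ml F_l = - int_U P(F) grad(phi_m) dX  + surface terms,

and recovered by a sparse mass solve.  Selective reduced integration guards
against volumetric locking: the base (unmodified) stress is integrated
with the full 2x2x2 rule, while the pressure-normalization and volumetric-
penalty contributions -- the pressure-like parts of the modified stress --
are integrated with the reduced single-point rule.  On affine (parallel-
epiped) elements both rules integrate the reference-state weak form
exactly, so the pressure-normalized force density vanishes identically at
chi = X; on curved elements a small quadrature residual of order a times
the element distortion remains (far below the loading scale), exactly as
in the underlying discretization this module reproduces.

Surface loads: the endocardial pressure is a follower load (traction
-p n da over the *deformed* faces); basal in-plane/longitudinal motion is
penalized per node in cylindrical components, leaving radial motion free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import (InvertedElementError, MaterialParams, compute_invariants,
                           det3, first_pk_stress, inv3)
from .mesh import HexMesh

__all__ = [
    "QuadratureRule", "full_rule", "reduced_rule",
    "shape_values", "shape_gradients",
    "deformation_gradient", "assemble_mass_matrix", "assemble_force_density",
    "endocardial_pressure_force", "surface_traction_force", "basal_penalty_force",
    "FemOperators", "project_qp_to_nodes",
]

_NODE_SIGNS = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], float)
_G = 1.0 / np.sqrt(3.0)


@dataclass(frozen=True)
class QuadratureRule:
    """Tensor-product Gauss rule on the reference hex [-1,1]^3."""

    points: np.ndarray      # (nq, 3)
    weights: np.ndarray     # (nq,)
    tag: str

    def __post_init__(self):
        if not np.isclose(self.weights.sum(), 8.0):
            raise ValueError("quadrature weights must sum to the reference volume 8")


def full_rule() -> QuadratureRule:
    pts = np.array([[x, y, z] for z in (-_G, _G) for y in (-_G, _G) for x in (-_G, _G)])
    return QuadratureRule(points=pts, weights=np.ones(8), tag="full_2x2x2")


def reduced_rule() -> QuadratureRule:
    return QuadratureRule(points=np.zeros((1, 3)), weights=np.array([8.0]),
                          tag="reduced_1pt")


def shape_values(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions at reference points (nq, 3) -> (nq, 8)."""
    xi = np.atleast_2d(xi)
    N = np.ones((xi.shape[0], 8))
    for d in range(3):
        N *= (1 + _NODE_SIGNS[None, :, d] * xi[:, None, d]) / 2.0
    return N


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """Reference gradients dN/dxi -> (nq, 8, 3)."""
    xi = np.atleast_2d(xi)
    nq = xi.shape[0]
    out = np.zeros((nq, 8, 3))
    for l in range(8):
        sx, sy, sz = _NODE_SIGNS[l]
        fx = 1 + sx * xi[:, 0]
        fy = 1 + sy * xi[:, 1]
        fz = 1 + sz * xi[:, 2]
        out[:, l, 0] = sx * fy * fz / 8.0
        out[:, l, 1] = fx * sy * fz / 8.0
        out[:, l, 2] = fx * fy * sz / 8.0
    return out


class FemOperators:
    """Precomputed geometric factors and the factorized mass matrix."""

    def __init__(self, mesh: HexMesh):
        self.mesh = mesh
        self.rules = {"full": full_rule(), "reduced": reduced_rule()}
        Xe = mesh.element_nodes()
        self.geo = {}
        for key, rule in self.rules.items():
            dN = shape_gradients(rule.points)
            Jm = np.einsum("eld,qlr->eqdr", Xe, dN)
            detJ = np.linalg.det(Jm)
            if np.any(detJ <= 0):
                raise ValueError("reference mesh has non-positive Jacobians")
            gradN = np.einsum("qlr,eqrd->eqld", dN, np.linalg.inv(Jm))
            self.geo[key] = {
                "N": shape_values(rule.points),
                "gradN": gradN,
                "wdetJ": detJ * rule.weights[None, :],
            }
        self.M = assemble_mass_matrix(mesh)
        self._M_lu = spla.splu(self.M.tocsc())

    def mass_solve(self, rhs: np.ndarray) -> np.ndarray:
        """Solve M x = rhs for each column of an (n, 3) right side."""
        return self._M_lu.solve(rhs)


def deformation_gradient(mesh: HexMesh, chi: np.ndarray,
                         rule: QuadratureRule | None = None,
                         ops: FemOperators | None = None,
                         key: str = "full") -> np.ndarray:
    """F = sum_l chi_l x grad(phi_l) at quadrature points -> (ne, nq, 3, 3).

    Raises :class:`InvertedElementError` listing inverted elements.
    """
    if ops is not None:
        gradN = ops.geo[key]["gradN"]
    else:
        rule = rule or full_rule()
        Xe = mesh.element_nodes()
        dN = shape_gradients(rule.points)
        Jm = np.einsum("eld,qlr->eqdr", Xe, dN)
        gradN = np.einsum("qlr,eqrd->eqld", dN, np.linalg.inv(Jm))
    xe = chi[mesh.elements]
    F = np.einsum("eld,eqlr->eqdr", xe, gradN)
    detF = np.linalg.det(F)
    if np.any(detF <= 0):
        bad = np.unique(np.argwhere(detF <= 0)[:, 0])
        raise InvertedElementError(
            f"inverted elements (det F <= 0): ids {bad.tolist()[:20]}"
            + ("..." if bad.size > 20 else ""))
    return F


def assemble_mass_matrix(mesh: HexMesh) -> sp.csr_matrix:
    """Consistent scalar FE mass matrix M_ml = int phi_m phi_l dX (full rule)."""
    rule = full_rule()
    N = shape_values(rule.points)                          # (nq, 8)
    dN = shape_gradients(rule.points)
    Xe = mesh.element_nodes()
    Jm = np.einsum("eld,qlr->eqdr", Xe, dN)
    wdetJ = np.linalg.det(Jm) * rule.weights[None, :]      # (ne, nq)
    Me = np.einsum("eq,qm,ql->eml", wdetJ, N, N)           # (ne, 8, 8)
    conn = mesh.elements
    rows = np.repeat(conn, 8, axis=1).ravel()
    cols = np.tile(conn, (1, 8)).ravel()
    M = sp.coo_matrix((Me.ravel(), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes))
    return M.tocsr()


def _modifier_coefficient(J: np.ndarray, params: MaterialParams, variant: str):
    """Scalar c(J) such that the pressure-like stress part is c(J) F^{-T}."""
    if variant == "raw":
        return None
    if variant == "pressure_normalized":
        return -params.a * J
    if variant == "penalized":
        return -params.a * J + params.beta_s * np.log(J)
    if variant == "penalized_no_ps":
        return params.beta_s * np.log(J)
    raise ValueError(f"unknown stress variant {variant!r}")


def element_stress_forces(mesh: HexMesh, ops: FemOperators, params: MaterialParams,
                          variant: str, xe: np.ndarray,
                          penalty_quadrature: str = "reduced") -> np.ndarray:
    """Per-element weak-form stress forces -int_e P : grad(phi) dX -> (ne, 8, 3).

    ``xe`` holds the deformed element node positions (ne, 8, 3).  Selective
    reduced integration: base stress at the full rule, pressure-like
    modification at the reduced rule.  ``penalty_quadrature="full"`` instead
    integrates the modification at the full rule (the volumetrically locked
    variant, kept for regression comparisons).
    """
    if mesh.fiber_f0 is None:
        raise ValueError("mesh has no fiber frame; call assign_fibers or use a fixture")
    _modifier_coefficient(np.ones(1), params, variant)   # validates variant

    geo = ops.geo["full"]
    F = np.einsum("eld,eqlr->eqdr", xe, geo["gradN"], optimize=True)
    detF = det3(F)
    if np.any(detF <= 0):
        bad = np.unique(np.argwhere(detF <= 0)[:, 0])
        raise InvertedElementError(f"inverted elements (det F <= 0): ids {bad.tolist()[:20]}")
    kin = compute_invariants(F, mesh.fiber_f0, mesh.fiber_s0)
    P = first_pk_stress(kin, params, variant="raw")
    if variant != "raw" and penalty_quadrature == "full":
        c = _modifier_coefficient(kin.J, params, variant)
        P = P + c[..., None, None] * np.swapaxes(inv3(F, kin.J), -1, -2)
        return -np.einsum("eq,eqdk,eqlk->eld", geo["wdetJ"], P, geo["gradN"],
                          optimize=True)
    with_ps = variant in ("pressure_normalized", "penalized")
    if with_ps:
        # constant part -a*I of the pressure normalization joins the full
        # rule so it cancels the isotropic reference residual of the base
        # stress exactly on any element geometry
        P = P - params.a * np.eye(3)
    re = -np.einsum("eq,eqdk,eqlk->eld", geo["wdetJ"], P, geo["gradN"],
                    optimize=True)

    if variant != "raw":
        # deformation-dependent pressure-like parts at the reduced rule;
        # each term is the gradient of a per-element energy, and all vanish
        # in the reference configuration
        geo_r = ops.geo["reduced"]
        Fr = np.einsum("eld,eqlr->eqdr", xe, geo_r["gradN"], optimize=True)
        Jr = det3(Fr)
        if np.any(Jr <= 0):
            raise InvertedElementError("inverted element at reduced quadrature point")
        c = _modifier_coefficient(Jr, params, variant)
        Pmod = c[..., None, None] * np.swapaxes(inv3(Fr, Jr), -1, -2)
        if with_ps:
            Pmod = Pmod + params.a * np.eye(3)
        re = re - np.einsum("eq,eqdk,eqlk->eld", geo_r["wdetJ"], Pmod,
                            geo_r["gradN"], optimize=True)
    return re


def _stress_rhs(mesh: HexMesh, chi: np.ndarray, params: MaterialParams,
                variant: str, ops: FemOperators) -> np.ndarray:
    """-int P : grad(phi) dX with selective reduced integration -> (n, 3)."""
    re = element_stress_forces(mesh, ops, params, variant, chi[mesh.elements])
    rhs = np.zeros((mesh.n_nodes, 3))
    np.add.at(rhs, mesh.elements.ravel(), re.reshape(-1, 3))
    return rhs


_Q2D = np.array([[-_G, -_G], [_G, -_G], [_G, _G], [-_G, _G]])


def _quad_shape(pts2d):
    xi, eta = pts2d[:, 0], pts2d[:, 1]
    s = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], float)
    N = (1 + s[None, :, 0] * xi[:, None]) * (1 + s[None, :, 1] * eta[:, None]) / 4.0
    dN = np.zeros((pts2d.shape[0], 4, 2))
    dN[:, :, 0] = s[None, :, 0] * (1 + s[None, :, 1] * eta[:, None]) / 4.0
    dN[:, :, 1] = (1 + s[None, :, 0] * xi[:, None]) * s[None, :, 1] / 4.0
    return N, dN


def _face_pressure_rhs(faces: np.ndarray, chi: np.ndarray, p: float,
                       n_nodes: int) -> np.ndarray:
    """Weak-form follower traction -p n da on deformed quad faces."""
    N, dN = _quad_shape(_Q2D)                      # (4g, 4l), (4g, 4l, 2)
    xq = chi[faces]                                # (nf, 4, 3)
    a1 = np.einsum("fld,gl->fgd", xq, dN[:, :, 0])
    a2 = np.einsum("fld,gl->fgd", xq, dN[:, :, 1])
    nvec = np.cross(a1, a2)                        # outward-oriented area vectors
    contrib = -p * np.einsum("gl,fgd->fld", N, nvec)
    rhs = np.zeros((n_nodes, 3))
    np.add.at(rhs, faces.ravel(), contrib.reshape(-1, 3))
    return rhs


def endocardial_pressure_force(mesh: HexMesh, chi: np.ndarray, p_endo: float,
                               face_set: str = "endocardium") -> np.ndarray:
    """Follower endocardial pressure load assembled into the weak form (n, 3).

    The traction is -p_endo n da over the *deformed* faces of ``face_set``
    with n the solid-outward normal, so the load follows the surface as it
    rotates and stretches.
    """
    if face_set not in mesh.face_sets:
        raise ValueError(f"mesh has no face set {face_set!r}")
    return _face_pressure_rhs(mesh.face_sets[face_set], chi, p_endo, mesh.n_nodes)


def surface_traction_force(mesh: HexMesh, traction: np.ndarray,
                           face_set: str) -> np.ndarray:
    """Dead (nominal, per reference area) uniform traction on a face set."""
    if face_set not in mesh.face_sets:
        raise ValueError(f"mesh has no face set {face_set!r}")
    faces = mesh.face_sets[face_set]
    N, dN = _quad_shape(_Q2D)
    Xq = mesh.nodes[faces]
    a1 = np.einsum("fld,gl->fgd", Xq, dN[:, :, 0])
    a2 = np.einsum("fld,gl->fgd", Xq, dN[:, :, 1])
    da = np.linalg.norm(np.cross(a1, a2), axis=-1)     # (nf, 4g)
    t = np.asarray(traction, float)
    contrib = np.einsum("gl,fg->fl", N, da)[..., None] * t[None, None, :]
    rhs = np.zeros((mesh.n_nodes, 3))
    np.add.at(rhs, faces.ravel(), contrib.reshape(-1, 3))
    return rhs


def basal_penalty_force(mesh: HexMesh, chi: np.ndarray,
                        kappa_bc: float) -> np.ndarray:
    """Nodal penalty force density opposing circumferential and longitudinal
    displacement of the basal plane; radial motion is left free.

    kappa_bc is the penalty stiffness (dyn/cm^4: force density per unit
    displacement).  Returns an (n, 3) array, nonzero only at basal nodes.
    """
    if "basal_plane" not in mesh.node_sets:
        raise ValueError("mesh has no basal_plane node set")
    out = np.zeros((mesh.n_nodes, 3))
    if kappa_bc == 0.0:
        return out
    ids = mesh.node_sets["basal_plane"]
    X = mesh.nodes[ids]
    Xc = X[:, :2] - X[:, :2].mean(axis=0)   # cylindrical basis about the LV axis
    rho = np.hypot(Xc[:, 0], Xc[:, 1])
    if np.any(rho < 1e-10):
        raise ValueError("basal node on the long axis: azimuthal direction undefined")
    e_r = np.zeros_like(X)
    e_r[:, 0] = Xc[:, 0] / rho
    e_r[:, 1] = Xc[:, 1] / rho
    e_t = np.zeros_like(X)
    e_t[:, 0] = -e_r[:, 1]
    e_t[:, 1] = e_r[:, 0]
    u = chi[ids] - X
    u_t = np.einsum("ni,ni->n", u, e_t)
    out[ids] = -kappa_bc * (u_t[:, None] * e_t)
    out[ids, 2] -= kappa_bc * u[:, 2]
    return out


def assemble_force_density(mesh: HexMesh, chi: np.ndarray, params: MaterialParams,
                           variant: str = "penalized", p_endo: float = 0.0,
                           kappa_bc: float = 0.0,
                           ops: FemOperators | None = None) -> np.ndarray:
    """Nodal elastic force density F_l (dyn/cm^3 per unit reference volume).

    Solves M F = -int P grad(phi) dX + follower endocardial pressure, with
    the base stress at the full 2x2x2 rule and the pressure-like p_s / beta_s
    contributions at the reduced single-point rule, then adds the basal
    penalty force density.
    """
    ops = ops or FemOperators(mesh)
    rhs = _stress_rhs(mesh, chi, params, variant, ops)
    if p_endo != 0.0:
        rhs = rhs + endocardial_pressure_force(mesh, chi, p_endo)
    F = ops.mass_solve(rhs)
    if kappa_bc != 0.0:
        F = F + basal_penalty_force(mesh, chi, kappa_bc)
    return F


def project_qp_to_nodes(mesh: HexMesh, values: np.ndarray,
                        ops: FemOperators | None = None) -> np.ndarray:
    """Lumped-mass L2 projection of a per-quadrature-point field (ne, nq[, k])
    (full rule) to the nodes."""
    ops = ops or FemOperators(mesh)
    geo = ops.geo["full"]
    w = geo["wdetJ"]                                   # (ne, nq)
    N = geo["N"]                                       # (nq, 8)
    vals = np.asarray(values, float)
    scalar = vals.ndim == 2
    if scalar:
        vals = vals[..., None]
    num = np.einsum("eq,ql,eqk->elk", w, N, vals)
    den = np.einsum("eq,ql->el", w, N)
    out = np.zeros((mesh.n_nodes, vals.shape[-1]))
    cnt = np.zeros(mesh.n_nodes)
    np.add.at(out, mesh.elements.ravel(), num.reshape(-1, vals.shape[-1]))
    np.add.at(cnt, mesh.elements.ravel(), den.ravel())
    out /= cnt[:, None]
    return out[:, 0] if scalar else out
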