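"""Synthetic hexahedral left-ventricle geometries, fixtures and mesh I/O.

The synthetic LV is a thick-walled truncated prolate ellipsoid: endocardial
and epicardial surfaces are coaxial ellipsoids of revolution (long axis +z,
base at the top, apex at the bottom), truncated by the flat basal plane
z = z_base.  The shell is meshed with a structured grid in (transmural,
circumferential, longitudinal) parameters; the apical pole is closed with a
structured square-patch cap so that every element is a non-degenerate
hexahedron.  Requires the circumferential resolution to be a multiple of 8
(the cap patch is an (n_c/4)^2 grid whose boundary ring coincides with the
last shell ring).

Node count = (n_t+1) * [ n_c*(n_l+1) + (n_c/4 - 1)^2 ],
element count = n_t * [ n_c*n_l + (n_c/4)^2 ].

Fiber architecture follows the rule-based (Potse-style) prescription: the
helix angle of the fiber axis f0 rotates linearly in the transmural
coordinate e from alpha_endo at the endocardium (e=0) to alpha_epi at the
epicardium (e=1), and the sheet axis s0 is tilted out of the wall-tangent
plane by a sheet angle interpolated likewise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LVGeometrySpec",
    "HexMesh",
    "generate_lv_mesh",
    "assign_fibers",
    "transmural_coordinate",
    "generate_fixture",
    "lv_node_count",
    "lv_element_count",
    "truncated_shell_volume",
    "write_vtu",
    "write_abaqus_inp",
    "save_mesh_text",
    "load_mesh_text",
]

# VTK_HEXAHEDRON local ordering: bottom quad CCW then top quad CCW.
_HEX_FACES = np.array([
    [0, 3, 2, 1],   # zeta = -1
    [4, 5, 6, 7],   # zeta = +1
    [0, 1, 5, 4],   # eta  = -1
    [2, 3, 7, 6],   # eta  = +1
    [0, 4, 7, 3],   # xi   = -1
    [1, 2, 6, 5],   # xi   = +1
])


@dataclass(frozen=True)
class LVGeometrySpec:
    """Truncated-ellipsoid LV geometry (all lengths in cm).

    r_endo/z_endo and r_epi/z_epi are the equatorial and long semi-axes of the
    endocardial and epicardial ellipsoids; z_base is the truncation height of
    the flat basal plane (measured from the common center).
    """

    r_endo: float = 2.5
    z_endo: float = 5.5
    r_epi: float = 3.6
    z_epi: float = 6.5
    z_base: float = 2.0
    n_transmural: int = 2
    n_circumferential: int = 16
    n_longitudinal: int = 8

    def __post_init__(self):
        if not (self.r_epi > self.r_endo and self.z_epi > self.z_endo):
            raise ValueError("epicardial semi-axes must exceed endocardial ones")
        if not (self.z_base < self.z_endo):
            raise ValueError("basal plane must truncate both surfaces (z_base < z_endo)")
        if self.n_transmural < 2 or self.n_circumferential < 8 or self.n_longitudinal < 4:
            raise ValueError("resolution too coarse: need n_t>=2, n_c>=8, n_l>=4")
        if self.n_circumferential % 8 != 0:
            raise ValueError("n_circumferential must be a multiple of 8 (apex cap patch)")


@dataclass
class HexMesh:
    """Unstructured 8-node hexahedral mesh with named sets and fiber frames.

    ``face_sets`` maps a name to an (n_faces, 4) array of node ids, oriented
    so the implied normal points out of the solid; ``face_elems`` gives the
    owning element of each face.  ``fiber_f0``/``fiber_s0``/``fiber_n0`` (if
    assigned) hold per-element per-quadrature-point orthonormal material
    frames for the full 2x2x2 rule, and ``transmural_nodal`` the wall-depth
    coordinate e in [0, 1] at the nodes.
    """

    nodes: np.ndarray                 # (n, 3) cm
    elements: np.ndarray              # (ne, 8) int
    node_sets: dict = field(default_factory=dict)
    face_sets: dict = field(default_factory=dict)
    face_elems: dict = field(default_factory=dict)
    transmural_nodal: np.ndarray | None = None
    fiber_f0: np.ndarray | None = None    # (ne, nq, 3)
    fiber_s0: np.ndarray | None = None
    fiber_n0: np.ndarray | None = None
    geometry: LVGeometrySpec | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_nodes(self, chi: np.ndarray | None = None) -> np.ndarray:
        """(ne, 8, 3) coordinates of element nodes (reference or deformed)."""
        x = self.nodes if chi is None else chi
        return x[self.elements]

    def translated(self, offset) -> "HexMesh":
        """Copy of the mesh with node coordinates shifted by ``offset``."""
        out = HexMesh(
            nodes=self.nodes + np.asarray(offset, float)[None, :],
            elements=self.elements,
            node_sets=self.node_sets,
            face_sets=self.face_sets,
            face_elems=self.face_elems,
            transmural_nodal=self.transmural_nodal,
            fiber_f0=self.fiber_f0, fiber_s0=self.fiber_s0, fiber_n0=self.fiber_n0,
            geometry=self.geometry,
        )
        return out


# ----------------------------------------------------------------------
# Structured LV generator
# ----------------------------------------------------------------------

def lv_node_count(spec: LVGeometrySpec) -> int:
    m = spec.n_circumferential // 4
    return (spec.n_transmural + 1) * (
        spec.n_circumferential * (spec.n_longitudinal + 1) + (m - 1) ** 2)


def lv_element_count(spec: LVGeometrySpec) -> int:
    m = spec.n_circumferential // 4
    return spec.n_transmural * (spec.n_circumferential * spec.n_longitudinal + m * m)


def _ellipsoid_point(r_ax, z_ax, phi, theta):
    """Point on an ellipsoid of revolution; phi measured from +z."""
    phi, theta = np.broadcast_arrays(np.asarray(phi, float), np.asarray(theta, float))
    sp = np.sin(phi)
    return np.stack([r_ax * sp * np.cos(theta),
                     r_ax * sp * np.sin(theta),
                     z_ax * np.cos(phi)], axis=-1)


def _cap_grid_param(m):
    """Map the (m+1)^2 cap patch nodes to polar (rho in [0,1], theta).

    Square rings (L-inf radius k) map to circles of radius k/(m/2); the
    position along each ring is proportional to the ring-perimeter step so
    that the boundary ring is exactly uniform in theta (matches the shell).
    """
    half = m // 2
    rho = np.zeros((m + 1, m + 1))
    theta = np.zeros((m + 1, m + 1))
    for i in range(m + 1):
        for j in range(m + 1):
            di, dj = i - half, j - half
            k = max(abs(di), abs(dj))
            if k == 0:
                continue
            # counterclockwise perimeter coordinate, start at (k, -k)
            if di == k and dj < k:
                s = dj + k
            elif dj == k:
                s = 2 * k + (k - di)
            elif di == -k:
                s = 4 * k + (k - dj)
            else:
                s = 6 * k + (di + k)
            rho[i, j] = k / half
            theta[i, j] = -np.pi / 4 + 2.0 * np.pi * s / (8.0 * k)
    return rho, theta


def generate_lv_mesh(spec: LVGeometrySpec) -> HexMesh:
    """Structured hex mesh of the truncated ellipsoidal shell with apex cap.

    Node/face sets: ``basal_plane`` (nodes with z = z_base),
    ``endocardium`` and ``epicardium`` (oriented quad face sets), plus the
    ``basal_ring_endo`` node set bounding the basal opening.
    """
    n_t, n_c, n_l = spec.n_transmural, spec.n_circumferential, spec.n_longitudinal
    m = n_c // 4
    if m % 2 != 0:
        raise ValueError("n_circumferential must be a multiple of 8")
    half = m // 2

    surf = {"endo": (spec.r_endo, spec.z_endo), "epi": (spec.r_epi, spec.z_epi)}
    phi_base = {s: np.arccos(np.clip(spec.z_base / z_ax, -1, 1))
                for s, (r_ax, z_ax) in surf.items()}
    # cap opening angle chosen so cap ring spacing continues the shell spacing
    phi_cap = {}
    for s in surf:
        fb = phi_base[s]
        phi_cap[s] = (np.pi + (half / n_l) * fb) / (1.0 + half / n_l)

    theta = -np.pi / 4 + 2.0 * np.pi * np.arange(n_c) / n_c

    # ---- shell nodes: id = ((k * n_c) + j) * (n_t+1) + i
    def shell_id(i, j, k):
        return (k * n_c + (j % n_c)) * (n_t + 1) + i

    n_shell = (n_t + 1) * n_c * (n_l + 1)
    nodes = np.zeros((lv_node_count(spec), 3))
    e_nodal = np.zeros(lv_node_count(spec))
    for k in range(n_l + 1):
        t = k / n_l
        phi_e = phi_base["endo"] + t * (phi_cap["endo"] - phi_base["endo"])
        phi_p = phi_base["epi"] + t * (phi_cap["epi"] - phi_base["epi"])
        p_endo = _ellipsoid_point(spec.r_endo, spec.z_endo, phi_e, theta)
        p_epi = _ellipsoid_point(spec.r_epi, spec.z_epi, phi_p, theta)
        for i in range(n_t + 1):
            e = i / n_t
            ids = shell_id(i, np.arange(n_c), k)
            nodes[ids] = (1 - e) * p_endo + e * p_epi
            e_nodal[ids] = e
    # basal plane is exact by construction at k=0
    nodes[shell_id(np.arange(n_t + 1)[:, None], np.arange(n_c)[None, :], 0).ravel(), 2] = spec.z_base

    # ---- cap nodes (interior of the square patch; boundary ring = shell k=n_l)
    rho_g, th_g = _cap_grid_param(m)
    cap_id = -np.ones((m + 1, m + 1, n_t + 1), dtype=int)
    next_id = n_shell
    for i in range(m + 1):
        for j in range(m + 1):
            k_ring = max(abs(i - half), abs(j - half))
            if k_ring == half:            # boundary: reuse shell node
                s = _boundary_step(i, j, half)
                for it in range(n_t + 1):
                    cap_id[i, j, it] = shell_id(it, s, n_l)
                continue
            for it in range(n_t + 1):
                cap_id[i, j, it] = next_id
                e = it / n_t
                pe = _cap_surface_point(spec.r_endo, spec.z_endo,
                                        phi_cap["endo"], rho_g[i, j], th_g[i, j])
                pp = _cap_surface_point(spec.r_epi, spec.z_epi,
                                        phi_cap["epi"], rho_g[i, j], th_g[i, j])
                nodes[next_id] = (1 - e) * pe + e * pp
                e_nodal[next_id] = e
                next_id += 1
    assert next_id == lv_node_count(spec)

    # ---- elements
    elems = []
    endo_faces, epi_faces, endo_own, epi_own = [], [], [], []
    for k in range(n_l):
        for j in range(n_c):
            for i in range(n_t):
                # bottom quad at transmural layer i (endo side), CCW seen from epi
                n000 = shell_id(i, j, k)
                n010 = shell_id(i, j + 1, k)
                n011 = shell_id(i, j + 1, k + 1)
                n001 = shell_id(i, j, k + 1)
                n100 = shell_id(i + 1, j, k)
                n110 = shell_id(i + 1, j + 1, k)
                n111 = shell_id(i + 1, j + 1, k + 1)
                n101 = shell_id(i + 1, j, k + 1)
                elems.append([n000, n010, n011, n001, n100, n110, n111, n101])
                if i == 0:
                    endo_faces.append([n000, n001, n011, n010])
                    endo_own.append(len(elems) - 1)
                if i == n_t - 1:
                    epi_faces.append([n100, n110, n111, n101])
                    epi_own.append(len(elems) - 1)
    for i in range(m):
        for j in range(m):
            for it in range(n_t):
                c = [cap_id[i, j, it], cap_id[i + 1, j, it],
                     cap_id[i + 1, j + 1, it], cap_id[i, j + 1, it],
                     cap_id[i, j, it + 1], cap_id[i + 1, j, it + 1],
                     cap_id[i + 1, j + 1, it + 1], cap_id[i, j + 1, it + 1]]
                elems.append(c)
                if it == 0:
                    endo_faces.append([c[0], c[3], c[2], c[1]])
                    endo_own.append(len(elems) - 1)
                if it == n_t - 1:
                    epi_faces.append([c[4], c[5], c[6], c[7]])
                    epi_own.append(len(elems) - 1)

    elements = np.asarray(elems, dtype=int)
    mesh = HexMesh(
        nodes=nodes, elements=elements,
        node_sets={
            "basal_plane": shell_id(np.arange(n_t + 1)[:, None],
                                    np.arange(n_c)[None, :], 0).ravel(),
            "basal_ring_endo": shell_id(0, np.arange(n_c), 0),
        },
        face_sets={"endocardium": np.asarray(endo_faces, int),
                   "epicardium": np.asarray(epi_faces, int)},
        face_elems={"endocardium": np.asarray(endo_own, int),
                    "epicardium": np.asarray(epi_own, int)},
        transmural_nodal=e_nodal,
        geometry=spec,
    )
    _fix_element_orientation(mesh)
    _orient_face_sets(mesh)
    _check_jacobians(mesh)
    return mesh


def _boundary_step(i, j, half):
    """Perimeter step index of boundary patch node (i, j) (ring k = half)."""
    di, dj = i - half, j - half
    k = half
    if di == k and dj < k:
        return dj + k
    if dj == k:
        return 2 * k + (k - di)
    if di == -k:
        return 4 * k + (k - dj)
    return 6 * k + (di + k)


def _cap_surface_point(r_ax, z_ax, phi_cap, rho, th):
    phi = np.pi - (np.pi - phi_cap) * rho
    return _ellipsoid_point(r_ax, z_ax, phi, th)


# ----------------------------------------------------------------------
# Jacobian checks / orientation
# ----------------------------------------------------------------------

_GAUSS_1D = np.array([-1.0, 1.0]) / np.sqrt(3.0)


def _ref_grad_shape(xi):
    """d N_l / d xi at reference points xi (nq, 3) -> (nq, 8, 3)."""
    sign = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                     [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], float)
    xi = np.atleast_2d(xi)
    nq = xi.shape[0]
    out = np.zeros((nq, 8, 3))
    for l in range(8):
        sx, sy, sz = sign[l]
        fx, fy, fz = (1 + sx * xi[:, 0]), (1 + sy * xi[:, 1]), (1 + sz * xi[:, 2])
        out[:, l, 0] = sx * fy * fz / 8.0
        out[:, l, 1] = fx * sy * fz / 8.0
        out[:, l, 2] = fx * fy * sz / 8.0
    return out


def element_jacobians(mesh: HexMesh, chi: np.ndarray | None = None) -> np.ndarray:
    """det(dX/dxi) at the 2x2x2 Gauss points -> (ne, 8)."""
    pts = np.array([[x, y, z] for z in _GAUSS_1D for y in _GAUSS_1D for x in _GAUSS_1D])
    dN = _ref_grad_shape(pts)                      # (8q, 8l, 3)
    Xe = mesh.element_nodes(chi)                   # (ne, 8, 3)
    Jm = np.einsum("eld,qlr->eqdr", Xe, dN)        # (ne, nq, 3, 3)
    return np.linalg.det(Jm)


def _fix_element_orientation(mesh: HexMesh):
    detJ = element_jacobians(mesh)
    bad = np.all(detJ < 0, axis=1)
    if np.any(bad):
        # swap bottom/top quads to flip orientation
        mesh.elements[bad] = mesh.elements[bad][:, [4, 5, 6, 7, 0, 1, 2, 3]]


def _check_jacobians(mesh: HexMesh):
    detJ = element_jacobians(mesh)
    if np.any(detJ <= 0):
        bad = np.unique(np.argwhere(detJ <= 0)[:, 0])
        raise ValueError(f"tangled elements (non-positive Jacobian): ids {bad.tolist()}")


def _orient_face_sets(mesh: HexMesh):
    """Ensure stored face quads have outward (solid-exterior) normals."""
    for name, faces in mesh.face_sets.items():
        own = mesh.face_elems[name]
        quad = mesh.nodes[faces]                     # (nf, 4, 3)
        c_face = quad.mean(axis=1)
        c_elem = mesh.nodes[mesh.elements[own]].mean(axis=1)
        n = np.cross(quad[:, 1] - quad[:, 0], quad[:, 3] - quad[:, 0])
        inward = np.einsum("fi,fi->f", n, c_face - c_elem) < 0
        faces[inward] = faces[inward][:, ::-1]


# ----------------------------------------------------------------------
# Transmural coordinate and fiber rule
# ----------------------------------------------------------------------

def transmural_coordinate(mesh: HexMesh, rule_points: np.ndarray | None = None) -> np.ndarray:
    """Per-quadrature-point transmural coordinate e in [0, 1].

    Interpolates the nodal wall-depth coordinate (0 on the endocardium, 1 on
    the epicardium, affine in the transmural mesh parameter) with the
    trilinear shape functions at the 2x2x2 Gauss points (or at the supplied
    reference points).  Raises if the mesh carries no transmural index.
    """
    if mesh.transmural_nodal is None:
        raise ValueError("mesh has no transmural index (unstructured input?)")
    if rule_points is None:
        rule_points = np.array([[x, y, z] for z in _GAUSS_1D
                                for y in _GAUSS_1D for x in _GAUSS_1D])
    N = _shape_values(rule_points)                  # (nq, 8)
    e_elem = mesh.transmural_nodal[mesh.elements]   # (ne, 8)
    return np.einsum("el,ql->eq", e_elem, N)


def _shape_values(xi):
    sign = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                     [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], float)
    xi = np.atleast_2d(xi)
    N = np.ones((xi.shape[0], 8))
    for d in range(3):
        N *= (1 + sign[None, :, d] * xi[:, None, d]) / 2.0
    return N


def assign_fibers(mesh: HexMesh, alpha_endo: float = -60.0, alpha_epi: float = 60.0,
                  beta_endo: float = -45.0, beta_epi: float = 45.0) -> HexMesh:
    """Rule-based fiber and sheet axes at the 2x2x2 quadrature points.

    The local wall basis at each point is: radial e_r = normalized gradient
    of the transmural coordinate (endo -> epi), circumferential e_c = the
    azimuthal direction orthogonalized against e_r, longitudinal
    e_l = e_r x e_c (apex -> base).  The fiber axis is rotated by the helix
    angle alpha(e) within the (e_c, e_l) plane and the sheet axis is tilted
    from the radial direction by the sheet angle beta(e); both angles are
    linear in e.  On the long axis (apex cap center) where the azimuth is
    singular, a fixed in-plane direction is substituted.
    """
    if mesh.transmural_nodal is None:
        raise ValueError("mesh has no transmural coordinate; generate_lv_mesh first")
    pts = np.array([[x, y, z] for z in _GAUSS_1D for y in _GAUSS_1D for x in _GAUSS_1D])
    N = _shape_values(pts)
    dN = _ref_grad_shape(pts)
    Xe = mesh.element_nodes()                       # (ne, 8, 3)
    Jm = np.einsum("eld,qlr->eqdr", Xe, dN)
    Jinv = np.linalg.inv(Jm)
    gradN = np.einsum("qlr,eqrd->eqld", dN, Jinv)   # (ne, nq, 8, 3)

    e_elem = mesh.transmural_nodal[mesh.elements]
    e_qp = np.einsum("el,ql->eq", e_elem, N)
    grad_e = np.einsum("el,eqld->eqd", e_elem, gradN)
    x_qp = np.einsum("eld,ql->eqd", Xe, N)

    e_r = _normalize(grad_e)
    # azimuthal direction about the mesh's own long axis
    x_qp = x_qp.copy()
    x_qp[..., :2] -= mesh.nodes[:, :2].mean(axis=0)
    rho = np.linalg.norm(x_qp[..., :2], axis=-1)
    e_c = np.zeros_like(x_qp)
    ok = rho > 1e-10
    e_c[ok, 0] = -x_qp[ok, 1] / rho[ok]
    e_c[ok, 1] = x_qp[ok, 0] / rho[ok]
    e_c[~ok] = np.array([1.0, 0.0, 0.0])            # apex axis fallback
    e_c = _normalize(e_c - np.einsum("...i,...i->...", e_c, e_r)[..., None] * e_r)
    e_l = np.cross(e_r, e_c)

    alpha = np.deg2rad(alpha_endo + (alpha_epi - alpha_endo) * e_qp)[..., None]
    beta = np.deg2rad(beta_endo + (beta_epi - beta_endo) * e_qp)[..., None]
    f0 = np.cos(alpha) * e_c + np.sin(alpha) * e_l
    s_plane = -np.sin(alpha) * e_c + np.cos(alpha) * e_l   # in-plane, normal to f0
    s0 = np.cos(beta) * e_r + np.sin(beta) * s_plane
    n0 = np.cross(f0, s0)

    mesh.fiber_f0, mesh.fiber_s0, mesh.fiber_n0 = f0, s0, n0
    return mesh


def _normalize(v):
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    n = np.where(n == 0, 1.0, n)
    return v / n


# ----------------------------------------------------------------------
# Analytic volumes
# ----------------------------------------------------------------------

def _ellipsoid_below(r_ax, z_ax, z0):
    """Volume of the ellipsoid region with z < z0."""
    c = np.clip(z0 / z_ax, -1.0, 1.0)
    return np.pi * r_ax ** 2 * z_ax * ((c - c ** 3 / 3.0) - (-1 + 1.0 / 3.0))


def truncated_shell_volume(spec: LVGeometrySpec) -> float:
    """Analytic wall volume of the truncated ellipsoidal shell (cm^3)."""
    return (_ellipsoid_below(spec.r_epi, spec.z_epi, spec.z_base)
            - _ellipsoid_below(spec.r_endo, spec.z_endo, spec.z_base))


def cavity_volume_analytic(spec: LVGeometrySpec) -> float:
    """Analytic volume of the (undeformed) truncated endocardial cavity."""
    return _ellipsoid_below(spec.r_endo, spec.z_endo, spec.z_base)


def mesh_volume(mesh: HexMesh, chi: np.ndarray | None = None) -> float:
    """Sum of element volumes by 2x2x2 Gaussian quadrature."""
    return float(np.sum(element_jacobians(mesh, chi)))


# ----------------------------------------------------------------------
# Fixtures
# ----------------------------------------------------------------------

def generate_fixture(kind: str, resolution: int = 2, **kw) -> HexMesh:
    """Analytic test fixtures: ``unit_cube``, ``slab`` or ``spherical_shell``.

    unit_cube: [0,1]^3 at resolution^3 elements, face sets xmin..zmax.
    slab: a 4 x 1 x 1 cm bar, (4r, r, r) elements, same face-set naming.
    spherical_shell: cubed-sphere shell, inner/outer radii ``r_inner``
    (default 1) and ``r_outer`` (default 1.5), ``resolution`` cells per cube
    edge and ``n_transmural`` layers (default 2); face sets ``inner`` and
    ``outer``.  Fibers default to a constant frame along x/y/z.
    """
    if kind == "unit_cube":
        mesh = _box_mesh((1.0, 1.0, 1.0), (resolution,) * 3)
    elif kind == "slab":
        mesh = _box_mesh((4.0, 1.0, 1.0), (4 * resolution, resolution, resolution))
    elif kind == "spherical_shell":
        mesh = _cubed_sphere_shell(kw.get("r_inner", 1.0), kw.get("r_outer", 1.5),
                                   resolution, kw.get("n_transmural", 2))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    nq = 8
    ne = mesh.n_elements
    mesh.fiber_f0 = np.tile(np.array([1.0, 0, 0]), (ne, nq, 1))
    mesh.fiber_s0 = np.tile(np.array([0, 1.0, 0]), (ne, nq, 1))
    mesh.fiber_n0 = np.tile(np.array([0, 0, 1.0]), (ne, nq, 1))
    _check_jacobians(mesh)
    return mesh


def _box_mesh(size, shape):
    lx, ly, lz = size
    nx, ny, nz = shape
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    elems = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                elems.append([nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k),
                              nid(i, j + 1, k), nid(i, j, k + 1), nid(i + 1, j, k + 1),
                              nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)])
    elements = np.asarray(elems, int)
    mesh = HexMesh(nodes=nodes, elements=elements)

    tol = 1e-12
    sets = {"xmin": nodes[:, 0] < tol, "xmax": nodes[:, 0] > lx - tol,
            "ymin": nodes[:, 1] < tol, "ymax": nodes[:, 1] > ly - tol,
            "zmin": nodes[:, 2] < tol, "zmax": nodes[:, 2] > lz - tol}
    mesh.node_sets = {k: np.where(v)[0] for k, v in sets.items()}
    for name, mask in sets.items():
        faces, own = _extract_boundary_faces(mesh, mask)
        mesh.face_sets[name] = faces
        mesh.face_elems[name] = own
    _fix_element_orientation(mesh)
    _orient_face_sets(mesh)
    return mesh


def _extract_boundary_faces(mesh, node_mask):
    faces, own = [], []
    for e, conn in enumerate(mesh.elements):
        for lf in _HEX_FACES:
            quad = conn[lf]
            if node_mask[quad].all():
                faces.append(quad)
                own.append(e)
    return np.asarray(faces, int).reshape(-1, 4), np.asarray(own, int)


def _cubed_sphere_shell(r_in, r_out, n_surf, n_t):
    """Cubed-sphere hexahedral shell between radii r_in and r_out."""
    panels = []
    # each panel: (fixed axis, sign)
    for ax in range(3):
        for sgn in (-1, 1):
            panels.append((ax, sgn))
    raw_nodes = []
    panel_grids = []
    u = np.linspace(-1, 1, n_surf + 1)
    for ax, sgn in panels:
        A, B = np.meshgrid(u, u, indexing="ij")
        pts = np.zeros((n_surf + 1, n_surf + 1, 3))
        other = [d for d in range(3) if d != ax]
        pts[..., ax] = sgn
        pts[..., other[0]] = A
        pts[..., other[1]] = B
        pts = pts / np.linalg.norm(pts, axis=-1, keepdims=True)
        panel_grids.append(pts)
        raw_nodes.append(pts.reshape(-1, 3))
    all_dirs = np.concatenate(raw_nodes, axis=0)
    # merge duplicate directions along panel seams
    key = np.round(all_dirs, 9)
    _, uniq_idx, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    dirs = all_dirs[uniq_idx]
    n_dir = dirs.shape[0]

    radii = np.linspace(r_in, r_out, n_t + 1)
    nodes = (dirs[None, :, :] * radii[:, None, None]).reshape(-1, 3)

    def nid(layer, d):
        return layer * n_dir + d

    elems, inner_faces, outer_faces, inner_own, outer_own = [], [], [], [], []
    offset = 0
    for p, (ax, sgn) in enumerate(panels):
        idx = inv[offset:offset + (n_surf + 1) ** 2].reshape(n_surf + 1, n_surf + 1)
        offset += (n_surf + 1) ** 2
        for i in range(n_surf):
            for j in range(n_surf):
                q = [idx[i, j], idx[i + 1, j], idx[i + 1, j + 1], idx[i, j + 1]]
                for it in range(n_t):
                    c = [nid(it, q[0]), nid(it, q[1]), nid(it, q[2]), nid(it, q[3]),
                         nid(it + 1, q[0]), nid(it + 1, q[1]), nid(it + 1, q[2]),
                         nid(it + 1, q[3])]
                    elems.append(c)
                    if it == 0:
                        inner_faces.append(c[:4][::-1])
                        inner_own.append(len(elems) - 1)
                    if it == n_t - 1:
                        outer_faces.append(c[4:])
                        outer_own.append(len(elems) - 1)
    mesh = HexMesh(nodes=nodes, elements=np.asarray(elems, int),
                   face_sets={"inner": np.asarray(inner_faces, int),
                              "outer": np.asarray(outer_faces, int)},
                   face_elems={"inner": np.asarray(inner_own, int),
                               "outer": np.asarray(outer_own, int)})
    mesh.node_sets = {"inner": np.unique(mesh.face_sets["inner"]),
                      "outer": np.unique(mesh.face_sets["outer"])}
    _fix_element_orientation(mesh)
    _orient_face_sets(mesh)
    return mesh


# ----------------------------------------------------------------------
# I/O: plain-text store, VTK XML, Abaqus
# ----------------------------------------------------------------------

def save_mesh_text(mesh: HexMesh, directory):
    """Plain-text mesh store: nodes.txt, elements.txt, sets.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "nodes.txt", mesh.nodes, header="x y z (cm)")
    np.savetxt(d / "elements.txt", mesh.elements, fmt="%d",
               header="8-node hex connectivity (0-based)")
    sets = {"node_sets": {k: v.tolist() for k, v in mesh.node_sets.items()},
            "face_sets": {k: v.tolist() for k, v in mesh.face_sets.items()},
            "face_elems": {k: v.tolist() for k, v in mesh.face_elems.items()}}
    if mesh.transmural_nodal is not None:
        sets["transmural_nodal"] = mesh.transmural_nodal.tolist()
    (d / "sets.json").write_text(json.dumps(sets))


def load_mesh_text(directory) -> HexMesh:
    d = Path(directory)
    nodes = np.loadtxt(d / "nodes.txt").reshape(-1, 3)
    elements = np.loadtxt(d / "elements.txt", dtype=int).reshape(-1, 8)
    sets = json.loads((d / "sets.json").read_text())
    mesh = HexMesh(
        nodes=nodes, elements=elements,
        node_sets={k: np.asarray(v, int) for k, v in sets["node_sets"].items()},
        face_sets={k: np.asarray(v, int).reshape(-1, 4)
                   for k, v in sets["face_sets"].items()},
        face_elems={k: np.asarray(v, int) for k, v in sets["face_elems"].items()},
    )
    if "transmural_nodal" in sets:
        mesh.transmural_nodal = np.asarray(sets["transmural_nodal"], float)
    return mesh


def write_vtu(mesh: HexMesh, path, chi: np.ndarray | None = None,
              point_data: dict | None = None, cell_data: dict | None = None):
    """ASCII VTK XML unstructured-grid writer (hexahedra only)."""
    x = mesh.nodes if chi is None else chi
    ne = mesh.n_elements

    def arr2txt(a):
        return " ".join(f"{v:.9g}" for v in np.asarray(a, float).ravel())

    lines = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
             '<UnstructuredGrid>',
             f'<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{ne}">',
             '<Points>',
             '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
             arr2txt(x), '</DataArray>', '</Points>', '<Cells>',
             '<DataArray type="Int64" Name="connectivity" format="ascii">',
             " ".join(map(str, mesh.elements.ravel())), '</DataArray>',
             '<DataArray type="Int64" Name="offsets" format="ascii">',
             " ".join(str(8 * (i + 1)) for i in range(ne)), '</DataArray>',
             '<DataArray type="UInt8" Name="types" format="ascii">',
             " ".join(["12"] * ne), '</DataArray>', '</Cells>']
    lines.append('<PointData>')
    for name, data in (point_data or {}).items():
        data = np.asarray(data, float)
        nc = 1 if data.ndim == 1 else data.shape[1]
        lines += [f'<DataArray type="Float64" Name="{name}" '
                  f'NumberOfComponents="{nc}" format="ascii">', arr2txt(data),
                  '</DataArray>']
    lines.append('</PointData>')
    lines.append('<CellData>')
    for name, data in (cell_data or {}).items():
        data = np.asarray(data, float)
        nc = 1 if data.ndim == 1 else data.shape[1]
        lines += [f'<DataArray type="Float64" Name="{name}" '
                  f'NumberOfComponents="{nc}" format="ascii">', arr2txt(data),
                  '</DataArray>']
    lines.append('</CellData>')
    lines += ['</Piece>', '</UnstructuredGrid>', '</VTKFile>']
    Path(path).write_text("\n".join(lines))


def write_abaqus_inp(mesh: HexMesh, path, name: str = "LV"):
    """Abaqus input-deck export: nodes, C3D8 connectivity and node sets."""
    out = [f"*HEADING\n{name} hexahedral mesh", "*NODE"]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        out.append(f"{i}, {x:.9g}, {y:.9g}, {z:.9g}")
    out.append("*ELEMENT, TYPE=C3D8")
    for e, conn in enumerate(mesh.elements, start=1):
        out.append(f"{e}, " + ", ".join(str(c + 1) for c in conn))
    for sname, ids in mesh.node_sets.items():
        out.append(f"*NSET, NSET={sname.upper()}")
        ids1 = [str(i + 1) for i in np.asarray(ids).ravel()]
        for i in range(0, len(ids1), 10):
            out.append(", ".join(ids1[i:i + 10]))
    Path(path).write_text("\n".join(out) + "\n")
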