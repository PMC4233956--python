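"""Derived quantities and model-vs-model comparison.

Fields of interest follow standard cardiac-mechanics reporting: logarithmic
fiber strain ln(lambda_f) = 1/2 ln I4f, fiber Cauchy stress sigma_ff,
Green-Lagrange strain components in the local circumferential/radial/
longitudinal basis, endocardial cavity volume (divergence theorem with a
flat basal cap), the normalized end-diastolic pressure-volume relation
EDV_n = (EDV - V0)/(V30 - V0), transmural path sampling, and difference
reports between a coupled IB/FE solution and the static FE reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fem import FemOperators, project_qp_to_nodes, shape_values
from .mesh import HexMesh, LVGeometrySpec, _ellipsoid_point

__all__ = [
    "log_fiber_strain", "LocalCardiacBasis", "green_lagrange_local",
    "cavity_volume", "edpvr_normalize", "TransmuralPath", "sample_transmural",
    "default_transmural_paths", "compare_models",
]


def log_fiber_strain(F: np.ndarray, f0: np.ndarray) -> np.ndarray:
    """ln(lambda_f) = 1/2 ln(I4f), the true strain along the fiber."""
    Ff = np.einsum("...ij,...j->...i", np.asarray(F, float), np.asarray(f0, float))
    I4f = np.einsum("...i,...i->...", Ff, Ff)
    if np.any(I4f <= 0):
        raise ValueError("non-positive I4f: degenerate fiber stretch")
    return 0.5 * np.log(I4f)


@dataclass
class LocalCardiacBasis:
    """Orthonormal circumferential/radial/longitudinal directions."""

    e_c: np.ndarray
    e_r: np.ndarray
    e_l: np.ndarray

    def __post_init__(self):
        Q = np.stack([self.e_c, self.e_r, self.e_l], axis=-2)
        if not np.allclose(np.einsum("...ik,...jk->...ij", Q, Q),
                           np.broadcast_to(np.eye(3), Q.shape), atol=1e-10):
            raise ValueError("local cardiac basis is not orthonormal")


def green_lagrange_local(F: np.ndarray, basis: LocalCardiacBasis) -> dict:
    """Green-Lagrange strain E = (F^T F - I)/2 in the local cardiac basis.

    Returns the six components E_cc, E_rr, E_ll, E_cr, E_cl, E_lr.
    """
    F = np.asarray(F, float)
    C = np.einsum("...ki,...kj->...ij", F, F)
    E = 0.5 * (C - np.eye(3))

    def proj(u, v):
        return np.einsum("...i,...ij,...j->...", u, E, v)

    c, r, l = basis.e_c, basis.e_r, basis.e_l
    return {"E_cc": proj(c, c), "E_rr": proj(r, r), "E_ll": proj(l, l),
            "E_cr": proj(c, r), "E_cl": proj(c, l), "E_lr": proj(l, r)}


def cavity_volume(mesh: HexMesh, chi: np.ndarray | None = None) -> float:
    """Volume (ml) enclosed by the deformed endocardial surface closed with
    a flat triangulated cap across the basal opening (divergence theorem)."""
    if "endocardium" not in mesh.face_sets:
        raise ValueError("mesh has no endocardium face set")
    if "basal_ring_endo" not in mesh.node_sets:
        raise ValueError("mesh has no basal_ring_endo node set")
    x = mesh.nodes if chi is None else chi
    tris = []
    # stored endocardial quads are solid-outward (pointing into the cavity);
    # reverse them so the closed cavity surface is consistently outward
    quads = x[mesh.face_sets["endocardium"]][:, ::-1]
    tris.append(quads[:, [0, 1, 2]])
    tris.append(quads[:, [0, 2, 3]])
    ring = x[mesh.node_sets["basal_ring_endo"]]
    centroid = ring.mean(axis=0)
    nr = ring.shape[0]
    cap = np.empty((nr, 3, 3))
    for i in range(nr):
        cap[i, 0] = centroid
        cap[i, 1] = ring[i]
        cap[i, 2] = ring[(i + 1) % nr]
    # cap must face upward (outward at the basal opening)
    nz = np.cross(cap[:, 1] - cap[:, 0], cap[:, 2] - cap[:, 0])[:, 2].sum()
    if nz < 0:
        cap = cap[:, ::-1]
    tris.append(cap)
    T = np.concatenate(tris, axis=0)
    v6 = np.einsum("ti,ti->t", T[:, 0], np.cross(T[:, 1], T[:, 2]))
    vol = v6.sum() / 6.0
    if vol <= 0:
        raise ValueError("non-positive cavity volume: inconsistent surface")
    return float(vol)


def edpvr_normalize(pressures, volumes, V0: float, V30: float):
    """Normalized EDPVR: EDV_n = (V - V0) / (V30 - V0)."""
    if not V30 > V0:
        raise ValueError("V30 must exceed V0")
    volumes = np.asarray(volumes, float)
    return pd.DataFrame({"pressure": np.asarray(pressures, float),
                         "edv_n": (volumes - V0) / (V30 - V0)})


@dataclass
class TransmuralPath:
    """Straight sampling segment from an endocardial to an epicardial point."""

    start: np.ndarray
    end: np.ndarray
    n_samples: int = 11

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("need at least two samples")
        self.start = np.asarray(self.start, float)
        self.end = np.asarray(self.end, float)

    @property
    def arc(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_samples)

    def points(self) -> np.ndarray:
        s = self.arc[:, None]
        return (1 - s) * self.start[None, :] + s * self.end[None, :]


def _invert_trilinear(Xe: np.ndarray, x: np.ndarray, tol=1e-9, maxit=50):
    """Damped Newton inversion of the trilinear map of one element; returns
    the reference coordinates xi or None if the point lies outside."""
    from .fem import shape_gradients
    scale = float(np.linalg.norm(Xe.max(axis=0) - Xe.min(axis=0))) + 1e-30
    xi = np.zeros(3)
    converged = False
    for _ in range(maxit):
        N = shape_values(xi[None, :])[0]
        r = N @ Xe - x
        if np.linalg.norm(r) < tol * scale:
            converged = True
            break
        dN = shape_gradients(xi[None, :])[0]
        Jm = Xe.T @ dN
        try:
            step = np.linalg.solve(Jm, r)
        except np.linalg.LinAlgError:
            return None
        nrm = np.linalg.norm(step)
        if nrm > 1.0:                      # damp large excursions
            step *= 1.0 / nrm
        xi = np.clip(xi - step, -1.5, 1.5)
    if converged and np.all(np.abs(xi) <= 1.0 + 1e-6):
        return xi
    return None


def sample_transmural(mesh: HexMesh, nodal_field: np.ndarray,
                      path: TransmuralPath,
                      chi: np.ndarray | None = None) -> pd.DataFrame:
    """Shape-function interpolation of a nodal field along a path.

    The path is defined in the configuration whose coordinates ``chi`` uses
    (reference coordinates by default).  Raises if a sample point exits the
    mesh.
    """
    x = mesh.nodes if chi is None else chi
    Xe_all = x[mesh.elements]
    lo = Xe_all.min(axis=1)
    hi = Xe_all.max(axis=1)
    pts = path.points()
    out = np.empty(pts.shape[0])
    pad = 1e-9 + 1e-6 * float(np.max(hi - lo))
    for k, xp in enumerate(pts):
        cands = np.where(np.all((xp >= lo - pad) & (xp <= hi + pad), axis=1))[0]
        found = False
        for e in cands:
            xi = _invert_trilinear(Xe_all[e], xp)
            if xi is not None:
                N = shape_values(xi[None, :])[0]
                out[k] = N @ nodal_field[mesh.elements[e]]
                found = True
                break
        if not found:
            raise ValueError(f"path sample {k} at {xp} exits the mesh")
    return pd.DataFrame({"arc": path.arc, "value": out})


def default_transmural_paths(mesh: HexMesh, n_paths: int = 7,
                             n_samples: int = 11) -> list[TransmuralPath]:
    """Transmural paths across the free wall of the synthetic LV.

    Paths follow transmural node columns (exactly straight by construction)
    at one azimuth, at ``n_paths`` evenly spaced longitudinal stations
    between base and apex region.
    """
    spec = mesh.geometry
    if spec is None:
        raise ValueError("mesh carries no LV geometry spec")
    n_t, n_c, n_l = spec.n_transmural, spec.n_circumferential, spec.n_longitudinal

    def shell_id(i, j, k):
        return (k * n_c + (j % n_c)) * (n_t + 1) + i

    paths = []
    for t in np.linspace(1.0, n_l - 1.0, n_paths):
        k = min(int(np.floor(t)), n_l - 1)
        w = t - k
        a = ((1 - w) * mesh.nodes[shell_id(0, 0, k)]
             + w * mesh.nodes[shell_id(0, 0, k + 1)])
        b = ((1 - w) * mesh.nodes[shell_id(n_t, 0, k)]
             + w * mesh.nodes[shell_id(n_t, 0, k + 1)])
        paths.append(TransmuralPath(start=a, end=b, n_samples=n_samples))
    return paths


def compare_models(disp_a: np.ndarray, disp_b: np.ndarray, mesh: HexMesh,
                   fields_a: dict | None = None, fields_b: dict | None = None,
                   paths: list[TransmuralPath] | None = None,
                   ops: FemOperators | None = None) -> dict:
    """Difference report between two solutions on the same mesh.

    ``disp_*`` are nodal displacements (cm); ``fields_*`` map field names
    (e.g. 'log_lambda_f', 'sigma_ff') to per-quadrature-point arrays
    (ne, nq) on the full rule, compared after nodal projection along the
    transmural paths; model b is the reference for relative differences
    (denominator: per-path mean absolute reference value).
    """
    if disp_a.shape != disp_b.shape or disp_a.shape[0] != mesh.n_nodes:
        raise ValueError("solutions are not defined on the same mesh")
    d = np.linalg.norm(disp_a - disp_b, axis=1)
    mag_a = np.linalg.norm(disp_a, axis=1)
    mag_b = np.linalg.norm(disp_b, axis=1)
    report = {
        "disp_diff_mean": float(d.mean()),
        "disp_diff_sd": float(d.std()),
        "disp_diff_max": float(d.max()),
        "max_disp_a": float(mag_a.max()),
        "max_disp_b": float(mag_b.max()),
        "max_disp_rel_diff": float(abs(mag_a.max() - mag_b.max())
                                   / max(mag_b.max(), 1e-30)),
    }
    if fields_a and paths:
        ops = ops or FemOperators(mesh)
        for name in fields_a:
            na = project_qp_to_nodes(mesh, fields_a[name], ops)
            nb = project_qp_to_nodes(mesh, fields_b[name], ops)
            means, rels = [], []
            for p in paths:
                va = sample_transmural(mesh, na, p)["value"].to_numpy()
                vb = sample_transmural(mesh, nb, p)["value"].to_numpy()
                means.append(np.mean(np.abs(va - vb)))
                ref = np.mean(np.abs(vb))
                rels.append(means[-1] / max(ref, 1e-30))
            report[f"{name}_path_mean_abs_diff"] = float(np.mean(means))
            report[f"{name}_path_mean_rel_diff"] = float(np.mean(rels))
    return report
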