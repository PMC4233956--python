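"""Lagrangian-Eulerian coupling: regularized delta kernel, adaptive
interaction quadrature, force spreading and adjoint velocity restriction.

The spreading operator S maps the Lagrangian force density F to a staggered
Eulerian force density,

    f_d(x_face) = sum_q F_d(X_q) delta_h(x_face - chi(X_q)) w_q ,

with delta_h the tensor-product four-point Peskin kernel and (X_q, w_q) a
dynamically generated Gauss rule dense enough to place at least two points
per Cartesian mesh width along every edge of every deformed element.  The
velocity restriction evaluates U^IB(X_q) = sum_faces u delta_h(...) h^3 at
the same points (making S and the evaluation exact adjoints under the
quadrature inner product) and then L2-projects U^IB onto the trilinear FE
space through the consistent mass matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .fem import FemOperators, shape_gradients, shape_values
from .mesh import HexMesh

__all__ = [
    "delta4", "InteractionQuadrature", "build_quadrature",
    "spread", "interpolate", "interpolate_and_project",
]

#: reference-edge node pairs along each reference direction of the hex
_EDGES = (
    ((0, 1), (3, 2), (4, 5), (7, 6)),     # xi
    ((0, 3), (1, 2), (4, 7), (5, 6)),     # eta
    ((0, 4), (1, 5), (2, 6), (3, 7)),     # zeta
)

#: staggering offsets (in h) of each velocity component's face lattice
_OFFSETS = ((0.0, 0.5, 0.5), (0.5, 0.0, 0.5), (0.5, 0.5, 0.0))


def delta4(r):
    """One-dimensional four-point regularized delta kernel phi(r).

    phi has support |r| < 2, phi(0) = 1/2, and satisfies the discrete
    partition of unity sum_i phi(r - i) = 1 for every real r.
    """
    r = np.abs(np.asarray(r, dtype=float))
    out = np.zeros_like(r)
    m1 = r <= 1.0
    out[m1] = (3.0 - 2.0 * r[m1] + np.sqrt(1.0 + 4.0 * r[m1] - 4.0 * r[m1] ** 2)) / 8.0
    m2 = (r > 1.0) & (r < 2.0)
    out[m2] = (5.0 - 2.0 * r[m2] - np.sqrt(-7.0 + 12.0 * r[m2] - 4.0 * r[m2] ** 2)) / 8.0
    return out if out.ndim else float(out)


@dataclass
class InteractionQuadrature:
    """Flattened interaction points for one structural configuration."""

    points: np.ndarray       # (Q, 3) physical positions chi(X_q)
    weights: np.ndarray      # (Q,) reference-measure weights w_q
    elem: np.ndarray         # (Q,) owning element id
    shape: np.ndarray        # (Q, 8) trilinear shape values at X_q
    ref_coords: np.ndarray   # (Q, 3)
    _eval_mat: object = None       # csr (Q, n): nodal -> quadrature values
    _scatter_mat: object = None    # csr (n, Q): weighted adjoint scatter

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def _matrices(self, mesh: HexMesh):
        import scipy.sparse as sp
        if self._eval_mat is None:
            Q = self.n_points
            rows = np.repeat(np.arange(Q), 8)
            cols = mesh.elements[self.elem].ravel()
            vals = self.shape.ravel()
            self._eval_mat = sp.csr_matrix((vals, (rows, cols)),
                                           shape=(Q, mesh.n_nodes))
            self._scatter_mat = self._eval_mat.T.multiply(
                self.weights[None, :]).tocsr()
        return self._eval_mat, self._scatter_mat

    def evaluate_nodal(self, mesh: HexMesh, nodal: np.ndarray) -> np.ndarray:
        """Interpolate a nodal field to the quadrature points -> (Q, k)."""
        E, _ = self._matrices(mesh)
        return E @ nodal


_LEGGAUSS: dict = {}


def _leggauss(n: int):
    if n not in _LEGGAUSS:
        _LEGGAUSS[n] = np.polynomial.legendre.leggauss(n)
    return _LEGGAUSS[n]


class QuadratureFactory:
    """Builds interaction quadratures, reusing the order-dependent structure.

    The Gauss orders depend on the deformed edge lengths and therefore can
    change between configurations, but the reference-measure weights, shape
    values and scatter matrices depend only on the orders; they are cached
    and reused while the orders are unchanged, so a rebuild normally costs a
    single interpolation of the physical point positions.
    """

    def __init__(self, mesh: HexMesh, min_order: int = 2, max_order: int = 8):
        self.mesh = mesh
        self.min_order = min_order
        self.max_order = max_order
        self._sig = None
        self._cached = None

    def build(self, chi: np.ndarray, h: float) -> InteractionQuadrature:
        mesh = self.mesh
        if not np.all(np.isfinite(chi)):
            raise ValueError("non-finite structure coordinates")
        xe = chi[mesh.elements]
        ne = xe.shape[0]
        orders = np.empty((ne, 3), dtype=int)
        for d in range(3):
            lmax = np.zeros(ne)
            for (n0, n1) in _EDGES[d]:
                lmax = np.maximum(lmax, np.linalg.norm(
                    xe[:, n1] - xe[:, n0], axis=1))
            orders[:, d] = np.clip(np.ceil(2.0 * lmax / h).astype(int),
                                   self.min_order, self.max_order)
        sig = (orders.tobytes(), float(h))
        if sig != self._sig:
            self._cached = _build_structure(mesh, orders)
            self._sig = sig
        q = self._cached
        pts = np.empty((q.n_points, 3))
        start = 0
        for (elems, N, nq) in q._groups:
            np.einsum("eld,ql->eqd", chi[mesh.elements[elems]], N,
                      out=pts[start:start + elems.size * nq].reshape(
                          elems.size, nq, 3), optimize=True)
            start += elems.size * nq
        return InteractionQuadrature(
            points=pts, weights=q.weights, elem=q.elem, shape=q.shape,
            ref_coords=q.ref_coords, _eval_mat=q._eval_mat,
            _scatter_mat=q._scatter_mat)


def _build_structure(mesh: HexMesh, orders: np.ndarray) -> InteractionQuadrature:
    Xe = mesh.element_nodes()
    ne = orders.shape[0]
    w_list, el_list, N_list, xi_list, groups = [], [], [], [], []
    uniq: dict = {}
    for e in range(ne):
        uniq.setdefault(tuple(orders[e]), []).append(e)
    for key, elems in uniq.items():
        elems = np.asarray(elems)
        gp, gw = zip(*(_leggauss(n) for n in key))
        XI, ETA, ZETA = np.meshgrid(gp[0], gp[1], gp[2], indexing="ij")
        xi = np.stack([XI.ravel(), ETA.ravel(), ZETA.ravel()], axis=1)
        wt = (gw[0][:, None, None] * gw[1][None, :, None]
              * gw[2][None, None, :]).ravel()
        N = shape_values(xi)
        dN = shape_gradients(xi)
        Jm = np.einsum("eld,qlr->eqdr", Xe[elems], dN, optimize=True)
        from .constitutive import det3
        detJ = det3(Jm)
        nq = xi.shape[0]
        w_list.append((detJ * wt[None, :]).ravel())
        el_list.append(np.repeat(elems, nq))
        N_list.append(np.tile(N, (elems.size, 1)))
        xi_list.append(np.tile(xi, (elems.size, 1)))
        groups.append((elems, N, nq))
    quad = InteractionQuadrature(
        points=np.empty((sum(w.size for w in w_list), 3)),
        weights=np.concatenate(w_list),
        elem=np.concatenate(el_list),
        shape=np.concatenate(N_list),
        ref_coords=np.concatenate(xi_list),
    )
    quad._groups = groups
    quad._matrices(mesh)
    return quad


def build_quadrature(mesh: HexMesh, chi: np.ndarray, h: float,
                     min_order: int = 2, max_order: int = 8) -> InteractionQuadrature:
    """Per-element Gauss rules satisfying the two-points-per-mesh-width rule.

    The order along each reference direction is ceil(2 * L / h) with L the
    longest deformed edge in that direction, floored at ``min_order`` and
    capped at ``max_order``.  Raises on degenerate (inverted) elements.
    """
    xe = chi[mesh.elements]
    from .constitutive import det3
    Jc = np.einsum("eld,qlr->eqdr", xe,
                   shape_gradients(np.zeros((1, 3))), optimize=True)
    if np.any(det3(Jc) <= 0):
        raise ValueError("degenerate (inverted) element in deformed configuration")
    return QuadratureFactory(mesh, min_order, max_order).build(chi, h)


# ----------------------------------------------------------------------
# numba kernels
# ----------------------------------------------------------------------

@njit(inline="always", cache=True)
def _phi4(r):
    a = abs(r)
    if a <= 1.0:
        return (3.0 - 2.0 * a + np.sqrt(1.0 + 4.0 * a - 4.0 * a * a)) / 8.0
    if a < 2.0:
        return (5.0 - 2.0 * a - np.sqrt(-7.0 + 12.0 * a - 4.0 * a * a)) / 8.0
    return 0.0


@njit(cache=True)
def _stencil_weights(pts, h, ox, oy, oz, idx, wgt):
    """Base indices (Q, 3) and 1-D kernel weights (Q, 3, 4) for one
    staggered component's face lattice."""
    off = (ox, oy, oz)
    for q in range(pts.shape[0]):
        for d in range(3):
            a = pts[q, d] / h - off[d]
            i0 = int(np.floor(a)) - 1
            idx[q, d] = i0
            for k in range(4):
                wgt[q, d, k] = _phi4(a - (i0 + k))


@njit(cache=True)
def _scatter(idx, wgt, vals, w, arr, h):
    inv_h3 = 1.0 / (h * h * h)
    for q in range(idx.shape[0]):
        i0, j0, k0 = idx[q, 0], idx[q, 1], idx[q, 2]
        g = vals[q] * w[q] * inv_h3
        for a in range(4):
            wa = g * wgt[q, 0, a]
            for b in range(4):
                wb = wa * wgt[q, 1, b]
                for c in range(4):
                    arr[i0 + a, j0 + b, k0 + c] += wb * wgt[q, 2, c]


@njit(cache=True)
def _gather(idx, wgt, arr, out):
    for q in range(idx.shape[0]):
        i0, j0, k0 = idx[q, 0], idx[q, 1], idx[q, 2]
        acc = 0.0
        for a in range(4):
            wa = wgt[q, 0, a]
            for b in range(4):
                wb = wa * wgt[q, 1, b]
                for c in range(4):
                    acc += arr[i0 + a, j0 + b, k0 + c] * wb * wgt[q, 2, c]
        out[q] = acc


def _check_margin(points: np.ndarray, h: float, domain: float):
    if not np.all(np.isfinite(points)):
        raise ValueError("non-finite interaction point positions "
                         "(diverged structure state)")
    lo = float(points.min())
    hi = float(points.max())
    if lo < 2.0 * h or hi > domain - 2.0 * h:
        raise ValueError(
            f"structure within 2h of the domain boundary (extent [{lo:.3f}, "
            f"{hi:.3f}] cm vs margin {2 * h:.3f} cm): the interaction kernel "
            "would be truncated")


def _stencils(quad: InteractionQuadrature, h: float, domain: float):
    """Cached kernel stencils (base indices and 1-D weights) per component."""
    key = (h, domain)
    cache = getattr(quad, "_stencil_cache", None)
    if cache is None or cache[0] != key:
        _check_margin(quad.points, h, domain)
        per_comp = []
        Q = quad.n_points
        for d in range(3):
            idx = np.empty((Q, 3), dtype=np.int64)
            wgt = np.empty((Q, 3, 4))
            _stencil_weights(quad.points, h, *_OFFSETS[d], idx, wgt)
            per_comp.append((idx, wgt))
        cache = (key, per_comp)
        quad._stencil_cache = cache
    return cache[1]


def spread(F_nodal: np.ndarray, quad: InteractionQuadrature, mesh: HexMesh,
           N: int, domain: float = 15.0):
    """Spread a nodal Lagrangian force density to the staggered grid.

    Returns the face-centered Eulerian force density (f1, f2, f3)
    (dyn/cm^3).  Raises if any interaction point lies within 2h of the
    domain boundary.
    """
    h = domain / N
    stencils = _stencils(quad, h, domain)
    Fq = quad.evaluate_nodal(mesh, F_nodal)             # (Q, 3)
    shapes = [(N + 1, N, N), (N, N + 1, N), (N, N, N + 1)]
    out = []
    for d in range(3):
        arr = np.zeros(shapes[d])
        idx, wgt = stencils[d]
        _scatter(idx, wgt, np.ascontiguousarray(Fq[:, d]), quad.weights,
                 arr, h)
        out.append(arr)
    return tuple(out)


def interpolate(u, quad: InteractionQuadrature, domain: float = 15.0) -> np.ndarray:
    """Kernel interpolation U^IB(X_q) of a staggered velocity -> (Q, 3)."""
    N = u[1].shape[0]
    h = domain / N
    stencils = _stencils(quad, h, domain)
    out = np.empty((quad.n_points, 3))
    tmp = np.empty(quad.n_points)
    for d in range(3):
        idx, wgt = stencils[d]
        _gather(idx, wgt, np.ascontiguousarray(u[d]), tmp)
        out[:, d] = tmp
    return out


def interpolate_and_project(u, quad: InteractionQuadrature, mesh: HexMesh,
                            ops: FemOperators, domain: float = 15.0) -> np.ndarray:
    """Nodal structure velocity: L2 projection of U^IB onto the FE space.

    Solves M U = int phi_m U^IB dX with the interaction quadrature on the
    right side and the consistent FE mass matrix on the left.
    """
    Uib = interpolate(u, quad, domain)
    _, S = quad._matrices(mesh)
    rhs = S @ Uib
    return ops.mass_solve(rhs)
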