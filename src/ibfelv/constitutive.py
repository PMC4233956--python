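"""Holzapfel-Ogden orthotropic constitutive law for passive myocardium.

The strain energy is built from the isotropic invariant I1 and the
structure-based invariants I4f, I4s (squared fiber / sheet stretches) and
I8fs (fiber-sheet shear coupling):

    W = a/(2b) exp[b(I1 - 3)]
      + sum_{i=f,s} a_i/(2 b_i) {exp[b_i (I4i* - 1)^2] - 1}
      + a_fs/(2 b_fs) {exp[b_fs I8fs^2] - 1}

with I4i* = max(I4i, 1), so the fiber and sheet families carry load only in
extension, never in compression.

Three stress variants are provided on top of the raw first Piola-Kirchhoff
stress P = dW/dF:

* ``raw``                 -- P itself.
* ``pressure_normalized`` -- P - a J F^{-T}, derived from the shifted energy
  W - a log J.  This removes the isotropic residual a*I at F = I, so the
  stress vanishes identically in the reference configuration; on an immersed
  interface it eliminates the leading pressure discontinuity.
* ``penalized``           -- the pressure-normalized stress plus a volumetric
  penalty beta_s log(J) F^{-T} (from U_vol = beta_s/2 (log J)^2) that imposes
  incompressibility approximately in Lagrangian form.
* ``penalized_no_ps``     -- raw stress plus the volumetric penalty only
  (pressure normalization off, penalty on).

All functions are vectorized over leading batch dimensions: F may have shape
(..., 3, 3) and f0, s0 shape (..., 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .units import kpa

__all__ = [
    "det3",
    "inv3",
    "MaterialParams",
    "Kinematics",
    "StressVariant",
    "VARIANTS",
    "compute_invariants",
    "strain_energy",
    "first_pk_stress",
    "cauchy_stress",
    "fiber_stress",
    "InvertedElementError",
]

#: maximum admissible argument of the material exponentials; larger values
#: are clamped (with a warning) instead of silently overflowing to inf.
EXP_CLAMP = 50.0

VARIANTS = ("raw", "pressure_normalized", "penalized", "penalized_no_ps")
StressVariant = str


class InvertedElementError(ValueError):
    """Raised when a deformation state has non-positive Jacobian det(F)."""


def det3(A: np.ndarray) -> np.ndarray:
    """Explicit determinant of stacked 3x3 matrices (fast path)."""
    return (A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
            - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
            + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]))


def inv3(A: np.ndarray, det: np.ndarray | None = None) -> np.ndarray:
    """Explicit inverse of stacked 3x3 matrices via the adjugate."""
    d = det3(A) if det is None else det
    out = np.empty_like(A)
    out[..., 0, 0] = A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1]
    out[..., 0, 1] = A[..., 0, 2] * A[..., 2, 1] - A[..., 0, 1] * A[..., 2, 2]
    out[..., 0, 2] = A[..., 0, 1] * A[..., 1, 2] - A[..., 0, 2] * A[..., 1, 1]
    out[..., 1, 0] = A[..., 1, 2] * A[..., 2, 0] - A[..., 1, 0] * A[..., 2, 2]
    out[..., 1, 1] = A[..., 0, 0] * A[..., 2, 2] - A[..., 0, 2] * A[..., 2, 0]
    out[..., 1, 2] = A[..., 0, 2] * A[..., 1, 0] - A[..., 0, 0] * A[..., 1, 2]
    out[..., 2, 0] = A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]
    out[..., 2, 1] = A[..., 0, 1] * A[..., 2, 0] - A[..., 0, 0] * A[..., 2, 1]
    out[..., 2, 2] = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    return out / d[..., None, None]


def _matvec(A: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Broadcasting 3x3 matrix-vector product (BLAS matmul path)."""
    return (A @ v[..., None])[..., 0]


@dataclass(frozen=True)
class MaterialParams:
    """Eight Holzapfel-Ogden constants plus the volumetric penalty modulus.

    Moduli (a, a_f, a_s, a_fs, beta_s) are stored in dyn/cm^2; the b's are
    dimensionless exponents.  Use :meth:`from_kpa` for values quoted in kPa.
    """

    a: float
    b: float
    a_f: float
    b_f: float
    a_s: float
    b_s: float
    a_fs: float
    b_fs: float
    beta_s: float = 0.0

    def __post_init__(self):
        for name in ("a", "b", "a_f", "b_f", "a_s", "b_s", "a_fs", "b_fs"):
            if getattr(self, name) < 0:
                raise ValueError(f"material parameter {name} must be non-negative")
        if self.beta_s < 0:
            raise ValueError("beta_s must be non-negative")

    @classmethod
    def from_kpa(cls, a, b, a_f, b_f, a_s, b_s, a_fs, b_fs, beta_s=0.0):
        """Build from moduli in kPa (beta_s is given directly in dyn/cm^2)."""
        return cls(kpa(a), b, kpa(a_f), b_f, kpa(a_s), b_s, kpa(a_fs), b_fs, beta_s)

    @classmethod
    def healthy_human(cls, beta_s: float = 5.0e6) -> "MaterialParams":
        """Default parameter set fitted to simple-shear data of porcine
        myocardium, with the standard volumetric penalty beta_s in dyn/cm^2."""
        return cls.from_kpa(
            a=0.2362, b=10.81,
            a_f=20.037, b_f=14.154,
            a_s=3.7245, b_s=5.1645,
            a_fs=0.4108, b_fs=11.3,
            beta_s=beta_s,
        )


@dataclass
class Kinematics:
    """Pointwise deformation state: F, its invariants and material axes."""

    F: np.ndarray          # (..., 3, 3)
    J: np.ndarray          # (...)
    C: np.ndarray          # (..., 3, 3)
    I1: np.ndarray
    I4f: np.ndarray
    I4s: np.ndarray
    I8fs: np.ndarray
    f0: np.ndarray         # (..., 3)
    s0: np.ndarray


def _check_units(f0, s0):
    nf = np.linalg.norm(f0, axis=-1)
    ns = np.linalg.norm(s0, axis=-1)
    if not (np.allclose(nf, 1.0, atol=1e-8) and np.allclose(ns, 1.0, atol=1e-8)):
        raise ValueError("f0 and s0 must be unit vectors")


def compute_invariants(F: np.ndarray, f0: np.ndarray, s0: np.ndarray) -> Kinematics:
    """Kinematic invariants I1 = tr C, I4f = f0.C.f0, I4s = s0.C.s0,
    I8fs = f0.C.s0 and J = det F, with C = F^T F.

    Raises :class:`InvertedElementError` if any det(F) <= 0.
    """
    F = np.asarray(F, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    _check_units(f0, s0)
    J = det3(F)
    if np.any(J <= 0):
        bad = np.argwhere(np.atleast_1d(J) <= 0)
        raise InvertedElementError(
            f"non-positive det(F) at {bad.shape[0]} state(s); first index {bad[0]}, "
            f"min J = {np.min(J):.3e}"
        )
    C = np.swapaxes(F, -1, -2) @ F
    I1 = np.trace(C, axis1=-2, axis2=-1)
    Ff, Fs = _matvec(F, f0), _matvec(F, s0)
    Cf = _matvec(C, f0)
    Cs = _matvec(C, s0)
    I4f = np.sum(f0 * Cf, axis=-1)
    I4s = np.sum(s0 * Cs, axis=-1)
    I8fs = np.sum(f0 * Cs, axis=-1)
    return Kinematics(F=F, J=J, C=C, I1=I1, I4f=I4f, I4s=I4s, I8fs=I8fs, f0=f0, s0=s0)


def _safe_exp(x, label):
    x = np.asarray(x)
    if np.any(x > EXP_CLAMP):
        warnings.warn(
            f"exponent argument for {label} reached {float(np.max(x)):.3g}; "
            f"clamped at {EXP_CLAMP}", RuntimeWarning, stacklevel=3,
        )
        x = np.minimum(x, EXP_CLAMP)
    return np.exp(x)


def strain_energy(kin: Kinematics, params: MaterialParams,
                  variant: StressVariant = "raw") -> np.ndarray:
    """Strain-energy density (dyn/cm^2) of the requested stress variant.

    ``raw`` is the Holzapfel-Ogden energy W; ``pressure_normalized``
    subtracts a (J - 1), whose stress a J F^{-T} is the push-forward of a
    constant Cauchy pressure a (to first order near J = 1 this matches the
    a log J shift of the analytic derivation); the penalized variants add
    the volumetric penalty beta_s/2 (log J)^2.
    """
    p = params
    W = (p.a / (2 * p.b)) * _safe_exp(p.b * (kin.I1 - 3.0), "I1 term")
    for a_i, b_i, I4 in ((p.a_f, p.b_f, kin.I4f), (p.a_s, p.b_s, kin.I4s)):
        e = np.maximum(I4, 1.0) - 1.0          # tension only
        W = W + (a_i / (2 * b_i)) * (_safe_exp(b_i * e * e, "I4 term") - 1.0)
    W = W + (p.a_fs / (2 * p.b_fs)) * (
        _safe_exp(p.b_fs * kin.I8fs ** 2, "I8fs term") - 1.0)

    if variant == "raw":
        return W
    logJ = np.log(kin.J)
    if variant == "pressure_normalized":
        return W - p.a * (kin.J - 1.0)
    if variant == "penalized":
        return W - p.a * (kin.J - 1.0) + 0.5 * p.beta_s * logJ ** 2
    if variant == "penalized_no_ps":
        return W + 0.5 * p.beta_s * logJ ** 2
    raise ValueError(f"unknown stress variant {variant!r}; expected one of {VARIANTS}")


def first_pk_stress(kin: Kinematics, params: MaterialParams,
                    variant: StressVariant = "penalized") -> np.ndarray:
    """First Piola-Kirchhoff stress P = dW/dF of the requested variant.

    The pressure-like modifications subtract a J F^{-T} (pressure
    normalization p_s) and/or add beta_s log(J) F^{-T} (volumetric penalty).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown stress variant {variant!r}; expected one of {VARIANTS}")
    p = params
    F, f0, s0 = kin.F, kin.f0, kin.s0

    dW1 = 0.5 * p.a * _safe_exp(p.b * (kin.I1 - 3.0), "I1 term")   # dW/dI1
    P = 2.0 * dW1[..., None, None] * F

    for a_i, b_i, I4, v in ((p.a_f, p.b_f, kin.I4f, f0), (p.a_s, p.b_s, kin.I4s, s0)):
        e = np.maximum(I4, 1.0) - 1.0
        coef = a_i * e * _safe_exp(b_i * e * e, "I4 term")          # dW/dI4
        Fv = _matvec(F, v)
        P = P + 2.0 * coef[..., None, None] * Fv[..., :, None] * v[..., None, :]

    coef8 = p.a_fs * kin.I8fs * _safe_exp(p.b_fs * kin.I8fs ** 2, "I8fs term")
    Ff = _matvec(F, f0)
    Fs = _matvec(F, s0)
    P = P + coef8[..., None, None] * (Ff[..., :, None] * s0[..., None, :]
                                + Fs[..., :, None] * f0[..., None, :])

    if variant == "raw":
        return P
    Finv_T = np.swapaxes(inv3(F, kin.J), -1, -2)
    if variant == "pressure_normalized":
        return P - p.a * kin.J[..., None, None] * Finv_T
    logJ = np.log(kin.J)[..., None, None]
    if variant == "penalized":
        return (P - p.a * kin.J[..., None, None] * Finv_T
                + p.beta_s * logJ * Finv_T)
    # penalized_no_ps
    return P + p.beta_s * logJ * Finv_T


def cauchy_stress(P: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Cauchy stress sigma = J^{-1} P F^T."""
    F = np.asarray(F, dtype=float)
    J = det3(F)
    if np.any(J <= 0):
        raise InvertedElementError(f"non-positive det(F): min J = {np.min(J):.3e}")
    return (P @ np.swapaxes(F, -1, -2)) / J[..., None, None]


def fiber_stress(sigma: np.ndarray, F: np.ndarray, f0: np.ndarray) -> np.ndarray:
    """Fiber Cauchy stress sigma_ff = fhat . sigma . fhat with
    fhat = F f0 / |F f0| the deformed (pushed-forward) fiber direction."""
    Ff = _matvec(np.asarray(F, float), np.asarray(f0, float))
    n = np.linalg.norm(Ff, axis=-1)
    if np.any(n == 0):
        raise ValueError("degenerate deformed fiber direction |F f0| = 0")
    fhat = Ff / n[..., None]
    return np.einsum("...i,...ij,...j->...", fhat, sigma, fhat)
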