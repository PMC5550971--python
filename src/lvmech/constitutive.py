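"""Passive myocardial constitutive law and stress projections.

The passive response of the myocardium is modelled with the invariant-based
Holzapfel--Ogden strain-energy function

    Psi = a/(2b) [exp(b (I1bar - 3)) - 1]
        + sum_{i in {f,s}} a_i/(2 b_i) [exp(b_i (I4i - 1)^2) - 1]   (I4i > 1 only)
        + a_fs/(2 b_fs) [exp(b_fs I8^2) - 1]

where ``I1bar = J^{-2/3} tr(C)`` is the isochoric first invariant,
``I4f = f0.C f0`` and ``I4s = s0.C s0`` are squared stretches along the
initial fibre and sheet directions, and ``I8 = f0.C s0`` couples the two.
Myofibres and sheets only bear load when taut, so the anisotropic
exponential terms are switched off under compression (I4 <= 1).

Scar tissue is stiffer than functional myocardium.  An infarct-extent
scalar ``M`` in [0, 1] (1 inside the scar, 0 in remote muscle, linear over
a transition band) scales the whole elastic energy by ``1 + 49 M`` so that
fully infarcted tissue is exactly 50-fold stiffer at any deformation.

Near-incompressibility is enforced through a volumetric penalty
``U(J) = beta_s (ln J)^2`` whose Cauchy contribution is
``(beta_s / J) ln(J^2) I`` with bulk modulus ``beta_s = 100 kPa``.

All functions broadcast over leading axes: ``F`` may be ``(..., 3, 3)``,
``f0``/``s0`` ``(..., 3)`` and ``M`` scalar or ``(...)``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "PassiveParams",
    "Deformation",
    "BETA_S_KPA",
    "INFARCT_STIFFENING",
    "passive_energy",
    "passive_cauchy_stress",
    "fiber_stress",
    "active_cauchy_stress",
    "normalize_by_sbp",
]

BETA_S_KPA: float = 100.0  # bulk modulus beta_s = 1.0e5 Pa
INFARCT_STIFFENING: float = 50.0  # scar-to-remote stiffness fold change

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class PassiveParams:
    """The eight Holzapfel--Ogden coefficients.

    ``a``-type parameters are stress-like (kPa); ``b``-type parameters are
    dimensionless exponents.  All must be strictly positive.
    """

    a: float
    b: float
    a_f: float
    b_f: float
    a_s: float
    b_s: float
    a_fs: float
    b_fs: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"PassiveParams.{f.name} must be strictly positive, got {v!r}")

    def scaled(self, stiffness_scale: float = 1.0, fiber_scale: float = 1.0) -> "PassiveParams":
        """Return a copy with all stress-like coefficients multiplied by
        ``stiffness_scale`` and the fibre pair (a_f, b_f) additionally
        multiplied by ``fiber_scale``."""
        d = asdict(self)
        for k in ("a", "a_f", "a_s", "a_fs"):
            d[k] *= stiffness_scale
        d["a_f"] *= fiber_scale
        d["b_f"] *= fiber_scale
        return PassiveParams(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PassiveParams":
        return cls(**{f.name: float(d[f.name]) for f in fields(cls)})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PassiveParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def healthy(cls) -> "PassiveParams":
        """Cohort-average parameters of the healthy control group."""
        return cls.from_yaml(_DATA_DIR / "healthy.yaml")

    @classmethod
    def mi_remote(cls) -> "PassiveParams":
        """Cohort-average parameters of remote myocardium in MI subjects."""
        return cls.from_yaml(_DATA_DIR / "mi_remote.yaml")


@dataclass
class Deformation:
    """A deformation state: gradient ``F`` plus initial fibre/sheet axes.

    ``f0`` and ``s0`` must be unit length and mutually orthogonal (checked
    to a loose tolerance); ``det F`` must be positive.
    """

    F: np.ndarray
    f0: np.ndarray
    s0: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        if self.F.shape[-2:] != (3, 3):
            raise ValueError("F must have shape (..., 3, 3)")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("non-finite deformation gradient")
        if np.any(np.linalg.det(self.F) <= 0):
            raise ValueError("det(F) must be positive")
        for name, v in (("f0", self.f0), ("s0", self.s0)):
            n = np.linalg.norm(v, axis=-1)
            if not np.allclose(n, 1.0, atol=1e-6):
                raise ValueError(f"{name} must be a unit vector")
        if not np.allclose(np.sum(self.f0 * self.s0, axis=-1), 0.0, atol=1e-6):
            raise ValueError("f0 and s0 must be orthogonal")


def _invariants(F, f0, s0):
    """Return J, I1bar, I4f, I4s, I8 and the push-forwards f = F f0, s = F s0."""
    J = np.linalg.det(F)
    C = np.swapaxes(F, -1, -2) @ F
    I1 = np.trace(C, axis1=-2, axis2=-1)
    I1bar = J ** (-2.0 / 3.0) * I1
    f = np.einsum("...ij,...j->...i", F, f0)
    s = np.einsum("...ij,...j->...i", F, s0)
    I4f = np.sum(f * f, axis=-1)
    I4s = np.sum(s * s, axis=-1)
    I8 = np.sum(f * s, axis=-1)
    return J, I1bar, I4f, I4s, I8, f, s


def _check_deform(F):
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite deformation gradient")
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("det(F) must be positive")
    return F, J


def elastic_energy(params: PassiveParams, F, f0, s0, M=0.0):
    """Holzapfel--Ogden elastic energy density (kPa), scaled by 1 + 49 M.

    Excludes the volumetric penalty; see :func:`passive_energy` for the
    full stored energy.  Tension-only switches apply to the fibre and
    sheet terms.
    """
    F, _ = _check_deform(F)
    _, I1bar, I4f, I4s, I8, _, _ = _invariants(F, np.asarray(f0, float), np.asarray(s0, float))
    p = params
    e4f = np.where(I4f > 1.0, I4f - 1.0, 0.0)
    e4s = np.where(I4s > 1.0, I4s - 1.0, 0.0)
    psi = (
        p.a / (2 * p.b) * np.expm1(p.b * (I1bar - 3.0))
        + p.a_f / (2 * p.b_f) * np.expm1(p.b_f * e4f**2)
        + p.a_s / (2 * p.b_s) * np.expm1(p.b_s * e4s**2)
        + p.a_fs / (2 * p.b_fs) * np.expm1(p.b_fs * I8**2)
    )
    return (1.0 + (INFARCT_STIFFENING - 1.0) * np.asarray(M)) * psi


def volumetric_energy(F):
    """Penalty energy density ``beta_s (ln J)^2`` (kPa)."""
    _, J = _check_deform(F)
    return BETA_S_KPA * np.log(J) ** 2


def passive_energy(params: PassiveParams, deform: Deformation, M=0.0, include_penalty: bool = True):
    """Total passive stored-energy density (kPa) at a deformation state.

    The elastic part is multiplied by ``1 + 49 M`` (infarct stiffening);
    the volumetric penalty, a numerical incompressibility device, is not.
    """
    w = elastic_energy(params, deform.F, deform.f0, deform.s0, M)
    if include_penalty:
        w = w + volumetric_energy(deform.F)
    return w


def passive_cauchy_stress(params: PassiveParams, deform: Deformation, M=0.0):
    """Passive Cauchy stress tensor (kPa), symmetric, shape ``(..., 3, 3)``.

    Analytic derivative of :func:`passive_energy` pushed forward to the
    current configuration:

        sigma = (1/J) dPsi/dF F^T + (beta_s/J) ln(J^2) I
    """
    F, J = _check_deform(np.asarray(deform.F, float))
    f0 = np.asarray(deform.f0, float)
    s0 = np.asarray(deform.s0, float)
    J, I1bar, I4f, I4s, I8, f, s = _invariants(F, f0, s0)
    p = params
    scale = 1.0 + (INFARCT_STIFFENING - 1.0) * np.asarray(M)

    def _bc(x):
        # broadcast a (...,) scalar field against (..., 3, 3) tensors
        return np.asarray(x, float)[..., None, None]

    B = F @ np.swapaxes(F, -1, -2)
    eye = np.broadcast_to(np.eye(3), B.shape)
    devB = B - _bc(np.trace(B, axis1=-2, axis2=-1)) / 3.0 * eye
    Jm = _bc(J)

    psi1 = p.a * np.exp(p.b * (I1bar - 3.0))  # 2 * dPsi/dI1bar
    sig = _bc(psi1 * J ** (-2.0 / 3.0)) * devB / Jm

    e4f = np.where(I4f > 1.0, I4f - 1.0, 0.0)
    w4f = 2.0 * p.a_f * e4f * np.exp(p.b_f * e4f**2)
    sig = sig + _bc(w4f) * _outer(f, f) / Jm

    e4s = np.where(I4s > 1.0, I4s - 1.0, 0.0)
    w4s = 2.0 * p.a_s * e4s * np.exp(p.b_s * e4s**2)
    sig = sig + _bc(w4s) * _outer(s, s) / Jm

    w8 = p.a_fs * I8 * np.exp(p.b_fs * I8**2)
    sig = sig + _bc(w8) * (_outer(f, s) + _outer(s, f)) / Jm

    sig = _bc(scale) * sig
    sig = sig + _bc((BETA_S_KPA / J) * np.log(J**2)) * eye
    return sig


def _outer(u, v):
    return u[..., :, None] * v[..., None, :]


def active_cauchy_stress(T_a, deform: Deformation):
    """Active Cauchy stress: rank-one tensor ``T_a fhat (x) fhat`` (kPa).

    ``fhat`` is the unit fibre direction in the current configuration.
    """
    F, _ = _check_deform(np.asarray(deform.F, float))
    f = np.einsum("...ij,...j->...i", F, np.asarray(deform.f0, float))
    lam = np.linalg.norm(f, axis=-1)
    if np.any(lam < 1e-12):
        raise ValueError("degenerate deformed fibre direction")
    fhat = f / lam[..., None]
    T_a = np.asarray(T_a, float)
    return T_a[..., None, None] * _outer(fhat, fhat) if np.ndim(T_a) else T_a * _outer(fhat, fhat)


def fiber_stress(sigma, deform: Deformation):
    """Project a Cauchy stress onto the current fibre direction (kPa):
    ``sigma_f = fhat . sigma . fhat``."""
    sigma = np.asarray(sigma, float)
    F, _ = _check_deform(np.asarray(deform.F, float))
    f = np.einsum("...ij,...j->...i", F, np.asarray(deform.f0, float))
    lam = np.linalg.norm(f, axis=-1)
    if np.any(lam < 1e-12):
        raise ValueError("degenerate deformed fibre direction")
    fhat = f / lam[..., None]
    return np.einsum("...i,...ij,...j->...", fhat, sigma, fhat)


def normalize_by_sbp(x, sbp_mmhg):
    """Normalize a stress or tension (kPa) by systolic blood pressure (mmHg).

    Returns the ratio in kPa per mmHg, the reporting unit for the
    normalized biomarkers.
    """
    sbp = np.asarray(sbp_mmhg, float)
    if np.any(sbp <= 0):
        raise ValueError("SBP must be positive")
    return np.asarray(x, float) / sbp
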