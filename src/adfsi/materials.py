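"""Hyperelastic constitutive models for the intimal flap.

Two strain-energy functions are supported, both in MPa:

* a third-order Ogden model in deviatoric principal stretches,

  .. math::

     \\psi = \\sum_{p=1}^{3} \\frac{\\mu_p}{\\alpha_p}
         (\\bar\\lambda_1^{\\alpha_p} + \\bar\\lambda_2^{\\alpha_p}
          + \\bar\\lambda_3^{\\alpha_p} - 3),

  with the silicone-rubber (Shore 20A) constants used for the flap, and

* a nearly incompressible neo-Hookean model,

  .. math::

     \\psi = \\frac{\\mu}{2}(\\bar I_1 - 3) + \\frac{1}{d}(J - 1)^2 .

Strictly incompressible behaviour is recovered as ``d -> 0`` (the volumetric
term is then dropped).  Both models are augmented with the same
``(1/d)(J-1)^2`` penalty so that the displacement-based solid solver has a
well-defined volumetric response at Poisson ratio 0.49.

The module works in MPa / mm; the solvers convert to Pa at their boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OgdenParams",
    "NeoHookeanParams",
    "ElasticConstants",
    "StrainState",
    "DEFAULT_OGDEN",
    "neo_hookean_from_elastic",
    "elastic_from_neo_hookean",
    "ogden_energy",
    "neo_hookean_energy",
    "uniaxial_nominal_stress",
    "small_strain_shear_modulus",
    "energy_density_plane_strain",
    "pk1_plane_strain",
    "ensure_volumetric",
    "elastic_from_neo_hookean",
    "DEFAULT_POISSON",
]

_INCOMPRESSIBLE_NU_TOL = 1e-9


@dataclass(frozen=True)
class OgdenParams:
    """Third-order Ogden constants ``(mu_p, alpha_p)`` in MPa.

    ``volumetric_d`` (1/MPa) controls the near-incompressibility penalty
    ``(1/d)(J-1)^2``; ``volumetric_d == 0`` selects the strictly
    incompressible evaluation path (no volumetric term).
    """

    mu: tuple[float, float, float]
    alpha: tuple[float, float, float]
    volumetric_d: float = 0.0

    def __post_init__(self) -> None:
        if len(self.mu) != 3 or len(self.alpha) != 3:
            raise ValueError("Ogden model requires exactly three (mu, alpha) pairs")
        if self.volumetric_d < 0:
            raise ValueError("volumetric_d must be >= 0")
        mu0 = 0.5 * sum(m * a for m, a in zip(self.mu, self.alpha))
        if mu0 <= 0:
            raise ValueError(
                f"small-strain shear modulus 0.5*sum(mu_p*alpha_p) = {mu0:g} "
                "must be positive"
            )


@dataclass(frozen=True)
class NeoHookeanParams:
    """Neo-Hookean initial shear modulus ``mu`` (MPa) and incompressibility
    parameter ``d`` (1/MPa); ``d == 0`` means strictly incompressible."""

    mu: float
    d: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.d < 0:
            raise ValueError("d must be >= 0")


@dataclass(frozen=True)
class ElasticConstants:
    """Small-strain Young's modulus E (MPa) and Poisson ratio nu."""

    E: float
    nu: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not (0.0 <= self.nu <= 0.5 + _INCOMPRESSIBLE_NU_TOL):
            raise ValueError(f"nu = {self.nu} outside [0, 0.5]")


@dataclass(frozen=True)
class StrainState:
    """Principal stretches with derived volume ratio and deviatoric invariant."""

    principal_stretches: tuple[float, float, float]
    J: float = field(default=0.0)
    I1_bar: float = field(default=0.0)

    def __post_init__(self) -> None:
        lam = self.principal_stretches
        if any(l <= 0 for l in lam):
            raise ValueError("principal stretches must be positive")
        J = lam[0] * lam[1] * lam[2]
        if self.J == 0.0:
            object.__setattr__(self, "J", J)
        elif abs(self.J - J) > 1e-9 * J:
            raise ValueError("J inconsistent with principal stretches")
        if self.J <= 0:
            raise ValueError("J must be positive")
        I1b = sum(l * l for l in lam) * self.J ** (-2.0 / 3.0)
        if self.I1_bar == 0.0:
            object.__setattr__(self, "I1_bar", I1b)


#: Flap constants for the Shore-20A silicone, third-order Ogden fit (MPa).
DEFAULT_OGDEN = OgdenParams(
    mu=(-2025.7, -451.4, 1230.2),
    alpha=(-0.0706, -0.4271, -0.2728),
)

#: Default Poisson ratio used whenever a volumetric penalty is derived from E.
DEFAULT_POISSON = 0.49


def ensure_volumetric(material, nu: float = DEFAULT_POISSON):
    """Return the material with a positive volumetric penalty parameter.

    The printed constitutive constants treat the flap as incompressible
    (no volumetric terms); a displacement-based solver needs a volumetric
    law, so a penalty ``(1/d)(J-1)^2`` with ``d = 2/K`` derived from the
    model's own small-strain shear modulus and Poisson ratio ``nu`` is
    attached when absent."""
    if isinstance(material, NeoHookeanParams):
        if material.d > 0:
            return material
        K = 2.0 * material.mu * (1.0 + nu) / (3.0 * (1.0 - 2.0 * nu))
        return NeoHookeanParams(mu=material.mu, d=2.0 / K)
    if isinstance(material, OgdenParams):
        if material.volumetric_d > 0:
            return material
        mu0 = 0.5 * sum(m * a for m, a in zip(material.mu, material.alpha))
        K = 2.0 * mu0 * (1.0 + nu) / (3.0 * (1.0 - 2.0 * nu))
        return OgdenParams(mu=material.mu, alpha=material.alpha, volumetric_d=2.0 / K)
    raise TypeError(f"unsupported material {type(material).__name__}")


def neo_hookean_from_elastic(ec: ElasticConstants) -> NeoHookeanParams:
    """Convert small-strain constants (E, nu) to neo-Hookean ``(mu, d)``.

    ``mu = E / (2 (1 + nu))`` and ``d = 2 / K`` with bulk modulus
    ``K = E / (3 (1 - 2 nu))``.  At ``nu = 0.5`` the bulk modulus diverges
    and the strictly incompressible ``d = 0`` limit is returned with a
    warning.
    """
    mu = ec.E / (2.0 * (1.0 + ec.nu))
    if ec.nu >= 0.5 - _INCOMPRESSIBLE_NU_TOL:
        warnings.warn(
            "nu = 0.5: incompressible limit, returning d = 0",
            stacklevel=2,
        )
        return NeoHookeanParams(mu=mu, d=0.0)
    K = ec.E / (3.0 * (1.0 - 2.0 * ec.nu))
    return NeoHookeanParams(mu=mu, d=2.0 / K)


def elastic_from_neo_hookean(p: NeoHookeanParams) -> ElasticConstants:
    """Inverse of :func:`neo_hookean_from_elastic` (requires ``d > 0``)."""
    if p.d == 0.0:
        raise ValueError("d = 0 (incompressible): nu = 0.5, E = 3 mu")
    K = 2.0 / p.d
    E = 9.0 * K * p.mu / (3.0 * K + p.mu)
    nu = (3.0 * K - 2.0 * p.mu) / (2.0 * (3.0 * K + p.mu))
    return ElasticConstants(E=E, nu=min(max(nu, 0.0), 0.5))


def _deviatoric_stretches(s: StrainState) -> np.ndarray:
    lam = np.asarray(s.principal_stretches, dtype=float)
    return lam * s.J ** (-1.0 / 3.0)


def ogden_energy(s: StrainState, p: OgdenParams) -> float:
    """Ogden strain-energy density (MPa) at a principal-stretch state.

    The isochoric sum is evaluated on the deviatoric stretches
    ``lam_bar = J^{-1/3} lam``; the volumetric penalty ``(1/d)(J-1)^2`` is
    added when ``volumetric_d > 0``.
    """
    lb = _deviatoric_stretches(s)
    psi = 0.0
    for mu_p, a_p in zip(p.mu, p.alpha):
        psi += mu_p / a_p * (np.sum(lb**a_p) - 3.0)
    if p.volumetric_d > 0.0:
        psi += (s.J - 1.0) ** 2 / p.volumetric_d
    return float(psi)


def neo_hookean_energy(s: StrainState, p: NeoHookeanParams) -> float:
    """Neo-Hookean strain-energy density (MPa); volumetric term dropped at d=0."""
    psi = 0.5 * p.mu * (s.I1_bar - 3.0)
    if p.d > 0.0:
        psi += (s.J - 1.0) ** 2 / p.d
    return float(psi)


def _uniaxial_energy(model, lam: float) -> float:
    s = StrainState(principal_stretches=(lam, lam**-0.5, lam**-0.5))
    if isinstance(model, OgdenParams):
        return ogden_energy(s, model)
    if isinstance(model, NeoHookeanParams):
        return neo_hookean_energy(s, model)
    raise TypeError(f"unsupported material {type(model).__name__}")


def uniaxial_nominal_stress(model, lam: float) -> float:
    """Nominal (first Piola-Kirchhoff) stress dpsi/dlam (MPa) along the
    incompressible uniaxial path ``(lam, lam^-1/2, lam^-1/2)``."""
    if lam <= 0:
        raise ValueError("stretch must be positive")
    if isinstance(model, OgdenParams):
        lam_ = np.float64(lam)
        return float(
            sum(
                mu_p * (lam_ ** (a_p - 1.0) - lam_ ** (-a_p / 2.0 - 1.0))
                for mu_p, a_p in zip(model.mu, model.alpha)
            )
        )
    if isinstance(model, NeoHookeanParams):
        return float(model.mu * (lam - lam**-2.0))
    raise TypeError(f"unsupported material {type(model).__name__}")


def small_strain_shear_modulus(p, target: float | None = None) -> float:
    """Consistency diagnostic: the small-strain shear modulus implied by the
    constants, ``mu0 = 0.5 * sum(mu_p * alpha_p)`` for Ogden, ``mu`` for
    neo-Hookean.  Warns when it disagrees with ``target`` by more than 2x
    (the packaged Ogden fit and the Shore-20A Young's-modulus estimate imply
    shear moduli that differ by roughly 2.4x; the discrepancy is reported,
    not resolved)."""
    if isinstance(p, OgdenParams):
        mu0 = 0.5 * sum(m * a for m, a in zip(p.mu, p.alpha))
    elif isinstance(p, NeoHookeanParams):
        mu0 = p.mu
    else:
        raise TypeError(f"unsupported material {type(p).__name__}")
    if target is not None and target > 0:
        ratio = mu0 / target
        if ratio > 2.0 or ratio < 0.5:
            warnings.warn(
                f"small-strain shear modulus {mu0:.4g} MPa differs from the "
                f"target {target:.4g} MPa by a factor {max(ratio, 1/ratio):.2f}",
                stacklevel=2,
            )
    return float(mu0)


# ---------------------------------------------------------------------------
# Plane-strain kernels (vectorized over quadrature points) for the FEM solver.
# F has shape (..., 2, 2): the in-plane deformation gradient; the out-of-plane
# stretch is 1.  Energies in MPa, i.e. N/mm^2 with mm geometry.
# ---------------------------------------------------------------------------


def _plane_strain_principal(F: np.ndarray):
    """Principal stretches (lam1, lam2) and reference directions of C = F^T F."""
    C11 = F[..., 0, 0] ** 2 + F[..., 1, 0] ** 2
    C22 = F[..., 0, 1] ** 2 + F[..., 1, 1] ** 2
    C12 = F[..., 0, 0] * F[..., 0, 1] + F[..., 1, 0] * F[..., 1, 1]
    tr = C11 + C22
    disc = np.sqrt(np.maximum((C11 - C22) ** 2 + 4.0 * C12**2, 0.0))
    c1 = 0.5 * (tr + disc)
    c2 = 0.5 * (tr - disc)
    lam1 = np.sqrt(np.maximum(c1, 1e-30))
    lam2 = np.sqrt(np.maximum(c2, 1e-30))
    # reference eigenvector for c1; guard the degenerate isotropic case
    vx = np.where(np.abs(C12) > 1e-14 * np.maximum(tr, 1.0), C12, c1 - C22)
    vy = np.where(np.abs(C12) > 1e-14 * np.maximum(tr, 1.0), c1 - C11, C12)
    deg = (np.abs(vx) + np.abs(vy)) < 1e-14 * np.maximum(tr, 1.0)
    vx = np.where(deg, 1.0, vx)
    vy = np.where(deg, 0.0, vy)
    nrm = np.sqrt(vx**2 + vy**2)
    return lam1, lam2, vx / nrm, vy / nrm


def energy_density_plane_strain(F: np.ndarray, material) -> np.ndarray:
    """Strain-energy density psi(F) (MPa) under plane strain (lam3 = 1)."""
    F = np.asarray(F)
    if not np.issubdtype(F.dtype, np.floating):
        F = F.astype(float)
    J = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    if np.any(J <= 0):
        raise ValueError("deformation gradient with non-positive determinant")
    if isinstance(material, NeoHookeanParams):
        I1 = np.einsum("...ij,...ij->...", F, F) + 1.0
        psi = 0.5 * material.mu * (I1 * J ** (-2.0 / 3.0) - 3.0)
        if material.d > 0:
            psi = psi + (J - 1.0) ** 2 / material.d
        return psi
    if isinstance(material, OgdenParams):
        lam1, lam2, _, _ = _plane_strain_principal(F)
        Jm13 = J ** (-1.0 / 3.0)
        lb1, lb2, lb3 = lam1 * Jm13, lam2 * Jm13, Jm13
        psi = np.zeros_like(J)
        for mu_p, a_p in zip(material.mu, material.alpha):
            psi = psi + mu_p / a_p * (lb1**a_p + lb2**a_p + lb3**a_p - 3.0)
        if material.volumetric_d > 0:
            psi = psi + (J - 1.0) ** 2 / material.volumetric_d
        return psi
    raise TypeError(f"unsupported material {type(material).__name__}")


def pk1_plane_strain(F: np.ndarray, material) -> np.ndarray:
    """First Piola-Kirchhoff stress P = dpsi/dF (MPa), plane strain.

    Neo-Hookean uses the closed invariant/deformation-gradient form; Ogden
    uses the principal-stretch (spectral) form.  The two routes are
    cross-checked against each other and against numerical differentiation
    in the test suite.
    """
    F = np.asarray(F)
    if not np.issubdtype(F.dtype, np.floating):
        F = F.astype(float)
    J = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    if np.any(J <= 0):
        raise ValueError("deformation gradient with non-positive determinant")
    # in-plane F^{-T} scaled by J: J * F^{-T} = [[F22, -F21], [-F12, F11]]
    JFinvT = np.empty_like(F)
    JFinvT[..., 0, 0] = F[..., 1, 1]
    JFinvT[..., 0, 1] = -F[..., 1, 0]
    JFinvT[..., 1, 0] = -F[..., 0, 1]
    JFinvT[..., 1, 1] = F[..., 0, 0]

    if isinstance(material, NeoHookeanParams):
        I1 = np.einsum("...ij,...ij->...", F, F) + 1.0
        Jm23 = J ** (-2.0 / 3.0)
        P = material.mu * Jm23[..., None, None] * (
            F - (I1 / (3.0 * J))[..., None, None] * JFinvT
        )
        if material.d > 0:
            P = P + (2.0 / material.d) * (J - 1.0)[..., None, None] * JFinvT
        return P
    if isinstance(material, OgdenParams):
        lam1, lam2, nx, ny = _plane_strain_principal(F)
        Jm13 = J ** (-1.0 / 3.0)
        lb = (lam1 * Jm13, lam2 * Jm13, Jm13)
        # dpsi_iso/dlam_bar_i
        dpsi_lb = [np.zeros_like(J) for _ in range(3)]
        for mu_p, a_p in zip(material.mu, material.alpha):
            for i in range(3):
                dpsi_lb[i] = dpsi_lb[i] + mu_p * lb[i] ** (a_p - 1.0)
        # chain rule to in-plane principal stretches (J = lam1*lam2, lam3 = 1):
        # dlb_i/dlam_a = J^{-1/3} (delta_ia - lam_i/(3 lam_a)), lb3 = J^{-1/3}
        lam = (lam1, lam2)
        dpsi = []
        for a in range(2):
            t = np.zeros_like(J)
            for i in range(2):
                t = t + dpsi_lb[i] * Jm13 * ((1.0 if i == a else 0.0) - lam[i] / (3.0 * lam[a]))
            t = t + dpsi_lb[2] * (-Jm13 / (3.0 * lam[a]))
            dpsi.append(t)
        if material.volumetric_d > 0:
            for a in range(2):
                dpsi[a] = dpsi[a] + (2.0 / material.volumetric_d) * (J - 1.0) * J / lam[a]
        # P = sum_a dpsi_a (F N_a / lam_a) x N_a with N_1 = (nx, ny), N_2 = (-ny, nx)
        N1 = np.stack([nx, ny], axis=-1)
        N2 = np.stack([-ny, nx], axis=-1)
        P = np.zeros_like(F)
        for a, N in enumerate((N1, N2)):
            FN = np.einsum("...ij,...j->...i", F, N)
            P = P + (dpsi[a] / lam[a])[..., None, None] * np.einsum(
                "...i,...j->...ij", FN, N
            )
        return P
    raise TypeError(f"unsupported material {type(material).__name__}")
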