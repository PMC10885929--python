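"""Scalar Maxwell–Fricke physics for blood conductivity.

Blood is modelled as a suspension of non-conductive oblate-spheroidal red
blood cells (RBCs, short semiaxis ``a``, long semiaxis ``b``, aspect ratio
``lambda = a/b < 1``) in conductive plasma. Shear stress deforms the cells
(reducing the aspect ratio) and shear rate drives a gradual transition from
random orientation to full tank-treading alignment. The module maps a
pointwise shear state (maximum shear stress tau_max, maximum shear rate
gamma_dot_max) to the two principal conductivities of the transversely
isotropic conductivity tensor:

* ``sigma_alpha`` — conductivity along the dominant RBC short-axis direction,
* ``sigma_beta``  — conductivity in the plane perpendicular to it,

with ``sigma_alpha <= sigma_beta <= sigma_pl``. All quantities are strict SI.

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "BloodParams",
    "ShearState",
    "PrincipalConductivities",
    "shape_angle",
    "shape_factor_M",
    "orientation_factors",
    "random_orientation_factor",
    "deformed_aspect_ratio",
    "aligned_fraction",
    "interpolated_orientation_factors",
    "conductivity_from_factor",
    "fully_aligned_conductivities",
    "stationary_conductivity",
    "principal_conductivities",
    "alignment_threshold_shear_rate",
    "classify_shear_rate",
]

#: Aspect ratio above which the sphere limit M = 2/3 is returned exactly.
_SPHERE_EPS = 1e-6

#: Relative tolerance for a redundantly specified ShearState.
_SHEAR_CONSISTENCY_RTOL = 1e-6


@dataclass(frozen=True)
class BloodParams:
    """Constant blood and RBC parameters, SI units.

    Defaults are the standard literature values for human blood at
    physiological hematocrit. ``blood_viscosity_override`` pins the dynamic
    blood viscosity to rho_bl * nu_bl with the kinematic viscosity
    nu_bl = 4.59e-5 m^2/s; note this is *not* Merrill's relation applied to
    the tabulated ``plasma_viscosity`` (the two printed constants are
    mutually inconsistent — see docs/methods.md). Set the override to None
    to fall back to eta_pl * (1 + 2.5 H + 7.32 H^2).
    """

    aspect_ratio: float = 0.38           # lambda = a/b, dimensionless
    plasma_conductivity: float = 1.3     # sigma_pl, S/m
    hematocrit: float = 0.45             # H, volume fraction
    short_semiaxis: float = 1.52e-6      # a, m
    long_semiaxis: float = 4e-6          # b, m
    membrane_shear_modulus: float = 1e-5  # mu, kg/s^2
    orientation_constant: float = 1.0    # k, s^(-1/2)
    plasma_viscosity: float = 4.8e-2     # eta_pl, kg m^-1 s^-1 (see note)
    blood_density: float = 1060.0        # rho_bl, kg/m^3
    blood_viscosity_override: Optional[float] = 1060.0 * 4.59e-5  # eta_bl

    def __post_init__(self) -> None:
        if not (0.0 < self.aspect_ratio < 1.0):
            raise ValueError(
                f"aspect_ratio must lie in (0, 1) for an oblate spheroid, "
                f"got {self.aspect_ratio}"
            )
        if not (0.0 <= self.hematocrit < 1.0):
            raise ValueError(f"hematocrit must lie in [0, 1), got {self.hematocrit}")
        for name in (
            "plasma_conductivity",
            "short_semiaxis",
            "long_semiaxis",
            "membrane_shear_modulus",
            "orientation_constant",
            "plasma_viscosity",
            "blood_density",
        ):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")
        ratio = self.short_semiaxis / self.long_semiaxis
        if abs(ratio - self.aspect_ratio) > 1e-6 * self.aspect_ratio:
            raise ValueError(
                f"aspect_ratio={self.aspect_ratio} inconsistent with "
                f"a/b={ratio:.6g}"
            )
        if self.blood_viscosity_override is not None and self.blood_viscosity_override <= 0:
            raise ValueError("blood_viscosity_override must be positive or None")

    @property
    def blood_viscosity(self) -> float:
        """Dynamic blood viscosity eta_bl in kg m^-1 s^-1."""
        if self.blood_viscosity_override is not None:
            return self.blood_viscosity_override
        H = self.hematocrit
        return self.plasma_viscosity * (1.0 + 2.5 * H + 7.32 * H * H)

    @property
    def kinematic_viscosity(self) -> float:
        """Kinematic blood viscosity nu_bl = eta_bl / rho_bl in m^2/s."""
        return self.blood_viscosity / self.blood_density

    def with_overrides(self, **kwargs) -> "BloodParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ShearState:
    """Pointwise shear magnitudes: tau_max (Pa) and gamma_dot_max (1/s).

    The two are redundant through the Newtonian constitutive law,
    gamma_dot_max = tau_max / (2 eta_bl). Construct with either one (the
    other is derived), or with both; inconsistent pairs are rejected.
    """

    tau_max: np.ndarray
    gamma_dot_max: np.ndarray

    @classmethod
    def from_stress(cls, tau_max, params: BloodParams) -> "ShearState":
        tau = np.asarray(tau_max, dtype=float)
        if np.any(tau < 0):
            raise ValueError("tau_max must be non-negative")
        return cls(tau_max=tau, gamma_dot_max=tau / (2.0 * params.blood_viscosity))

    @classmethod
    def from_shear_rate(cls, gamma_dot_max, params: BloodParams) -> "ShearState":
        g = np.asarray(gamma_dot_max, dtype=float)
        if np.any(g < 0):
            raise ValueError("gamma_dot_max must be non-negative")
        return cls(tau_max=2.0 * params.blood_viscosity * g, gamma_dot_max=g)

    @classmethod
    def consistent(cls, tau_max, gamma_dot_max, params: BloodParams) -> "ShearState":
        """Build from both magnitudes, enforcing the constitutive relation."""
        tau = np.asarray(tau_max, dtype=float)
        g = np.asarray(gamma_dot_max, dtype=float)
        expect = tau / (2.0 * params.blood_viscosity)
        scale = np.maximum(np.abs(expect), np.abs(g))
        bad = np.abs(g - expect) > _SHEAR_CONSISTENCY_RTOL * np.maximum(scale, 1e-300)
        if np.any(bad & (scale > 0)):
            raise ValueError(
                "tau_max and gamma_dot_max violate gamma = tau/(2 eta_bl) "
                f"beyond relative tolerance {_SHEAR_CONSISTENCY_RTOL:g}"
            )
        return cls(tau_max=tau, gamma_dot_max=g)


@dataclass(frozen=True)
class PrincipalConductivities:
    """The two principal conductivities in S/m, sigma_alpha <= sigma_beta."""

    sigma_alpha: np.ndarray
    sigma_beta: np.ndarray

    @property
    def ratio(self) -> np.ndarray:
        """Conductivity ratio lambda_sigma = sigma_alpha / sigma_beta in (0, 1]."""
        return np.asarray(self.sigma_alpha) / np.asarray(self.sigma_beta)


def shape_angle(aspect_ratio):
    """Shape angle phi = arccos(lambda) of an oblate spheroid, radians."""
    lam = np.asarray(aspect_ratio, dtype=float)
    if np.any((lam < 0) | (lam > 1)):
        raise ValueError(
            "aspect ratio must lie in [0, 1]: the RBC is modelled as an "
            "oblate spheroid with short semiaxis a <= long semiaxis b"
        )
    return np.arccos(lam)


def shape_factor_M(aspect_ratio):
    """Fricke shape factor M(lambda) = (phi - sin phi cos phi) cos phi / sin^3 phi.

    Strictly increasing on (0, 1) with the sphere limit M -> 2/3 as
    lambda -> 1 (a removable 0/0 singularity, returned exactly near 1).
    """
    lam = np.asarray(aspect_ratio, dtype=float)
    phi = shape_angle(lam)
    near_sphere = lam > 1.0 - _SPHERE_EPS
    phi_safe = np.where(near_sphere, np.pi / 4, phi)
    s, c = np.sin(phi_safe), np.cos(phi_safe)
    M = (phi_safe - s * c) * c / s**3
    M = np.where(near_sphere, 2.0 / 3.0, M)
    return M[()] if M.ndim == 0 else M


def orientation_factors(M):
    """Orientation factors (Ca, Cb) for fully aligned oblate spheroids.

    Ca = 1/M applies along the short axis, Cb = 2/(2-M) in the plane of the
    long axes; Ca >= 3/2 >= Cb >= 1 with equality at the sphere (M = 2/3).
    """
    M = np.asarray(M, dtype=float)
    if np.any(M <= 0) or np.any(M > 2.0 / 3.0 + 1e-12):
        raise ValueError("shape factor M must lie in (0, 2/3]")
    return 1.0 / M, 2.0 / (2.0 - M)


def random_orientation_factor(Ca, Cb):
    """Average orientation factor Cr = (Ca + 2 Cb)/3 for random orientation."""
    Ca = np.asarray(Ca, dtype=float)
    Cb = np.asarray(Cb, dtype=float)
    if np.any(Ca < 1) or np.any(Cb < 1):
        raise ValueError("orientation factors must be >= 1")
    return (Ca + 2.0 * Cb) / 3.0


def deformed_aspect_ratio(params: BloodParams, tau_max):
    """Shear-stress-dependent aspect ratio of the deformed RBC.

    lambda_d = lambda * (1 + tau_max * b / (4 mu))^-3, strictly decreasing
    in tau_max: membrane shear stress elongates the cell.
    """
    tau = np.asarray(tau_max, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau_max must be non-negative")
    stretch = 1.0 + tau * params.long_semiaxis / (4.0 * params.membrane_shear_modulus)
    return params.aspect_ratio * stretch**-3


def aligned_fraction(gamma_dot_max, k: float = 1.0):
    """Fraction of RBCs in the aligned (tank-treading) state.

    f(gamma) = gamma / (gamma + k sqrt(gamma)); 0 at rest, -> 1 at infinite
    shear rate. ``k`` is the orientation/disorientation constant, s^(-1/2).
    """
    g = np.asarray(gamma_dot_max, dtype=float)
    if np.any(g < 0):
        raise ValueError("gamma_dot_max must be non-negative")
    if k <= 0:
        raise ValueError("orientation constant k must be positive")
    denom = g + k * np.sqrt(g)
    with np.errstate(invalid="ignore"):
        f = np.where(denom > 0, g / np.where(denom > 0, denom, 1.0), 0.0)
    return f[()] if f.ndim == 0 else f


def alignment_threshold_shear_rate(f, k: float = 1.0):
    """Invert the aligned fraction: the shear rate at which f is attained.

    Closed form gamma = (f k / (1 - f))^2. The conventional regime
    boundaries are f = 0.20 ("low" below) and f = 0.80 ("high" beyond),
    i.e. 0.0625 and 16 s^-1 for k = 1.
    """
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f >= 1)):
        raise ValueError("aligned fraction must lie in [0, 1)")
    return (f * k / (1.0 - f)) ** 2


def classify_shear_rate(gamma_dot_max, k: float = 1.0):
    """Label shear rates 'low' (f<0.2), 'intermediate', or 'high' (f>0.8)."""
    lo = alignment_threshold_shear_rate(0.20, k)
    hi = alignment_threshold_shear_rate(0.80, k)
    g = np.asarray(gamma_dot_max, dtype=float)
    out = np.where(g < lo, "low", np.where(g > hi, "high", "intermediate"))
    return out[()] if out.ndim == 0 else out


def interpolated_orientation_factors(Ca, Cb, Cr, f):
    """Interpolate between random (f=0) and fully aligned (f=1) factors.

    C_alpha = f Ca + (1-f) Cr,  C_beta = f Cb + (1-f) Cr.
    """
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("aligned fraction must lie in [0, 1]")
    return f * Ca + (1.0 - f) * Cr, f * Cb + (1.0 - f) * Cr


def conductivity_from_factor(C, params: BloodParams):
    """Maxwell–Fricke suspension conductivity for orientation factor C.

    sigma = sigma_pl (1 - H) / (1 + (C - 1) H); the hematocrit H dilutes the
    conductive plasma and the factor C encodes particle shape/orientation.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 1):
        raise ValueError("orientation factor must be >= 1")
    H = params.hematocrit
    return params.plasma_conductivity * (1.0 - H) / (1.0 + (C - 1.0) * H)


def fully_aligned_conductivities(params: BloodParams, tau_max) -> PrincipalConductivities:
    """Principal conductivities for perfectly aligned, shear-deformed RBCs."""
    lam_d = deformed_aspect_ratio(params, tau_max)
    Ca, Cb = orientation_factors(shape_factor_M(lam_d))
    return PrincipalConductivities(
        sigma_alpha=conductivity_from_factor(Ca, params),
        sigma_beta=conductivity_from_factor(Cb, params),
    )


def stationary_conductivity(params: BloodParams):
    """Isotropic conductivity of stationary blood (random orientation, no shear)."""
    Ca, Cb = orientation_factors(shape_factor_M(params.aspect_ratio))
    return conductivity_from_factor(random_orientation_factor(Ca, Cb), params)


def principal_conductivities(params: BloodParams, shear: ShearState) -> PrincipalConductivities:
    """Full deformation-and-alignment chain: shear state -> (sigma_alpha, sigma_beta).

    The deformed aspect ratio (from tau_max) sets the orientation factors
    Ca, Cb, Cr; the aligned fraction (from gamma_dot_max) interpolates
    between the random and aligned states; the Maxwell–Fricke formula maps
    the interpolated factors to conductivities. The ratio
    lambda_sigma = sigma_alpha / sigma_beta decreases monotonically with
    shear rate — anisotropy grows with shear.
    """
    lam_d = deformed_aspect_ratio(params, shear.tau_max)
    Ca, Cb = orientation_factors(shape_factor_M(lam_d))
    Cr = random_orientation_factor(Ca, Cb)
    f = aligned_fraction(shear.gamma_dot_max, params.orientation_constant)
    C_alpha, C_beta = interpolated_orientation_factors(Ca, Cb, Cr, f)
    return PrincipalConductivities(
        sigma_alpha=conductivity_from_factor(C_alpha, params),
        sigma_beta=conductivity_from_factor(C_beta, params),
    )
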