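"""Pointwise kinematics and the two RBC-orientation models.

Tank-treading red blood cells orient with their short (symmetry) axis along
a flow-determined direction ``e_alpha``. Two models for that direction are
implemented:

* **EV (eigenvector) model** — ``e_alpha`` is the normal of the maximum-
  shear plane of the viscous stress tensor that most nearly contains the
  velocity vector. The two candidate normals are ``(e1 -+ e3)/sqrt(2)``
  built from the eigenvectors of the extreme principal stresses; the one
  making the *larger* angle with the velocity is the shear-plane normal
  sought.
* **VV (velocity–vorticity) model** — ``e_alpha`` is the direction of the
  Lamb vector ``u x omega``.

Given ``e_alpha`` and the two principal conductivities, the transversely
isotropic conductivity tensor is
``sigma = sigma_alpha e_alpha (x) e_alpha + sigma_beta (I - e_alpha (x) e_alpha)``.

Functions operate on single points (shape ``(3,)``/``(3, 3)``) or batches
(leading dimensions broadcast).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .fricke_core import (
    BloodParams,
    PrincipalConductivities,
    ShearState,
    aligned_fraction,
    conductivity_from_factor,
    deformed_aspect_ratio,
    orientation_factors,
    principal_conductivities,
    random_orientation_factor,
    shape_factor_M,
)
from .flow_fields import FlowField

__all__ = [
    "StressSpectrum",
    "OrientationAxis",
    "ConductivityTensorField",
    "rate_of_deformation",
    "viscous_stress",
    "vorticity",
    "stress_spectrum",
    "eigenvector_axis",
    "lamb_axis",
    "assemble_tensor",
    "apply_ohm",
    "anisotropy_indicator",
    "conductivity_field",
    "sign_normalize",
]

#: Default stress scale below which the spectrum is treated as degenerate, Pa.
EPS_TAU = 1e-12
#: Default relative Lamb-vector magnitude below which u x omega is degenerate.
EPS_LAMB = 1e-8
#: Relative tolerance for the incompressibility (trace) warning.
TRACE_TOL = 1e-6

_SQRT2 = np.sqrt(2.0)


def sign_normalize(v: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Flip vectors so their first non-negligible component is positive.

    Orientation axes are physically defined only up to sign; this fixes a
    reproducible representative.
    """
    v = np.asarray(v, dtype=float)
    mag = np.linalg.norm(v, axis=-1, keepdims=True)
    significant = np.abs(v) > tol * np.maximum(mag, 1e-300)
    idx = np.argmax(significant, axis=-1)[..., None]
    lead = np.take_along_axis(v, idx, axis=-1)
    sign = np.where(lead < 0, -1.0, 1.0)
    return v * sign


@dataclass(frozen=True)
class StressSpectrum:
    """Eigenvalues (descending) and orthonormal eigenvectors of a stress tensor.

    ``eigenvectors[..., :, i]`` is the unit eigenvector for ``eigenvalues[..., i]``;
    index 0 is the maximum principal stress tau_1, index 2 the minimum tau_3.
    ``tau_max = tau_1 - tau_3`` is (twice) the maximum shear stress scale used
    throughout, and ``gamma_dot_max = tau_max / (2 eta_bl)``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    tau_max: np.ndarray

    def shear_state(self, params: BloodParams) -> ShearState:
        return ShearState.from_stress(self.tau_max, params)


@dataclass(frozen=True)
class OrientationAxis:
    """Dominant RBC short-axis direction with provenance.

    ``degenerate`` is None for a well-defined axis, otherwise one of
    'zero-stress', 'repeated-eigenvalue', 'parallel-u-omega', 'zero-velocity'.
    """

    e_alpha: np.ndarray
    model: str  # 'EV' or 'VV'
    degenerate: Optional[str] = None


def rate_of_deformation(grad: np.ndarray) -> np.ndarray:
    """Rate-of-deformation tensor D = (grad u + grad u^T)/2."""
    g = np.asarray(grad, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("velocity gradient must be finite")
    return 0.5 * (g + np.swapaxes(g, -1, -2))


def viscous_stress(D: np.ndarray, eta_bl: float) -> np.ndarray:
    """Newtonian viscous stress tau = 2 eta_bl D."""
    return 2.0 * eta_bl * np.asarray(D, dtype=float)


def vorticity(grad: np.ndarray) -> np.ndarray:
    """Vorticity omega = curl u from the velocity gradient du_i/dx_j."""
    g = np.asarray(grad, dtype=float)
    return np.stack(
        [
            g[..., 2, 1] - g[..., 1, 2],
            g[..., 0, 2] - g[..., 2, 0],
            g[..., 1, 0] - g[..., 0, 1],
        ],
        axis=-1,
    )


def check_incompressibility(grad: np.ndarray, tol: float = TRACE_TOL) -> None:
    """Warn if trace(grad u) exceeds tol * ||grad u|| anywhere."""
    g = np.asarray(grad, dtype=float)
    tr = np.abs(np.trace(g, axis1=-2, axis2=-1))
    norm = np.linalg.norm(g, axis=(-2, -1))
    if np.any(tr > tol * np.maximum(norm, 1e-300)):
        warnings.warn(
            "velocity gradient has non-negligible divergence; the input "
            "flow does not look incompressible",
            stacklevel=2,
        )


def stress_spectrum(
    tau: np.ndarray, symmetry_tol: float = 1e-8
) -> StressSpectrum:
    """Spectral decomposition of the viscous stress tensor.

    Returns eigenvalues sorted descending (tau_1 >= tau_2 >= tau_3) with
    sign-normalized orthonormal eigenvectors and tau_max = tau_1 - tau_3.
    """
    t = np.asarray(tau, dtype=float)
    asym = np.linalg.norm(t - np.swapaxes(t, -1, -2), axis=(-2, -1))
    scale = np.maximum(np.linalg.norm(t, axis=(-2, -1)), 1e-300)
    if np.any(asym > symmetry_tol * scale):
        raise ValueError("stress tensor must be symmetric")
    w, v = np.linalg.eigh(0.5 * (t + np.swapaxes(t, -1, -2)))
    w = w[..., ::-1]                      # descending
    v = v[..., ::-1]
    v = np.swapaxes(sign_normalize(np.swapaxes(v, -1, -2)), -1, -2)
    return StressSpectrum(
        eigenvalues=w, eigenvectors=v, tau_max=w[..., 0] - w[..., 2]
    )


def _ev_axis_vec(spec: StressSpectrum, u: np.ndarray):
    """Vectorized EV axis: returns (axis, chose_minus) without degeneracy logic."""
    e1 = spec.eigenvectors[..., :, 0]
    e3 = spec.eigenvectors[..., :, 2]
    minus = (e1 - e3) / _SQRT2
    plus = (e1 + e3) / _SQRT2
    proj_plus = np.abs(np.einsum("...i,...i->...", u, plus))
    proj_minus = np.abs(np.einsum("...i,...i->...", u, minus))
    take_minus = proj_plus > proj_minus
    axis = np.where(take_minus[..., None], minus, plus)
    return sign_normalize(axis), take_minus


def eigenvector_axis(
    spec: StressSpectrum, u: np.ndarray, eps_tau: float = EPS_TAU
) -> OrientationAxis:
    """EV-model short-axis direction at one point.

    Of the two maximum-shear-plane normals ``(e1 -+ e3)/sqrt(2)``, pick the
    one making the larger angle with the velocity (equivalently, whose
    *counterpart* carries the larger velocity projection); ties take the
    ``(e1 + e3)/sqrt(2)`` branch. Degenerate when tau_max < eps_tau — the
    extreme eigenvalues coincide and no shear plane is defined.
    """
    u = np.asarray(u, dtype=float)
    axis, _ = _ev_axis_vec(spec, u)
    tau_max = np.asarray(spec.tau_max)
    w = np.asarray(spec.eigenvalues)
    if tau_max.ndim == 0:
        if float(tau_max) < eps_tau:
            reason = "zero-stress" if np.all(np.abs(w) < eps_tau) else "repeated-eigenvalue"
            return OrientationAxis(e_alpha=axis, model="EV", degenerate=reason)
        return OrientationAxis(e_alpha=axis, model="EV")
    raise ValueError("eigenvector_axis is pointwise; use conductivity_field for batches")


def lamb_axis(
    u: np.ndarray, omega: np.ndarray, eps_lamb: float = EPS_LAMB
) -> OrientationAxis:
    """VV-model short-axis direction: the normalized Lamb vector u x omega.

    Degenerate when either vector (nearly) vanishes or when u and omega are
    (nearly) parallel, ||u x omega|| < eps_lamb ||u|| ||omega||.
    """
    u = np.asarray(u, dtype=float)
    omega = np.asarray(omega, dtype=float)
    lamb = np.cross(u, omega)
    nu, nw, nl = (np.linalg.norm(a) for a in (u, omega, lamb))
    if nu < 1e-300:
        return OrientationAxis(np.zeros(3), "VV", degenerate="zero-velocity")
    if nw < 1e-300 or nl < eps_lamb * nu * nw:
        return OrientationAxis(np.zeros(3), "VV", degenerate="parallel-u-omega")
    return OrientationAxis(sign_normalize(lamb / nl), "VV")


def assemble_tensor(
    axis: OrientationAxis, pc: PrincipalConductivities, iso_tol: float = 1e-9
) -> np.ndarray:
    """Transversely isotropic conductivity tensor from axis and principal values.

    sigma = sigma_alpha (e (x) e) + sigma_beta (I - e (x) e); invariant under
    e -> -e. A degenerate axis is only admissible when the conductivities
    are (numerically) isotropic, in which case sigma = sigma I.
    """
    sa = float(np.asarray(pc.sigma_alpha))
    sb = float(np.asarray(pc.sigma_beta))
    if axis.degenerate is not None:
        if abs(sa - sb) > iso_tol * max(abs(sb), 1e-300):
            raise ValueError(
                f"degenerate axis ({axis.degenerate}) with anisotropic "
                "conductivities: no orientation available to assemble the tensor"
            )
        return sb * np.eye(3)
    e = np.asarray(axis.e_alpha, dtype=float)
    return sb * np.eye(3) + (sa - sb) * np.outer(e, e)


def apply_ohm(sigma: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Ohm's law J = sigma . E (A/m^2)."""
    return np.einsum("...ij,...j->...i", np.asarray(sigma, float), np.asarray(E, float))


def anisotropy_indicator(pc: PrincipalConductivities):
    """Anisotropy indicator eta = (sigma_beta - sigma_alpha)/(2 sigma_beta + sigma_alpha).

    The difference of the extreme principal conductivities over the sum of
    all three principal values {sigma_alpha, sigma_beta, sigma_beta};
    0 for isotropy, -> 1/2 as sigma_alpha/sigma_beta -> 0.
    """
    sa = np.asarray(pc.sigma_alpha, dtype=float)
    sb = np.asarray(pc.sigma_beta, dtype=float)
    return (sb - sa) / (2.0 * sb + sa)


@dataclass
class ConductivityTensorField:
    """Conductivity tensor plus per-point diagnostics on a structured grid.

    ``degenerate`` holds '' at regular points, otherwise the reason; points
    outside the domain mask carry 'masked' and NaN diagnostics.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    model: str
    tensors: np.ndarray        # (nx, ny, nz, 3, 3), S/m
    e_alpha: np.ndarray        # (nx, ny, nz, 3)
    sigma_alpha: np.ndarray    # (nx, ny, nz), S/m
    sigma_beta: np.ndarray
    tau_max: np.ndarray        # Pa
    gamma_dot_max: np.ndarray  # 1/s
    aligned_f: np.ndarray
    lambda_d: np.ndarray
    eta: np.ndarray            # anisotropy indicator
    degenerate: np.ndarray     # (nx, ny, nz) of str
    params: BloodParams = None

    @property
    def shape(self) -> tuple:
        return (self.x.size, self.y.size, self.z.size)

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of points with a well-defined orientation axis."""
        return self.degenerate == ""

    def points(self) -> np.ndarray:
        X, Y, Z = np.meshgrid(self.x, self.y, self.z, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)

    def to_dataframe(self) -> pd.DataFrame:
        """Per-point diagnostic table (one row per grid point, x varying slowest)."""
        pts = self.points()
        n = pts.shape[0]
        t = self.tensors.reshape(n, 3, 3)
        df = pd.DataFrame(
            {
                "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
                "sxx": t[:, 0, 0], "syy": t[:, 1, 1], "szz": t[:, 2, 2],
                "sxy": t[:, 0, 1], "sxz": t[:, 0, 2], "syz": t[:, 1, 2],
                "gamma_dot_max": self.gamma_dot_max.ravel(),
                "tau_max": self.tau_max.ravel(),
                "aligned_f": self.aligned_f.ravel(),
                "lambda_d": self.lambda_d.ravel(),
                "sigma_alpha": self.sigma_alpha.ravel(),
                "sigma_beta": self.sigma_beta.ravel(),
                "eta": self.eta.ravel(),
                "degenerate": self.degenerate.ravel(),
            }
        )
        return df


def conductivity_field(
    flow: FlowField,
    params: BloodParams,
    model: str,
    eps_tau: float = EPS_TAU,
    eps_lamb: float = EPS_LAMB,
    vv_fallback: str = "isotropic",
) -> ConductivityTensorField:
    """Map a velocity field to a conductivity tensor field with one model.

    At every grid point: velocity gradient -> rate of deformation -> viscous
    stress -> spectral decomposition -> (tau_max, gamma_dot_max) -> principal
    conductivities via the Maxwell–Fricke chain -> orientation axis (EV or
    VV) -> tensor assembly. Degenerate points (no defined axis) fall back to
    the isotropic random-orientation conductivity; for the VV model,
    ``vv_fallback='ev'`` borrows the EV axis instead where it is defined.
    """
    if model not in ("EV", "VV"):
        raise ValueError(f"model must be 'EV' or 'VV', got {model!r}")
    if vv_fallback not in ("isotropic", "ev"):
        raise ValueError(f"vv_fallback must be 'isotropic' or 'ev', got {vv_fallback!r}")

    shape = flow.shape
    n = int(np.prod(shape))
    u = flow.velocity.reshape(n, 3)
    grads = flow.gradients().reshape(n, 3, 3)
    if not np.all(np.isfinite(grads)):
        bad = np.argwhere(~np.isfinite(grads).all(axis=(1, 2)))[0, 0]
        raise ValueError(f"non-finite velocity gradient at point index {bad}")
    check_incompressibility(grads)

    eta_bl = params.blood_viscosity
    D = rate_of_deformation(grads)
    tau = viscous_stress(D, eta_bl)
    spec = stress_spectrum(tau)
    tau_max = spec.tau_max
    gamma = tau_max / (2.0 * eta_bl)

    # Maxwell-Fricke chain, vectorized over points
    lam_d = deformed_aspect_ratio(params, tau_max)
    Ca, Cb = orientation_factors(shape_factor_M(lam_d))
    Cr = random_orientation_factor(Ca, Cb)
    f = aligned_fraction(gamma, params.orientation_constant)
    pc = principal_conductivities(params, ShearState(tau_max, gamma))
    sa = np.asarray(pc.sigma_alpha)
    sb = np.asarray(pc.sigma_beta)
    sigma_iso = conductivity_from_factor(Cr, params)  # random-orientation fallback

    zero_stress = tau_max < eps_tau
    degenerate = np.where(zero_stress, "zero-stress", "")
    axis, _ = _ev_axis_vec(spec, u)

    if model == "VV":
        omega = vorticity(grads)
        lamb = np.cross(u, omega)
        nu = np.linalg.norm(u, axis=-1)
        nw = np.linalg.norm(omega, axis=-1)
        nl = np.linalg.norm(lamb, axis=-1)
        zero_vel = nu < 1e-300
        parallel = (~zero_vel) & ((nw < 1e-300) | (nl < eps_lamb * nu * nw))
        vv_axis = sign_normalize(
            lamb / np.maximum(nl, 1e-300)[..., None]
        )
        vv_bad = zero_vel | parallel
        if vv_fallback == "ev":
            # borrow the EV axis where the stress spectrum still defines one
            usable = vv_bad & ~zero_stress
            vv_axis = np.where(usable[..., None], axis, vv_axis)
            vv_bad = vv_bad & zero_stress
        degenerate = np.where(
            vv_bad & (degenerate == ""),
            np.where(zero_vel, "zero-velocity", "parallel-u-omega"),
            degenerate,
        )
        axis = vv_axis

    bad = degenerate != ""
    axis = np.where(bad[..., None], 0.0, axis)

    # assemble: sigma = sb*I + (sa-sb) e(x)e, isotropic sigma_iso at bad points
    eye = np.eye(3)
    outer = np.einsum("ni,nj->nij", axis, axis)
    sa_eff = np.where(bad, sigma_iso, sa)
    sb_eff = np.where(bad, sigma_iso, sb)
    tensors = sb_eff[:, None, None] * eye + (sa_eff - sb_eff)[:, None, None] * outer
    eta_ind = (sb_eff - sa_eff) / (2.0 * sb_eff + sa_eff)

    if flow.mask is not None:
        outside = ~flow.mask.ravel()
        degenerate = np.where(outside, "masked", degenerate)
        for arr in (tensors, axis):
            arr[outside] = np.nan
        sa_eff = np.where(outside, np.nan, sa_eff)
        sb_eff = np.where(outside, np.nan, sb_eff)
        eta_ind = np.where(outside, np.nan, eta_ind)

    return ConductivityTensorField(
        x=flow.x, y=flow.y, z=flow.z, model=model,
        tensors=tensors.reshape(shape + (3, 3)),
        e_alpha=axis.reshape(shape + (3,)),
        sigma_alpha=sa_eff.reshape(shape),
        sigma_beta=sb_eff.reshape(shape),
        tau_max=tau_max.reshape(shape),
        gamma_dot_max=gamma.reshape(shape),
        aligned_f=np.asarray(f).reshape(shape),
        lambda_d=np.asarray(lam_d).reshape(shape),
        eta=eta_ind.reshape(shape),
        degenerate=degenerate.reshape(shape),
        params=params,
    )
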