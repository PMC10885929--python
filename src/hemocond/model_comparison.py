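"""Quantifying the disagreement between the EV and VV orientation models.

Two angles measure the disagreement at a point: ``psi_alpha``, the angle
between the two predicted short-axis directions (sign-invariant, in
[0, 90] degrees), and ``psi_sigma``, the Frobenius angle between the two
assembled conductivity tensors. Because both tensors share the same
principal values, ``psi_sigma`` depends only on ``psi_alpha`` and the
conductivity ratio ``lambda_sigma = sigma_alpha / sigma_beta``:

    cos psi_sigma = [l^2 c^2 + 2 l (1 - c^2) + 1 + c^2] / (l^2 + 2),

with ``c = cos psi_alpha`` and ``l = lambda_sigma``. ``psi_sigma`` is always
far smaller than ``psi_alpha``: the limited anisotropy of blood mends most
of the axis disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .orientation_tensor import ConductivityTensorField

__all__ = [
    "psi_alpha",
    "psi_sigma",
    "psi_sigma_closed_form",
    "compare_fields",
    "ComparisonSummary",
]

#: arccos arguments are clamped to [0, 1] within this tolerance.
_CLAMP_TOL = 1e-12


def _clamped_arccos_deg(c):
    c = np.asarray(c, dtype=float)
    if np.any(c > 1.0 + _CLAMP_TOL) or np.any(c < -_CLAMP_TOL):
        raise ValueError("cosine argument outside [0, 1] beyond tolerance")
    return np.degrees(np.arccos(np.clip(c, 0.0, 1.0)))


def psi_alpha(e_ev: np.ndarray, e_vv: np.ndarray):
    """Angle between the two model axes, degrees in [0, 90].

    psi_alpha = arccos |<e_EV, e_VV>|; the absolute value makes the angle
    independent of the (physically meaningless) axis signs.
    """
    a = np.asarray(e_ev, dtype=float)
    b = np.asarray(e_vv, dtype=float)
    norm = np.linalg.norm(a, axis=-1) * np.linalg.norm(b, axis=-1)
    if np.any(norm < 1e-300):
        raise ValueError("psi_alpha is undefined for zero (degenerate) axes")
    dot = np.abs(np.einsum("...i,...i->...", a, b))
    # atan2(|a x b|, |a.b|) resolves near-parallel axes to machine precision,
    # where arccos of the normalized dot product loses ~1e-8 rad
    cross = np.linalg.norm(np.cross(a, b), axis=-1)
    return np.degrees(np.arctan2(cross, dot))


def psi_sigma(sigma_ev: np.ndarray, sigma_vv: np.ndarray, norm_rtol: float = 1e-9):
    """Frobenius angle between two conductivity tensors, degrees.

    psi_sigma = arccos( <A, B> / (||A|| ||B||) ) with the Frobenius inner
    product. Both tensors must share the same principal values (equal
    norms sqrt(sigma_alpha^2 + 2 sigma_beta^2)); a norm mismatch indicates
    the tensors were not built from the same shear state and is rejected.
    """
    A = np.asarray(sigma_ev, dtype=float)
    B = np.asarray(sigma_vv, dtype=float)
    na = np.linalg.norm(A, axis=(-2, -1))
    nb = np.linalg.norm(B, axis=(-2, -1))
    if np.any(np.abs(na - nb) > norm_rtol * np.maximum(na, nb)):
        raise ValueError(
            "tensor norms differ: the two tensors do not share principal values"
        )
    inner = np.einsum("...ij,...ij->...", A, B)
    if np.any(inner / (na * nb) < -_CLAMP_TOL):
        raise ValueError("cosine argument outside [0, 1] beyond tolerance")
    # chord form 2 arcsin(||A/||A|| - B/||B||| / 2): accurate for the small
    # angles that dominate near-coinciding tensor fields
    diff = np.linalg.norm(
        A / na[..., None, None] - B / nb[..., None, None], axis=(-2, -1)
    )
    return np.degrees(2.0 * np.arcsin(np.clip(diff / 2.0, 0.0, 1.0)))


def psi_sigma_closed_form(lambda_sigma, psi_alpha_deg):
    """Tensor angle from the conductivity ratio and the axis angle, degrees.

    Closed form of the Frobenius angle between two transversely isotropic
    tensors with shared principal values: zero at isotropy (lambda_sigma=1)
    or coinciding axes, maximal at psi_alpha = 90 degrees.
    """
    l = np.asarray(lambda_sigma, dtype=float)
    if np.any((l <= 0) | (l > 1.0 + _CLAMP_TOL)):
        raise ValueError("lambda_sigma must lie in (0, 1]")
    p = np.radians(np.asarray(psi_alpha_deg, dtype=float))
    if np.any((p < 0) | (p > np.pi / 2 + _CLAMP_TOL)):
        raise ValueError("psi_alpha must lie in [0, 90] degrees")
    # algebraically identical to
    #   cos psi_sigma = [l^2 c^2 + 2 l (1-c^2) + 1 + c^2] / (l^2 + 2)
    # via 1 - cos psi_sigma = sin^2(psi_alpha) (1-l)^2 / (l^2 + 2), but exact
    # at the psi_sigma = 0 boundary where the cosine form loses an ulp
    s = np.sin(p)
    half_sin = s * (1.0 - l) / np.sqrt(2.0 * (l**2 + 2.0))
    return np.degrees(2.0 * np.arcsin(np.clip(half_sin, 0.0, 1.0)))


@dataclass(frozen=True)
class ComparisonSummary:
    """Field-level summary of the model disagreement (degenerate points excluded)."""

    n_points: int
    n_compared: int
    n_degenerate: int
    psi_alpha_max: float
    psi_alpha_mean: float
    psi_sigma_max: float
    psi_sigma_mean: float
    psi_alpha_q95: float
    psi_sigma_q95: float
    lambda_sigma_min: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def compare_fields(
    field_ev: ConductivityTensorField, field_vv: ConductivityTensorField
) -> tuple[pd.DataFrame, ComparisonSummary]:
    """Per-point EV-vs-VV comparison on a shared grid.

    Returns a per-point table (psi_alpha, psi_sigma, lambda_sigma,
    degeneracy) and a summary over the points where both axes are defined.
    Points flagged degenerate by either model are excluded from the
    statistics and counted separately.
    """
    if field_ev.model != "EV" or field_vv.model != "VV":
        raise ValueError("compare_fields expects (EV field, VV field) in that order")
    for ax in ("x", "y", "z"):
        if not np.array_equal(getattr(field_ev, ax), getattr(field_vv, ax)):
            raise ValueError(f"grid mismatch along {ax}")
    if field_ev.params != field_vv.params:
        raise ValueError("fields were computed with different blood parameters")

    n = int(np.prod(field_ev.shape))
    ok = (field_ev.valid & field_vv.valid).ravel()
    e_ev = field_ev.e_alpha.reshape(n, 3)
    e_vv = field_vv.e_alpha.reshape(n, 3)
    lam = (field_ev.sigma_alpha / field_ev.sigma_beta).ravel()

    pa = np.full(n, np.nan)
    ps = np.full(n, np.nan)
    if ok.any():
        pa[ok] = psi_alpha(e_ev[ok], e_vv[ok])
        # tensor-route angle; the closed form is kept as an independent check
        ps[ok] = psi_sigma(
            field_ev.tensors.reshape(n, 3, 3)[ok],
            field_vv.tensors.reshape(n, 3, 3)[ok],
        )

    pts = field_ev.points()
    df = pd.DataFrame(
        {
            "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
            "psi_alpha": pa,
            "psi_sigma": ps,
            "lambda_sigma": lam,
            "degenerate_ev": field_ev.degenerate.ravel(),
            "degenerate_vv": field_vv.degenerate.ravel(),
        }
    )
    masked = (field_ev.degenerate.ravel() == "masked")
    n_deg = int((~ok & ~masked).sum())
    n_cmp = int(ok.sum())
    if n_cmp:
        summary = ComparisonSummary(
            n_points=n,
            n_compared=n_cmp,
            n_degenerate=n_deg,
            psi_alpha_max=float(np.max(pa[ok])),
            psi_alpha_mean=float(np.mean(pa[ok])),
            psi_sigma_max=float(np.max(ps[ok])),
            psi_sigma_mean=float(np.mean(ps[ok])),
            psi_alpha_q95=float(np.quantile(pa[ok], 0.95)),
            psi_sigma_q95=float(np.quantile(ps[ok], 0.95)),
            lambda_sigma_min=float(np.min(lam[ok])),
        )
    else:
        summary = ComparisonSummary(n, 0, n_deg, *([float("nan")] * 7))
    return df, summary
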