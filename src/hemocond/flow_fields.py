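"""Benchmark flows, blood rheology scalars, and discrete differential operators.

Velocity fields live on structured Cartesian grids (vertex-centred, axes
inclusive of endpoints, ``ij`` index ordering). Analytic generators carry an
exact velocity-gradient closure; fields read from disk fall back to
second-order finite differences. The analytic pipe flows stand in for CFD
output: a Poiseuille profile in a straight rigid vessel, and the same
profile with a superposed solid-body swirl — the simplest flow in which the
eigenvector and velocity–vorticity orientation models disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "FlowField",
    "PipeSpec",
    "blood_viscosity",
    "kinematic_viscosity",
    "reynolds",
    "poiseuille_pipe",
    "swirling_pipe",
    "uniform_flow",
    "random_solenoidal_field",
    "fd_gradient",
]


@dataclass
class FlowField:
    """A velocity vector field on a structured Cartesian grid.

    Attributes
    ----------
    x, y, z : 1-D strictly monotone coordinate axes, m.
    velocity : array (nx, ny, nz, 3), m/s.
    gradient_fn : optional closure mapping points (N, 3) -> gradients
        (N, 3, 3) with entries d u_i / d x_j; if absent, gradients are
        obtained by finite differences.
    mask : optional boolean array (nx, ny, nz); True marks points inside
        the physical domain (e.g. inside the vessel lumen).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    velocity: np.ndarray
    gradient_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        for name, ax in (("x", self.x), ("y", self.y), ("z", self.z)):
            if ax.ndim != 1 or ax.size < 1:
                raise ValueError(f"axis {name} must be a 1-D array")
            if ax.size > 1 and not (np.all(np.diff(ax) > 0) or np.all(np.diff(ax) < 0)):
                raise ValueError(f"axis {name} must be strictly monotone")
        expected = (self.x.size, self.y.size, self.z.size, 3)
        if self.velocity.shape != expected:
            raise ValueError(
                f"velocity shape {self.velocity.shape} does not match grid {expected}"
            )
        if not np.all(np.isfinite(self.velocity)):
            raise ValueError("velocity must be finite everywhere")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != expected[:3]:
                raise ValueError("mask shape does not match grid")

    @property
    def shape(self) -> tuple:
        return (self.x.size, self.y.size, self.z.size)

    def points(self) -> np.ndarray:
        """All grid points as an (N, 3) array, x index varying slowest."""
        X, Y, Z = np.meshgrid(self.x, self.y, self.z, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)

    def gradients(self) -> np.ndarray:
        """Velocity gradient du_i/dx_j at every grid point, (nx, ny, nz, 3, 3)."""
        if self.gradient_fn is not None:
            g = self.gradient_fn(self.points())
            return g.reshape(self.shape + (3, 3))
        return fd_gradient(self)

    def max_divergence(self) -> float:
        """Max |trace(grad u)| over the grid — incompressibility diagnostic."""
        g = self.gradients()
        tr = np.abs(np.trace(g, axis1=-2, axis2=-1))
        if self.mask is not None:
            tr = tr[self.mask]
        return float(tr.max()) if tr.size else 0.0


@dataclass(frozen=True)
class PipeSpec:
    """A straight circular pipe: diameter, mean axial velocity, axis, swirl.

    The pipe axis runs along +z through (x, y) = (0, 0); the radial
    coordinate is r = sqrt(x^2 + y^2). ``swirl_rate`` is the solid-body
    angular rate Omega of the superposed azimuthal motion (0 for pure
    Poiseuille flow).
    """

    diameter: float = 0.04       # D, m
    mean_velocity: float = 0.008  # u_bar, m/s
    swirl_rate: float = 0.0      # Omega, 1/s

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.mean_velocity <= 0:
            raise ValueError("diameter and mean_velocity must be positive")


def blood_viscosity(eta_pl: float, hematocrit: float) -> float:
    """Merrill's hematocrit dependence: eta_bl = eta_pl (1 + 2.5 H + 7.32 H^2)."""
    if not (0.0 <= hematocrit < 1.0):
        raise ValueError("hematocrit must lie in [0, 1)")
    H = hematocrit
    return eta_pl * (1.0 + 2.5 * H + 7.32 * H * H)


def kinematic_viscosity(eta_bl: float, rho_bl: float) -> float:
    """nu_bl = eta_bl / rho_bl, m^2/s."""
    if rho_bl <= 0:
        raise ValueError("density must be positive")
    return eta_bl / rho_bl


def reynolds(mean_velocity: float, diameter: float, nu_bl: float) -> float:
    """Pipe Reynolds number Re = u_bar D / nu_bl."""
    if nu_bl <= 0:
        raise ValueError("kinematic viscosity must be positive")
    return mean_velocity * diameter / nu_bl


def _pipe_grid(spec: PipeSpec, resolution: int, length: Optional[float]):
    if resolution < 3:
        raise ValueError("resolution must be at least 3 points per axis")
    R = spec.diameter / 2.0
    L = spec.diameter if length is None else length
    x = np.linspace(-R, R, resolution)
    y = np.linspace(-R, R, resolution)
    z = np.linspace(0.0, L, resolution)
    return x, y, z, R


def _pipe_velocity_and_gradient(spec: PipeSpec, R: float, L: float):
    """Closures for u(x) and grad u(x) of the (possibly swirling) pipe flow.

    Axial profile u_z(r) = 2 u_bar (1 - (r/R)^2). The swirl is an axially
    *developing* solid-body twist, u_theta(r, z) = Omega r sin(pi z / L)
    ((u_x, u_y) = Omega (-y, x) sin(pi z / L)): zero at inlet and outlet,
    fully developed at mid-pipe. The axial modulation is what makes the flow
    genuinely three-dimensional — a z-independent swirl u_theta = Omega r
    contributes nothing to the rate of deformation and leaves both
    orientation models radially aligned, exactly like pure Poiseuille flow
    (any unidirectional axisymmetric u_theta(r), u_z(r) does; see
    docs/methods.md). The field stays exactly divergence-free. Points with
    r > R (outside the lumen) carry zero velocity and zero gradient.
    """
    ub, Om = spec.mean_velocity, spec.swirl_rate
    c = 2.0 * ub / R**2  # u_z = 2 ub - c r^2
    kz = np.pi / L

    def velocity(pts: np.ndarray) -> np.ndarray:
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        r2 = x * x + y * y
        inside = r2 <= R * R
        s = Om * np.sin(kz * z)
        u = np.zeros((pts.shape[0], 3))
        u[:, 0] = np.where(inside, -s * y, 0.0)
        u[:, 1] = np.where(inside, s * x, 0.0)
        u[:, 2] = np.where(inside, 2.0 * ub - c * r2, 0.0)
        return u

    def gradient(pts: np.ndarray) -> np.ndarray:
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        inside = (x * x + y * y) <= R * R
        s = Om * np.sin(kz * z)
        ds = Om * kz * np.cos(kz * z)
        g = np.zeros((pts.shape[0], 3, 3))
        g[:, 0, 1] = np.where(inside, -s, 0.0)
        g[:, 0, 2] = np.where(inside, -ds * y, 0.0)
        g[:, 1, 0] = np.where(inside, s, 0.0)
        g[:, 1, 2] = np.where(inside, ds * x, 0.0)
        g[:, 2, 0] = np.where(inside, -2.0 * c * x, 0.0)
        g[:, 2, 1] = np.where(inside, -2.0 * c * y, 0.0)
        return g

    return velocity, gradient


def poiseuille_pipe(
    spec: PipeSpec = PipeSpec(),
    resolution: int = 33,
    length: Optional[float] = None,
) -> FlowField:
    """Fully developed laminar flow in a straight rigid vessel.

    u_z(r) = 2 u_bar (1 - (2r/D)^2): centreline velocity 2 u_bar, no slip at
    the wall, wall shear rate 8 u_bar / D. The analytic gradient closure is
    attached; points outside the lumen (r > D/2) are masked.
    """
    if spec.swirl_rate != 0.0:
        raise ValueError("poiseuille_pipe requires swirl_rate == 0; use swirling_pipe")
    return _build_pipe(spec, resolution, length)


def swirling_pipe(
    spec: PipeSpec,
    resolution: int = 33,
    length: Optional[float] = None,
) -> FlowField:
    """Poiseuille profile with a superposed axially developing swirl.

    u_theta(r, z) = Omega r sin(pi z / L): the twist builds up along the
    pipe, so the axial gradient of the swirl adds a shear component that the
    purely radial Poiseuille shear does not have. Wherever both are active
    the local maximum-shear plane no longer contains the velocity vector and
    the eigenvector and velocity–vorticity orientation models pick
    measurably different axes — a desk-scale surrogate for curved-vessel
    secondary flow.
    """
    if spec.swirl_rate <= 0.0:
        raise ValueError("swirling_pipe requires swirl_rate > 0")
    return _build_pipe(spec, resolution, length)


def _build_pipe(spec: PipeSpec, resolution: int, length: Optional[float]) -> FlowField:
    x, y, z, R = _pipe_grid(spec, resolution, length)
    vel_fn, grad_fn = _pipe_velocity_and_gradient(spec, R, z[-1] - z[0])
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
    u = vel_fn(pts).reshape(X.shape + (3,))
    mask = (X**2 + Y**2) <= R**2
    return FlowField(x=x, y=y, z=z, velocity=u, gradient_fn=grad_fn, mask=mask)


def uniform_flow(speed: float = 0.01, resolution: int = 5, box: float = 0.01) -> FlowField:
    """Spatially constant velocity along +z — zero gradient everywhere."""
    ax = np.linspace(0.0, box, resolution)
    u = np.zeros((resolution, resolution, resolution, 3))
    u[..., 2] = speed
    return FlowField(
        x=ax, y=ax, z=ax, velocity=u,
        gradient_fn=lambda pts: np.zeros((pts.shape[0], 3, 3)),
    )


def random_solenoidal_field(
    seed: int,
    box: float = 1.0,
    smoothness: float = 1.0,
    amplitude: float = 1.0,
    resolution: int = 17,
    n_modes: int = 8,
) -> FlowField:
    """Random smooth divergence-free velocity field for property testing.

    The velocity is the curl of a random Fourier vector potential,
    u = sum_m sin(k_m . x + phi_m) (a_m x k_m), so div u = 0 holds exactly
    and the gradient closure is analytic. ``smoothness`` scales the inverse
    wavenumber magnitude (larger = smoother); ``amplitude`` sets the rms
    velocity. Deterministic per seed.
    """
    if box <= 0 or amplitude < 0:
        raise ValueError("box and amplitude must be positive (amplitude may be 0)")
    rng = np.random.default_rng(seed)
    kmag = 2.0 * np.pi / (box * max(smoothness, 1e-6))
    k = rng.normal(size=(n_modes, 3)) * kmag
    a = rng.normal(size=(n_modes, 3))
    phase = rng.uniform(0, 2 * np.pi, size=n_modes)
    coef = np.cross(a, k)  # (a x k): k . (a x k) = 0 => solenoidal

    def velocity(pts: np.ndarray) -> np.ndarray:
        arg = pts @ k.T + phase  # (N, m)
        return np.sin(arg) @ coef

    def gradient(pts: np.ndarray) -> np.ndarray:
        arg = pts @ k.T + phase
        # du_i/dx_j = sum_m cos(arg_m) coef_{m,i} k_{m,j}
        return np.einsum("nm,mi,mj->nij", np.cos(arg), coef, k)

    ax = np.linspace(0.0, box, resolution)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
    u = velocity(pts)
    rms = np.sqrt(np.mean(np.sum(u**2, axis=1)))
    scale = amplitude / rms if rms > 0 and amplitude > 0 else (0.0 if amplitude == 0 else 1.0)
    coef = coef * scale
    u = velocity(pts)
    return FlowField(
        x=ax, y=ax, z=ax,
        velocity=u.reshape(X.shape + (3,)),
        gradient_fn=gradient,
    )


def fd_gradient(field: FlowField) -> np.ndarray:
    """Finite-difference velocity gradient, (nx, ny, nz, 3, 3).

    Second-order central differences in the interior and second-order
    one-sided stencils at the boundaries (numpy.gradient, edge_order=2);
    exact for velocity fields of polynomial degree <= 2 in the interior.
    """
    for name, ax in (("x", field.x), ("y", field.y), ("z", field.z)):
        if ax.size < 3:
            raise ValueError(f"fd_gradient needs >= 3 points along {name}")
    g = np.empty(field.shape + (3, 3))
    for i in range(3):
        dx, dy, dz = np.gradient(
            field.velocity[..., i], field.x, field.y, field.z, edge_order=2
        )
        g[..., i, 0], g[..., i, 1], g[..., i, 2] = dx, dy, dz
    return g
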