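"""Kinematics, stress spectra, the two orientation models, tensor assembly."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hemocond.fricke_core import (
    BloodParams,
    PrincipalConductivities,
    ShearState,
    principal_conductivities,
    stationary_conductivity,
)
from hemocond.flow_fields import uniform_flow
from hemocond.orientation_tensor import (
    OrientationAxis,
    anisotropy_indicator,
    apply_ohm,
    assemble_tensor,
    conductivity_field,
    eigenvector_axis,
    lamb_axis,
    rate_of_deformation,
    sign_normalize,
    stress_spectrum,
    viscous_stress,
    vorticity,
)


def simple_shear_grad(gdot: float) -> np.ndarray:
    """du_x/dy = gdot, everything else zero."""
    g = np.zeros((3, 3))
    g[0, 1] = gdot
    return g


class TestKinematics:
    def test_rigid_rotation_has_zero_deformation(self):
        g = np.array([[0.0, -1.0, 0.5], [1.0, 0.0, -2.0], [-0.5, 2.0, 0.0]])
        assert np.allclose(rate_of_deformation(g), 0.0)

    def test_simple_shear_deformation(self):
        D = rate_of_deformation(simple_shear_grad(3.0))
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = 1.5
        assert np.allclose(D, expected)

    def test_symmetric_gradient_unchanged(self, rng):
        g = rng.normal(size=(3, 3))
        g = g + g.T
        assert np.allclose(rate_of_deformation(g), g)

    def test_stress_is_linear_in_deformation(self, rng):
        D = rate_of_deformation(rng.normal(size=(3, 3)))
        assert np.allclose(viscous_stress(3.0 * D, 0.05), 3.0 * viscous_stress(D, 0.05))
        assert np.allclose(viscous_stress(D, 0.05), 0.1 * D)

    @pytest.mark.parametrize(
        "grad, expected",
        [
            (simple_shear_grad(2.0), [0.0, 0.0, -2.0]),
            # solid-body rotation about z at rate Omega: omega = 2 Omega e_z
            (np.array([[0.0, -0.7, 0.0], [0.7, 0.0, 0.0], [0.0, 0.0, 0.0]]),
             [0.0, 0.0, 1.4]),
        ],
    )
    def test_vorticity(self, grad, expected):
        assert np.allclose(vorticity(grad), expected)

    def test_irrotational_gradient(self, rng):
        g = rng.normal(size=(3, 3))
        assert np.allclose(vorticity(g + g.T), 0.0)


class TestStressSpectrum:
    def test_simple_shear_eigenvalues(self):
        s = 0.4
        tau = np.zeros((3, 3))
        tau[0, 1] = tau[1, 0] = s
        spec = stress_spectrum(tau)
        assert np.allclose(spec.eigenvalues, [s, 0.0, -s], atol=1e-12)
        assert float(spec.tau_max) == pytest.approx(2 * s)

    def test_isotropic_pressure_is_degenerate(self):
        spec = stress_spectrum(2.5 * np.eye(3))
        assert float(spec.tau_max) == pytest.approx(0.0, abs=1e-12)

    def test_nonsymmetric_rejected(self):
        t = np.zeros((3, 3))
        t[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            stress_spectrum(t)

    def test_tau_max_matches_rotation_search(self, rng):
        """tau_1 - tau_3 = twice the largest shear component over all plane
        orientations — checked against a brute-force search over random
        orthonormal frames, an independent route to the same quantity."""
        A = rng.normal(size=(3, 3))
        tau = A + A.T
        spec = stress_spectrum(tau)
        R = Rotation.random(200_000, random_state=rng).as_matrix()
        shear = np.abs(np.einsum("ki,ij,kj->k", R[:, :, 0], tau, R[:, :, 1]))
        # random-search maximum approaches from below at ~N^(-2/3)
        best = shear.max()
        assert best <= 0.5 * float(spec.tau_max) * (1 + 1e-12)
        assert float(spec.tau_max) == pytest.approx(2.0 * best, rel=5e-3)

    def test_eigenvectors_orthonormal(self, rng):
        A = rng.normal(size=(3, 3))
        spec = stress_spectrum(A + A.T)
        V = spec.eigenvectors
        assert np.allclose(V.T @ V, np.eye(3), atol=1e-10)


class TestEigenvectorAxis:
    def test_simple_shear_picks_gradient_direction(self, params):
        """u = (gdot*y, 0, 0): the shear-plane normal containing most of the
        flow is x-normal, so e_alpha = e_y."""
        tau = viscous_stress(rate_of_deformation(simple_shear_grad(1.0)),
                             params.blood_viscosity)
        spec = stress_spectrum(tau)
        axis = eigenvector_axis(spec, u=np.array([0.3, 0.0, 0.0]))
        assert axis.degenerate is None
        assert abs(axis.e_alpha @ np.array([0.0, 1.0, 0.0])) == pytest.approx(1.0, abs=1e-12)

    def test_candidates_orthonormal_and_orthogonal_to_e2(self, rng):
        A = rng.normal(size=(3, 3))
        spec = stress_spectrum(A + A.T)
        e1 = spec.eigenvectors[:, 0]
        e2 = spec.eigenvectors[:, 1]
        e3 = spec.eigenvectors[:, 2]
        plus = (e1 + e3) / np.sqrt(2)
        minus = (e1 - e3) / np.sqrt(2)
        assert np.linalg.norm(plus) == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(minus) == pytest.approx(1.0, abs=1e-10)
        assert plus @ minus == pytest.approx(0.0, abs=1e-10)
        assert plus @ e2 == pytest.approx(0.0, abs=1e-10)
        assert minus @ e2 == pytest.approx(0.0, abs=1e-10)

    def test_tie_takes_plus_branch(self, params):
        """Velocity along e2 projects equally (zero) on both candidates; the
        'otherwise' branch returns (e1 + e3)/sqrt(2)."""
        tau = viscous_stress(rate_of_deformation(simple_shear_grad(1.0)),
                             params.blood_viscosity)
        spec = stress_spectrum(tau)
        e2 = spec.eigenvectors[:, 1]
        plus = (spec.eigenvectors[:, 0] + spec.eigenvectors[:, 2]) / np.sqrt(2)
        axis = eigenvector_axis(spec, u=0.7 * e2)
        assert abs(axis.e_alpha @ plus) == pytest.approx(1.0, abs=1e-12)

    def test_zero_stress_flagged(self):
        spec = stress_spectrum(np.zeros((3, 3)))
        axis = eigenvector_axis(spec, u=np.array([1.0, 0.0, 0.0]))
        assert axis.degenerate == "zero-stress"


class TestLambAxis:
    def test_simple_shear_agrees_with_ev(self):
        u = np.array([0.5, 0.0, 0.0])
        omega = np.array([0.0, 0.0, -1.0])  # curl of u=(y,0,0)
        axis = lamb_axis(u, omega)
        assert axis.degenerate is None
        assert abs(axis.e_alpha @ np.array([0.0, 1.0, 0.0])) == pytest.approx(1.0)

    def test_parallel_vectors_degenerate(self):
        u = np.array([1.0, 2.0, 3.0])
        assert lamb_axis(u, 2.0 * u).degenerate == "parallel-u-omega"
        assert lamb_axis(np.zeros(3), u).degenerate == "zero-velocity"


class TestTensorAssembly:
    def test_isotropic_regardless_of_axis(self, rng):
        pc = PrincipalConductivities(0.5, 0.5)
        e = rng.normal(size=3)
        e /= np.linalg.norm(e)
        T = assemble_tensor(OrientationAxis(e, "EV"), pc)
        assert np.allclose(T, 0.5 * np.eye(3))

    def test_axis_aligned(self):
        pc = PrincipalConductivities(0.4, 0.6)
        T = assemble_tensor(OrientationAxis(np.array([0.0, 0.0, 1.0]), "EV"), pc)
        assert np.allclose(T, np.diag([0.6, 0.6, 0.4]))

    def test_spectrum_roundtrip_random_axis(self, rng):
        """Eigen-decomposition of the assembled tensor recovers
        {sigma_alpha, sigma_beta, sigma_beta} and the axis."""
        pc = PrincipalConductivities(0.45, 0.6)
        for _ in range(20):
            e = rng.normal(size=3)
            e /= np.linalg.norm(e)
            T = assemble_tensor(OrientationAxis(e, "VV"), pc)
            assert np.allclose(T, T.T)
            w, v = np.linalg.eigh(T)
            assert np.allclose(w, [0.45, 0.6, 0.6], atol=1e-12)
            assert abs(v[:, 0] @ e) == pytest.approx(1.0, abs=1e-9)
            # sign invariance
            assert np.allclose(T, assemble_tensor(OrientationAxis(-e, "VV"), pc))

    def test_degenerate_axis_needs_isotropy(self):
        pc = PrincipalConductivities(0.4, 0.6)
        axis = OrientationAxis(np.zeros(3), "VV", degenerate="parallel-u-omega")
        with pytest.raises(ValueError, match="degenerate"):
            assemble_tensor(axis, pc)
        iso = assemble_tensor(
            OrientationAxis(np.zeros(3), "VV", degenerate="zero-stress"),
            PrincipalConductivities(0.5, 0.5),
        )
        assert np.allclose(iso, 0.5 * np.eye(3))

    def test_ohm_in_principal_frame(self):
        pc = PrincipalConductivities(0.4, 0.6)
        e = np.array([0.0, 0.0, 1.0])
        T = assemble_tensor(OrientationAxis(e, "EV"), pc)
        assert np.allclose(apply_ohm(T, 2.0 * e), 0.8 * e)          # E || axis
        perp = np.array([1.0, 0.0, 0.0])
        assert np.allclose(apply_ohm(T, perp), 0.6 * perp)          # E _|_ axis
        assert np.allclose(apply_ohm(0.5 * np.eye(3), [1.0, 2.0, 3.0]),
                           [0.5, 1.0, 1.5])


class TestAnisotropyIndicator:
    def test_isotropic_zero(self):
        assert anisotropy_indicator(PrincipalConductivities(0.5, 0.5)) == 0.0

    def test_limit_half(self):
        assert anisotropy_indicator(PrincipalConductivities(1e-12, 0.6)) == pytest.approx(0.5, abs=1e-9)

    def test_chain_value(self, params):
        """At the 1.9 1/s shear chain: (sigma_b - sigma_a)/(2 sigma_b + sigma_a)."""
        pc = principal_conductivities(params, ShearState.from_shear_rate(1.9, params))
        assert float(anisotropy_indicator(pc)) == pytest.approx(0.0830389, abs=1e-5)


class TestFrameEquivariance:
    def test_fifty_random_rotations(self, params, rng):
        """Rotating u and grad u rotates e_alpha (both models) and conjugates
        the tensor, for a generic shear state."""
        g0 = rng.normal(size=(3, 3))
        g0 -= np.eye(3) * np.trace(g0) / 3.0  # make incompressible
        u0 = rng.normal(size=3)
        eta = params.blood_viscosity

        def compute(g, u):
            tau = viscous_stress(rate_of_deformation(g), eta)
            spec = stress_spectrum(tau)
            shear = ShearState.from_stress(spec.tau_max, params)
            pc = principal_conductivities(params, shear)
            ev = eigenvector_axis(spec, u)
            vv = lamb_axis(u, vorticity(g))
            return (
                ev.e_alpha,
                vv.e_alpha,
                assemble_tensor(ev, pc),
                assemble_tensor(vv, pc),
            )

        e_ev, e_vv, T_ev, T_vv = compute(g0, u0)
        for _ in range(50):
            R = Rotation.random(random_state=rng).as_matrix()
            re_ev, re_vv, rT_ev, rT_vv = compute(R @ g0 @ R.T, R @ u0)
            assert abs(abs(re_ev @ (R @ e_ev)) - 1.0) < 1e-8
            assert abs(abs(re_vv @ (R @ e_vv)) - 1.0) < 1e-8
            assert np.allclose(rT_ev, R @ T_ev @ R.T, atol=1e-8)
            assert np.allclose(rT_vv, R @ T_vv @ R.T, atol=1e-8)


class TestConductivityField:
    def test_uniform_flow_is_stationary_isotropic(self, params):
        field = conductivity_field(uniform_flow(), params, "EV")
        sigma0 = stationary_conductivity(params)
        assert np.all(field.degenerate == "zero-stress")
        assert np.allclose(field.tensors, sigma0 * np.eye(3), atol=1e-12)
        assert np.allclose(field.eta, 0.0)

    def test_unknown_model_rejected(self, params):
        with pytest.raises(ValueError, match="model"):
            conductivity_field(uniform_flow(), params, "XX")

    def test_assembled_spectra_match_principal_values(self, params):
        from hemocond.flow_fields import PipeSpec, swirling_pipe

        flow = swirling_pipe(PipeSpec(swirl_rate=0.8), resolution=9)
        field = conductivity_field(flow, params, "EV")
        ok = field.valid
        T = field.tensors[ok]
        w = np.linalg.eigvalsh(T)
        sa = field.sigma_alpha[ok]
        sb = field.sigma_beta[ok]
        assert np.allclose(w[:, 0], sa, rtol=1e-9)
        assert np.allclose(w[:, 1], sb, rtol=1e-9)
        assert np.allclose(w[:, 2], sb, rtol=1e-9)


def test_sign_normalize_first_component_positive(rng):
    v = rng.normal(size=(40, 3))
    out = sign_normalize(v)
    for row in out:
        lead = row[np.abs(row) > 1e-12 * np.linalg.norm(row)][0]
        assert lead > 0
    assert np.allclose(np.abs(out), np.abs(v))
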