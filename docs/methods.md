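# Methods notes

## Physical picture and assumptions

Blood is treated as a Newtonian suspension of non-conductive oblate
spheroidal red blood cells (RBCs) in conductive plasma, at constant
hematocrit. At low shear the cells tumble and their short axes are
isotropically distributed; with increasing shear an increasing fraction
enters the steady tank-treading regime, in which the cell keeps a fixed
ellipsoidal shape and orientation while its membrane circulates. A
tank-treading cell sits with its flat faces in a plane of maximum shear
stress that (mostly) contains the velocity vector — equivalently, in the
experimentally studied unidirectional flows, the plane spanned by velocity
and vorticity. In general 3D flow these two planes differ, which motivates
the two orientation models:

- **EV** — short axis along the maximum-shear-plane normal chosen by the
  velocity-projection rule (of the two candidate normals (e₁ ∓ e₃)/√2 built
  from the extreme stress eigenvectors, take the one making the *larger*
  angle with u; an exact tie takes the (e₁ + e₃)/√2 branch).
- **VV** — short axis along the Lamb vector u × ω.

The conductivity tensor is transversely isotropic about the short-axis
direction, σ = σ_α e_α⊗e_α + σ_β (I − e_α⊗e_α), with principal values from
Maxwell–Fricke suspension theory evaluated at the *deformed* aspect ratio
and interpolated between random and aligned orientation states by the
aligned fraction f(γ̇_max). Everything is pointwise: no orientation
relaxation dynamics, no feedback of alignment on viscosity (the
constitutive law stays isotropic), no Jeffery-orbit tumbling model, and
hematocrit is a constant, not a field.

## Parameters (strict SI)

| parameter | symbol | default | unit | meaning |
|---|---|---|---|---|
| aspect_ratio | λ | 0.38 | – | undeformed a/b of the oblate RBC |
| plasma_conductivity | σ_pl | 1.3 | S/m | plasma conductivity |
| hematocrit | H | 0.45 | – | RBC volume fraction |
| short_semiaxis | a | 1.52e-6 | m | RBC short semiaxis |
| long_semiaxis | b | 4e-6 | m | RBC long semiaxis |
| membrane_shear_modulus | μ | 1e-5 | kg/s² | resists shear deformation |
| orientation_constant | k | 1 | s^(−1/2) | sets the alignment transition |
| plasma_viscosity | η_pl | 4.8e-2 | kg/(m·s) | see viscosity note below |
| blood_density | ρ_bl | 1060 | kg/m³ | whole blood |
| blood_viscosity_override | η_bl | 1060 × 4.59e-5 | kg/(m·s) | see below |

**Blood-viscosity note.** The tabulated constants are mutually
inconsistent: Merrill's relation η_bl = η_pl(1 + 2.5H + 7.32H²) applied to
η_pl = 4.8e-2 gives η_bl ≈ 0.173, i.e. ν_bl ≈ 1.63e-4 m²/s, whereas the
reference kinematic viscosity is ν_bl = 4.59e-5 m²/s (which itself implies
η_pl ≈ 1.35e-2 — a value consistent with plasma being mostly water). All
published downstream numbers (Re = 6.96/11.49, λ_σ ≈ 0.77) follow from
ν_bl, so `BloodParams` pins η_bl = ρ_bl·ν_bl = 4.8654e-2 kg/(m·s) through
`blood_viscosity_override` and uses it everywhere the dynamic viscosity
appears. Setting the override to `None` falls back to Merrill's relation on
the tabulated η_pl.

**Alignment regimes.** Shear rates are labelled low/intermediate/high at
the aligned fractions f = 0.20 and f = 0.80. The boundaries follow from
inverting f in closed form, γ̇ = (f·k/(1−f))², giving 0.0625 and 16 s⁻¹ at
k = 1; the classifier recomputes them from k rather than hard-coding the
numbers, so a non-default k moves the labels consistently.

## Numerical choices

- **Spectral decomposition** via `numpy.linalg.eigh`, eigenvalues sorted
  descending; every eigenvector and orientation axis is sign-normalized so
  its first non-negligible component is positive (the physics is
  sign-invariant; reproducible output needs a convention).
- **Degeneracy.** Where τ_max < ε_τ (default 1e-12 Pa) no shear plane
  exists; where |u×ω| < ε_L·|u||ω| (default ε_L = 1e-8) or u ≈ 0 the Lamb
  axis is undefined. Such points are flagged with a reason and assembled
  isotropically with the random-orientation conductivity (the C_r path) —
  continuous with the regular branch, since f(γ̇) → 0 as the stress
  vanishes. For the VV model, `vv_fallback="ev"` instead borrows the EV
  axis where the stress spectrum still defines one. Degenerate points are
  excluded from comparison statistics and counted separately, since an
  angle against an undefined axis is meaningless.
- **Repeated intermediate eigenvalue** (τ₁ = τ₂ or τ₂ = τ₃ with
  τ₁ − τ₃ still finite): only the extreme eigenvectors enter the EV rule,
  so the axis construction proceeds with whatever basis the decomposition
  returns for the degenerate subspace.
- **Angles.** ψ_α is computed as atan2(|a×b|, |a·b|) and ψ_σ in the chord
  form 2·arcsin(‖Â−B̂‖_F/2); the closed-form link is evaluated as
  ψ_σ = 2·arcsin( sinψ_α·(1−λ_σ)/√(2(λ_σ²+2)) ), algebraically identical to
  the cosine form but exact at the ψ_σ = 0 boundary. The naive arccos
  expressions bottom out near 1e-6 degrees (one ulp below cosθ = 1), which
  matters when verifying that two fields coincide. arccos arguments, where
  used, are clamped to [0, 1] with a 1e-12 guard.
- **Sphere limit.** M(λ) has a removable 0/0 singularity at λ = 1; for
  λ > 1 − 1e-6 the series limit M = 2/3 is returned exactly, reproducing
  Maxwell's sphere result σ = σ_pl(1−H)/(1+H/2) to 1e-9 relative.
- **Shear-state redundancy.** τ_max and γ̇_max are related by the
  constitutive law γ̇ = τ/(2η_bl); `ShearState` derives one from the other,
  and a constructor taking both rejects pairs inconsistent beyond 1e-6
  relative, because a silent mismatch would corrupt the alignment
  interpolation. In field computations γ̇_max is always derived from the
  stress spectrum, never from flow-specific scalar formulas.
- **Finite differences** are 2nd-order central in the interior and
  2nd-order one-sided at boundaries; analytic generators attach exact
  gradient closures instead. Incompressibility is monitored via
  max |tr ∇u| and a warning is raised above 1e-6·‖∇u‖ (fields read from
  truncated data, e.g. a pipe field with the exterior zeroed, trigger it
  legitimately at the wall).
- **Formats.** CSV is the archival format (17 significant digits, rows
  keyed by coordinates, read back with correctly rounded parsing); VTK
  legacy ASCII structured-points output serves visualization tools.

## Benchmark flows: what they emulate, and what they do not

- `poiseuille_pipe` — the fully developed laminar straight-vessel case
  (D = 0.04 m, ū = 0.008 m/s, Re ≈ 7). Both models provably coincide here
  (axes radial); σ_β peaks and σ_α dips at the wall; the anisotropy
  indicator η = (σ_β−σ_α)/(2σ_β+σ_α) grows monotonically with radius.
- `swirling_pipe` — the in-repo flow on which the models *disagree*. A
  plain solid-body swirl u_θ = Ωr superposed on the Poiseuille profile does
  not do this: for any axisymmetric unidirectional flow
  u = u_θ(r)e_θ + u_z(r)e_z the stress is a local simple shear with radial
  gradient direction, the EV rule selects e_r, and
  u×ω = [u_θ(u_θ' + u_θ/r) + u_z u_z']·e_r is radial too, so ψ_α ≡ 0
  wherever both axes are defined. The twist is therefore made to develop
  along the axis, u_θ(r,z) = Ωr·sin(πz/L) — still exactly divergence-free —
  whose axial swirl gradient adds a shear component outside the rz-plane
  and separates the models (ψ_α up to ~90° at the default Ω = 0.8 s⁻¹,
  with ψ_σ capped by the closed-form bound at the observed λ_σ,min). This
  is a desk-scale surrogate for curved-vessel (aortic-arch) secondary flow;
  the published aorta geometry itself is not reproduced, so those field
  maps are only matched qualitatively (criterion: the models *do* diverge
  where swirl and axial shear coexist, and the analytic bound ~11.6° holds).
- `random_solenoidal_field` — curl of a random Fourier vector potential:
  exactly divergence-free, analytic gradient, deterministic per seed. Used
  for property testing (frame equivariance, spectra); it emulates smooth
  incompressible velocity variation, not turbulence or boundary layers.

None of these are solutions of the Navier–Stokes equations with realistic
inflow; passing tests on them validates the conductivity pipeline, not any
CFD. Real CFD fields enter through the readers and the finite-difference
gradient path.

Default problem sizes: 33³ grids for field-level tests and demos (the
analytic-gradient checks are resolution-independent; a 64³ field takes a
few seconds on one core).

## Known limitations

- **High-shear pathology of the composed chain.** The random-orientation
  factor C_r is evaluated at the deformed aspect ratio, and
  λ_d ∝ τ_max⁻³ makes C_r(λ_d) grow like τ_max³ while the random fraction
  1 − f decays only like γ̇^(−1/2). Beyond γ̇_max ≈ a few hundred s⁻¹ the
  product (1−f)·C_r dominates C_β, so σ_β collapses instead of approaching
  the fully aligned value; the formal γ̇ → ∞ limit of the chain is (0, 0),
  not the aligned pair. This is irrelevant at the shear rates of the
  reference flows (≤ 2 s⁻¹) but means the chain should not be extrapolated
  to arterial wall shear rates of order 10³ s⁻¹ without revisiting the
  deformation law. The alignment-limit property is accordingly verified
  with deformation frozen (rigid membrane).
- The oblate-spheroid idealization ignores the triaxial shape of real
  tank-treading RBCs (which would give three distinct principal
  conductivities), biconcave rest shape, and shape pathologies.
- Constant hematocrit; no temperature dependence of σ_pl; Newtonian
  rheology only (shear thinning, thixotropy, viscoelasticity omitted);
  rigid walls; no electromagnetic forward simulation beyond pointwise
  Ohm's law J = σ·E.
- The anisotropy indicator is implemented as η = (σ_β−σ_α)/(2σ_β+σ_α) —
  the difference of the extreme principal conductivities over the sum of
  all three — which is the reading consistent with its verbal definition;
  it equals 0 at isotropy and approaches 1/2 as σ_α/σ_β → 0.
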