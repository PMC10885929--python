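# hemocond

Anisotropic electrical conductivity of flowing blood, computed as a tensor
field from a 3D velocity field.

## The problem

Bioimpedance diagnostics (impedance cardiography and plethysmography) read
physiology off the electrical conductivity of blood, and that conductivity
depends on the local hemodynamics: red blood cells (RBCs) are
non-conductive oblate spheroids that deform, orient, and align under shear.
Where RBCs align, the plasma between them forms channel-like conductive
paths along the cell faces and the conductivity becomes *anisotropic* —
larger in the plane of the cell faces than along their short axes. 1D
models of this effect exist for straight-vessel flow; `hemocond`
implements two closely related models that extend it to arbitrary 3D flow
fields, for anyone post-processing CFD (or analytic) velocity data into
conductivity input for electromagnetic simulation.

## The model

At each point of the flow, with velocity gradient ∇u:

1. **Kinematics** — rate of deformation D = (∇u + ∇uᵀ)/2, Newtonian stress
   τ = 2η<sub>bl</sub>D, spectral decomposition τ₁ ≥ τ₂ ≥ τ₃ with
   eigenvectors e₁, e₂, e₃. The maximum shear stress is
   τ<sub>max</sub> = τ₁ − τ₃ and the maximum shear rate
   γ̇<sub>max</sub> = τ<sub>max</sub>/(2η<sub>bl</sub>).
2. **Scalar physics (Maxwell–Fricke)** — the cell deforms,
   λ_d = λ(1 + τ<sub>max</sub>b/4μ)⁻³; shape factor
   M(λ) = (φ − sinφ cosφ)cosφ/sin³φ with φ = arccos λ; orientation factors
   C_a = 1/M, C_b = 2/(2−M), random average C_r = (C_a + 2C_b)/3; aligned
   fraction f(γ̇) = γ̇/(γ̇ + k√γ̇) interpolates C<sub>α,β</sub> = f·C_{a,b} +
   (1−f)·C_r; finally σ<sub>α,β</sub> = σ_pl(1−H)/(1 + (C<sub>α,β</sub>−1)H).
3. **Orientation** — the dominant RBC short-axis direction e<sub>α</sub>, by
   either of two models:
   * **EV** (eigenvector): the maximum-shear-plane normal
     (e₁ ∓ e₃)/√2 that makes the larger angle with the velocity;
   * **VV** (velocity–vorticity): the normalized Lamb vector u×ω / |u×ω|.
4. **Assembly** — σ = σ<sub>α</sub>(e<sub>α</sub>⊗e<sub>α</sub>) +
   σ<sub>β</sub>(I − e<sub>α</sub>⊗e<sub>α</sub>), a transversely isotropic
   tensor with principal values {σ<sub>α</sub>, σ<sub>β</sub>, σ<sub>β</sub>}.

The two models coincide in unidirectional and axisymmetric shear flows
(pipes, channels) and differ in genuinely 3D flows. The disagreement is
quantified by the axis angle ψ<sub>α</sub> = arccos|⟨e<sub>α</sub>ᴱⱽ,
e<sub>α</sub>ⱽⱽ⟩| and the Frobenius tensor angle ψ<sub>σ</sub>, which obey
the closed-form relation

cos ψ<sub>σ</sub> = [λ<sub>σ</sub>²cos²ψ<sub>α</sub> +
2λ<sub>σ</sub>(1−cos²ψ<sub>α</sub>) + 1 + cos²ψ<sub>α</sub>] /
(λ<sub>σ</sub>² + 2),  λ<sub>σ</sub> = σ<sub>α</sub>/σ<sub>β</sub>.

Because blood's anisotropy is limited (λ<sub>σ</sub> ≳ 0.77 at the shear
rates of the reference flows), ψ<sub>σ</sub> stays below ~11.6° even when
the axes disagree by 90°.

## Worked example

```sh
$ hemocond demo-pipe
straight vessel: D = 0.04 m, u_bar = 0.008 m/s
nu_bl = 4.59e-05 m^2/s  ->  Re = 6.97
max |psi_alpha| over interior points = 3.75e-14 deg (models coincide in unidirectional shear)
     r [m]  sigma_alpha   sigma_beta       eta
    0.0000      0.54949      0.54949   0.00000
    0.0025      0.50341      0.57508   0.04334
    0.0050      0.49221      0.58187   0.05414
    ...
    0.0200      0.46539      0.59728   0.07946
sigma_beta peaks at the wall, sigma_alpha dips there; eta grows monotonically from the centreline.
```

This is the laminar straight-vessel case (Re ≈ 7): on the centreline the
shear vanishes, RBC orientation is random, and the conductivity is the
isotropic stationary-blood value 0.549 S/m. Toward the wall the shear rate
rises to 8ū/D = 1.6 s⁻¹, cells align with faces parallel to the flow, the
tangential conductivity σ<sub>β</sub> rises to 0.597 S/m while the radial
σ<sub>α</sub> falls to 0.465 S/m, and the anisotropy indicator
η = (σ<sub>β</sub>−σ<sub>α</sub>)/(2σ<sub>β</sub>+σ<sub>α</sub>) grows
monotonically. Both orientation models give the radial direction here — the
angle between them is numerical zero.

```sh
$ hemocond demo-aorta-bound
gamma_dot_max = 1.9 1/s  (tau_max = 0.184885 Pa)
lambda_sigma = sigma_alpha/sigma_beta = 0.77
psi_sigma_max (at psi_alpha = 90 deg) = 11.6 deg
```

At the peak shear rate of a low-Re aorta-like flow (1.9 s⁻¹), the
conductivity ratio bottoms out at 0.77, capping the worst-case tensor
disagreement between the models at 11.6°.

The models are separated by the bundled swirling-pipe flow (a Poiseuille
profile with an axially developing twist):

```sh
$ hemocond compare --generator swirl --resolution 21
...
psi_alpha_max     = 90
psi_sigma_max     = 11.5924
lambda_sigma_min  = 0.766236
```

Library use mirrors the CLI:

```python
from hemocond import BloodParams, PipeSpec, swirling_pipe, conductivity_field, compare_fields

flow = swirling_pipe(PipeSpec(swirl_rate=0.8), resolution=33)
params = BloodParams()
sigma_ev = conductivity_field(flow, params, "EV")
sigma_vv = conductivity_field(flow, params, "VV")
per_point, summary = compare_fields(sigma_ev, sigma_vv)
```

Velocity fields can also be read from VTK legacy ASCII or CSV files
(`hemocond compute --input field.vtk --model EV --output sigma.csv`); see
`hemocond --help`.

## Layout

- `src/hemocond/fricke_core.py` — scalar Maxwell–Fricke physics
- `src/hemocond/orientation_tensor.py` — kinematics, EV/VV axes, tensor assembly
- `src/hemocond/flow_fields.py` — analytic benchmark flows, rheology scalars, finite differences
- `src/hemocond/model_comparison.py` — ψ<sub>α</sub>, ψ<sub>σ</sub>, closed form, field comparison
- `src/hemocond/cli_io.py`, `src/hemocond/cli.py` — formats, config, command line
- `docs/methods.md` — modelling assumptions, parameter provenance, numerical choices
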