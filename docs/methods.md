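# Methods

## The model

`cgblob` treats a molecule as a *rigid blob*: a fixed set of interaction
sites ("united atoms") at positions ρ_α about the centre of mass. Two blobs
A and B whose atoms all interact through one pair potential U(r) have the
exact interaction energy

    E(R, Ω) = Σ_α Σ_β U(|R + ρ_αβ|),        ρ_αβ = ρ_α − ρ_β,

with R the centre-to-centre vector. Taylor-expanding U about |R| and
collecting terms by powers of ρ factorises the energy into radial
coefficients times purely geometric angular parts:

    V(R, Ω) = Σ_(m,n) V(mn)(R) · Θ(mn)(Ω),
    V(mn)   = [1 / (n! (m−n)!!)] R^n (1/R d/dR)^((m+n)/2) U(R),
    Θ(mn)   = Σ_αβ (R̂·ρ_αβ)^n |ρ_αβ|^(m−n),

where the index pairs satisfy m+n and m−n both even (n = m, m−2, … down to
0 or 1). Truncation at m ≤ 4 is implemented; "order 0" keeps only (0,0)
(the bare centre potential scaled by N_A N_B), "order 3" all m ≤ 3.

The computational point of the method is that Θ(mn) needs no atom loops.
With the interaction moment tensors Γ(m) = Σ_α ρ_α⊗…⊗ρ_α (Γ(0) = atom
count), the pair difference moment

    M(m) = Σ_αβ ρ_αβ^⊗m = Σ_q (−1)^(m−q) C(m,q) Sym[Γ_A(q) ⊗ Γ_B(m−q)]

is fully symmetric, and

    Θ(mn) = ⟨ M(m), Sym[R̂^⊗n ⊗ δ^⊗(m−n)/2] ⟩.

This single contraction identity replaces the nine case-by-case angular
formulas; it is validated against the explicit double sum (the "all-atom
oracle") at machine precision for every (m,n) on random blob geometries.
It also yields closed derivatives: the force follows from V′(mn) and from
∂Θ/∂R̂ projected onto the sphere, and the torque on a blob from the action
of the rotation generator on its Γ(q) (contracting the Levi-Civita symbol
with Γ(q) and ∂Θ/∂Γ(q)). Both are verified against symmetric finite
differences of the energy, which remain available as the reference path.

Radial coefficients are analytic for any potential exposing exact
derivatives: (1/R d/dR)^k expands into Σ_j c_kj U^(j) R^(j−2k) with integer
coefficients generated by recursion. Morse (De, α, R0) and a generalised
Lennard-Jones (ε, σ, exponents a > b > 0) are built in; the Lennard-Jones
coefficients additionally have the double-factorial closed form, kept as an
independent cross-check of the operator route.

### Validity domain

The expansion is a Taylor series in ρ_αβ about R, so its convergence is
governed by the potential's own length scale, not only by ρ/R. For an
exponential (Morse) U the all-atom sum is amplified by ⟨e^(2αρ_z)⟩ relative
to N² U(R); with αρ ≳ 1 no finite order captures that factor and the
*relative* series error saturates with distance (≈ 57–72 % for the C60 cage
with the atomic Morse, α = 1.3 Å⁻¹, ρ = 3.54 Å), while the *absolute* error
still decays monotonically with both order and distance. For inverse-power
potentials the amplification is polynomial and the relative error does
vanish with distance (a graphitic 12-6 C60 pair is inside 5 % at 16 Å at
fourth order). Property tests that probe order-convergence therefore draw
random blobs with σ = 0.5 Å (αρ ≲ 1.3), inside the method's own domain.

## The C60 cage

The truncated icosahedron is built from first principles: each vertex of a
regular icosahedron (edge L) is cut at fraction t along its five edges,
giving 60 pentagon edges of length tL and 30 hexagon–hexagon edges of
length (1−2t)L. Prescribing the two bond lengths b_CC (pentagon, C–C
single) and b_CC′ (hexagon–hexagon, C=C double) fixes L = 2b_CC + b_CC′ and
t = b_CC/L exactly. With the quantum-chemistry bond lengths 1.450/1.386 Å
the cage radius is 3.536 Å. All vertices are exactly equidistant from the
centre and the icosahedral point group holds to machine precision, so the
moment tensors are *exactly* isotropic through rank 4 (ranks ≤ 4 admit no
icosahedral invariant beyond δ-combinations): odd ranks vanish, Γ(2) ∝ δ,
Γ(4) ∝ Sym(δ⊗δ). Every angular part of a C60 pair is then an orientation-
independent constant and the truncated series is a radial potential.

## Effective single-site parameterisation

The coarse-grained C60 model is parameterised against the exact all-atom
Morse sum (atomic parameters De = 0.074 kcal/mol, α = 1.3 Å⁻¹, R0 = 4.1 Å,
the standard Girifalco-calibrated set). Reference curves are generated for
the three face-to-face approaches (hex–hex, hex–pent, pent–pent), which
coincide within ≈ 9 % of the well depth near the minimum and within 5 %
beyond 10.4 Å, and are averaged with equal weights. A single-site Morse
scaled by N_A N_B = 3600 (so De is quoted per atom pair) with α held at
1.3 Å⁻¹ is then least-squares fitted through the order-truncated series
over the window [0.9, 1.6]·R_min, chosen to bracket the well without
letting the steep repulsive wall dominate the unweighted residual. The
orientation averaging, the equal weights, the window and the unweighted
loss are this package's choices where the procedure is otherwise
underdetermined. At order 0 this fit lands at the all-atom minimum
(R0 ≈ 9.89 Å, De ≈ 0.0019 kcal/mol per atom pair, i.e. a ≈ 7.0 kcal/mol
molecular well at the position of the all-atom liquid's first RDF peak).

For the liquid simulations the effective model is the fitted single-site
Morse itself — molecules are structureless blobs interacting through
3600·U_Morse. The truncation order enters through *which* fitted parameter
set is used, not by re-expanding the effective potential: re-applying the
series machinery to the effective Morse with the cage's moment tensors
would be outside the expansion's validity domain (αρ ≈ 4.6) and produces a
spurious deeper well. The liquid-state reproductions below use the
literature effective parameter sets (order 0: R0 = 9.5 Å, De = 0.0017
kcal/mol; order 3: R0 = 9.65 Å, De = 0.00177 kcal/mol, both α = 1.3 Å⁻¹,
3600-scaled) directly as inputs.

## Molecular dynamics

Rigid-body NVT dynamics in a cubic periodic box:

* **Translation** — leapfrog Verlet. **Rotation** — body-frame Euler
  equations, I dω/dt = τ_body − ω×(Iω), integrated by a quaternion
  leapfrog: a half-step estimate of ω feeds the gyroscopic term, and the
  orientation advances by the exact rotation exp(ω dt), keeping
  quaternions normalised. Structureless blobs carry no rotational state.
* **Thermostat** — velocity rescaling of linear and angular velocities by
  √(T/T_kin), T_kin from equipartition over 6 degrees of freedom per rigid
  body (3 for point blobs). Default intervals: every 10 steps during
  equilibration, every 100 during production.
* **Cutoff** — default 3σ*, where σ* (the simulation length unit) is the
  potential's equilibrium distance, clamped below half the box edge. The
  radial CG path shifts the effective potential to zero at the cutoff
  (continuous energy, conservative forces); the all-atom engine applies an
  atom–atom cut-and-shift with molecule pairs screened at cutoff + 2×blob
  radius; the anisotropic CG path truncates without shift (its cutoff
  energy is orientation dependent; NVE work with it should place the
  cutoff beyond interaction range).
* **Initialisation** — FCC lattice (N = 4k³) at the box size implied by
  the density and molar mass; uniform random orientations; Maxwell–
  Boltzmann linear and angular velocities with net momentum removed and an
  exact rescale to the target temperature. How the reference work drew its
  initial conditions is unstated; this seeded scheme is the package's own.
* **Engines** — `allatom` (exact atom sums; the benchmark), and `cg`,
  which automatically uses the radial fast path when the template's
  tensors are isotropic (point blobs, icosahedral cages) and the full
  anisotropic series with analytic forces and torques otherwise. The two
  CG paths agree to round-off on isotropic templates; the all-atom and CG
  engines coincide exactly for point blobs.
* **Timestep** — default 5 fs for the CG liquid (the effective well's
  vibrational period is ≈ 1.3 ps), 2 fs for all-atom rigid-body work.
  NVE drift over 10⁴ steps at 2 fs is < 10⁻³ of the well depth for both
  engines (≈ 2×10⁻⁷ for the all-atom pair).

Determinism: a run is a pure function of (configuration, seed); repeated
runs are bit-identical.

## Liquid-state analysis

* **RDF** — centre-of-mass pair histogram, minimum image, normalised by
  ideal-gas shell counts; bin width 0.1 Å; first-peak height/position by
  parabolic interpolation through the top bin and neighbours (the
  published peak positions imply sub-bin resolution).
* **VAF** — C_v(t) = ⟨v(t)·v(0)⟩/⟨v²(0)⟩ averaged over molecules and time
  origins; C_v(0) = 1 by construction.
* **Green–Kubo diffusion** — D = (1/3)⟨v²⟩∫C_v dt (trapezoid), reported
  in 10⁻⁹ m²/s (Å²/ps × 10). The integrator refuses a window whose tail
  has not decayed below |C_v| = 0.05 unless overridden, and reports the
  value at 80 % of the window as a sensitivity check. At the C60 liquid
  state points the tail is still ≈ 0.09 at 0.5 ps and the integral there
  is ≈ 20 % short; diffusion runs therefore integrate to 3 ps (tail
  < 0.01), which agrees with the independent mean-squared-displacement
  (Einstein) estimate within a few per cent. 0.5 ps remains the default
  plotting window for C_v itself.

## Reproduction scales

Desk-scale defaults chosen for the bundled tests and the acceptance
script: RDF state points run 256 molecules with 12.5–15 ps equilibration
and 30–40 ps production (the test suite's diffusion check uses 108
molecules); the acceptance script's diffusion run uses 256 molecules and
70 ps production. Longer runs sharpen the statistics but do not move the
peak values at the quoted tolerances.

## What the synthetic generators emulate

Random Gaussian blobs exercise the tensor algebra with no symmetry to
hide sign errors; they are not molecules, and passing on them shows the
series identity and its derivatives, not chemical realism. The
Ornstein–Uhlenbeck velocity process supplies the one case where the
Green–Kubo integral has a closed form (D = ⟨v²⟩τ/3); it lacks the caging
back-scatter (negative C_v dip) of a real liquid, so it validates the
estimator's normalisation and integration, not its behaviour on
structured correlation functions — that is cross-checked against the MSD
route on the liquid itself.

## Known limitations

* Blobs are rigid; internal degrees of freedom and their entropy are
  outside the model.
* The multipolar series is implemented to rank 4 in 3 dimensions; no
  electrostatic multipoles, no many-body CG terms, no Ewald sums.
* The velocity-rescaling thermostat does not generate a canonical
  ensemble; at the rescale intervals used its effect on the RDF and on D
  is below the quoted tolerances.
* Single cubic box, FCC initialisation, one species; NVT only.
* Self-diffusion carries the usual periodic-box finite-size bias; values
  are quoted at the stated system sizes without hydrodynamic correction.
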