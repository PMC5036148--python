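# Methods

## Physical picture and model

The system is a graphene (or GO) sheet separated from a lipid bilayer by a
nanometre-scale water gallery, immersed in water, with the far side of the
bilayer thermostatted at T_e = 300 K. Heat generated in the sheet at areal
power density p crosses the sheet–water–lipid interface (treated as a
single thermal contact of conductance G_C, because the thin water layer is
effectively isothermal) and is then conducted through the bilayer to the
sink. Transport is assumed diffusive (Fourier's law); convection and
lateral spreading are neglected, and all properties are
temperature-independent. The model is therefore strictly linear in p,
which the tests exploit as a superposition check.

Steady state, with through-interface flux q = η·p:

- water plateau: T_W = T_e + q·δ/κ_L
- sheet: T_G = T_W + q/G_C
- lipid: linear in z from T_W at the inner surface z_s down to T_e at z_s+δ.

Transient (lumped-parameter): the sheet is a single heat-capacity node with
areal capacity ρ_g·c_g·d, giving
T_g(t) = T_W + (η·p/G_C)·(1 − exp(−t/τ)), τ = ρ_g·c_g·d/G_C. With the
default constants (ρ_g = 2.265 g cm⁻³, c_g = 2.1 J g⁻¹ K⁻¹, d = 0.34 nm)
the areal capacity is 1.617×10⁻³ J m⁻² K⁻¹; at G_C ≈ 10 MW m⁻² K⁻¹, τ is
~160 ps. c_g is the Dulong–Petit value 3·N_A·k_B per gram of carbon
(2.08 J g⁻¹ K⁻¹, conventionally quoted as 2.1).

**Closure for T_W.** The water plateau is tied to the lipid inner-surface
temperature at steady state; during transients T_W is held constant (by
default the curve's initial value). This is the simplest closure consistent
with an isothermal, low-heat-capacity water layer; it slightly understates
late-time sheet temperatures when the lipid side also warms appreciably.

**Flux partition η ∈ [0, 1].** The serial model sends all heat through the
confined interface. In reality part of the power leaks through bulk water
around the contact, so the observed membrane heating corresponds to
η < 1. η defaults to 1 (pure serial model) and is exposed as a fittable
parameter; `fit_flux_partition` reports the η that reconciles a predicted
and an observed critical power. It is a descriptive partition, not a
mechanistic prediction.

**Critical power.** The hottest lipid point is its inner surface
(rise η·p·δ/κ_L), so p_c = κ_L·ΔT_c/(η·δ); the volume-average lipid rise is
half the surface rise, doubling p_c. The default threshold ΔT_c = 20 K is
the usual cell-viability criterion. δ defaults to 4 nm, a typical POPC
bilayer thickness.

## Estimators

*Relaxation time*: nonlinear least squares of T_e + ΔT₀·e^(−t/τ),
initialized from a log-linear regression of the positive excess; all points
weighted equally. A series that does not start above T_e or does not decay
is rejected.

*Kapitza conductance*: G_K = ρ_g·c_g·d/τ, the per-area form of C/(τA) —
intensive, hence independent of A.

*Steady-profile fit*: bins are classified by the known geometry (sheet
z < 0, water 0 ≤ z < z_s, lipid z_s ≤ z ≤ z_s+δ); (G_C, κ_L) are fitted by
least squares with moment-based starting values (interface step → G_C,
lipid drop → κ_L). A profile with no interfacial step yields G_C → ∞ and is
flagged unidentifiable; a gradient-free profile is rejected as degenerate.

*Transient fit*: least squares for G_C (optionally η). When the data do not
approach the plateau (t_max below ~half the fitted τ) the conductance is
flagged unidentifiable — the early-time response is linear in η·p only.

*MSD / diffusion*: exact multiple-time-origin average via the standard FFT
autocorrelation decomposition; D is the slope over a fit window of 10–50%
of the maximum lag (avoiding the short-time regime and the
poor-statistics tail), divided by 2·d_i. Independent runs are fitted
separately and averaged; the spread gives the standard error. Wrapped
periodic coordinates are detected (single-step jump > box/2) and rejected
with an instruction to unwrap.

*Density profile*: per-slab mass over slab volume, averaged over frames,
with 0.1 nm slabs by default — the same slab convention used for kinetic
temperature profiles (T = Σmv²/3Nk_B with 3 translational degrees of
freedom per particle; constrained-bond DOF corrections are out of scope and
a documented limitation). Bins are aligned to the z = 0 grid of the
graphene plane so slab boundaries are reproducible. The bulk reference
density is 0.997 g cm⁻³ unless measured from a user-designated far-field
window.

*t_W*: width of the contiguous super-bulk run containing the first peak,
with isolated single-bin dips bridged (sampling-noise robustness). Water
that penetrates the bilayer is excluded by construction since the density
there falls below bulk.

*Peak boundaries (M₁)*: flanking local minima, bulk crossings or profile
ends, with the walk stopping once the per-bin decrease falls below 5% of
the peak prominence so that a noisy plateau does not randomly extend the
integration region; ties break toward the wall. M₁ is the trapezoidal
integral of A·ρ(z) over [z₀, z₁].

## Synthetic surrogates

The generators provide inputs with the statistical structure the estimators
assume, at desk scale; they are not molecular simulations.

*Layered density*: z sampled by inverse-CDF from bulk + Gaussian peaks
(closed-form integrals make the generator its own oracle); per-molecule
mass is total analytic mass / n, so the binned profile converges to the
target density. Real density profiles are not Gaussian mixtures and their
peaks are correlated with wall chemistry; passing tests show estimator
correctness, not force-field realism.

*Brownian trajectories*: independent Gaussian increments of variance
2·D·dt per active axis — free diffusion with no hydrodynamic or
confinement memory effects.

*Lattice conduction*: an explicit-Euler chain of heat capacities
(sheet | water | lipid) with intra-layer link conductances, two interfacial
junction conductances, a sink coupling and optional per-step Gaussian
temperature noise. Pairwise exchange terms are antisymmetric, so with the
sink decoupled total energy is conserved to round-off (< 10⁻⁶ relative
over 10⁵ steps). Stability requires dt·max(g)/min(C) < 0.5 and divergence
aborts with a diagnostic. The pulse-relaxation protocol ramps the sheet
temperature to 500 K over 100 ps — the analogue of velocity rescaling,
whose per-step details the surrogate does not model — then releases it;
the heating protocol injects constant power into the sheet layer. An
`area` field maps lattice conductances to the per-area Kapitza convention.
Parameters are chosen per test to sit in the diffusive, lumped regimes the
model assumes.

## Problem sizes and numerical choices

Default test sizes: 10⁵ molecules for density fixtures (per-bin sampling
error ≲ 1.5%), 500 particles × 2000 frames for diffusion (D recovered
within 5%), 10⁵ lattice steps for conservation checks, 0.1 nm bins and
1 ps sampling for profiles and series. These sizes make every estimator's
sampling error comfortably smaller than its test tolerance while keeping
the whole suite fast on one CPU. Fits use scipy's Levenberg–Marquardt with
analytic-free Jacobians; round-trip recoveries on noiseless inputs are
exact to optimizer tolerance (≪ 0.1%).

## Known limitations

- The lumped transient holds T_W fixed; at the highest powers the
  steady-state sheet rise p/G_C therefore exceeds what a coupled
  water/lipid model (or MD) would give. The discrepancy is physical
  information about the closure, and the fit does not force agreement.
- No phonon-level or spectral treatment; conductances are scalars.
- Kinetic temperatures assume 3 DOF per particle (no constraint
  corrections).
- Only extended-XYZ and LAMMPS-dump text trajectories are read; other
  formats must be converted upstream. LAMMPS dumps are assumed to be in
  `real` units (Å, fs).
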