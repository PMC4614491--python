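# Methods

## Model overview

The package simulates one inflation of an initially flooded and collapsed
peripheral airway network under prescribed tidal volume. Three scales are
coupled:

1. **Airway wall elasticity** — a Lambert-type two-branch tube law per
   generation, `P = F(a)`, strictly increasing, analytically invertible,
   mapping all transmural pressures onto `(0, A_max)`. The per-generation
   coefficient table (α₀, α₀′, n₁, n₂, total generation area, length;
   generations 0–16) is shipped as a JSON constants file
   (`src/ventnet/data/lambert1982.json`) so it can be audited or replaced
   wholesale; per-airway maximal area is the generation total divided by
   2^generation. Branch pressure scales are fixed by continuity of value
   and slope at `P = 0`: `P₁ = α₀ n₁/α₀′`, `P₂ = −(1−α₀) n₂/α₀′`.
2. **Single-airway reopening** — yield pressure, peeling velocity and tip
   stress laws (below).
3. **Network coupling** — one global air pressure determined at every
   instant by volume conservation against the delivered volume.

Internal units are CGS throughout; the single conversion constant
1 cm H₂O = 980.665 dyn cm⁻² lives in `ventnet.tube_law.CM_H2O`.

## Heterogeneity

Each airway carries a scale parameter λ drawn independently from a normal
distribution with unit mean and standard deviation `d`, redrawn while at or
below a floor of 0.05 (redrawing rather than clipping avoids an atom at the
floor). λ multiplies the generation's reference maximal area only; shape
constants are untouched. This single parameter then simultaneously alters
the maximal extension, the equilibrium area (`a_eq = α₀ λ A_max,ref`) and
the stiffness (`Γ(λa) = Γ(a)/λ` — a pure area rescale, which tests exploit
as an exact identity). Spatial correlation between airways is deliberately
absent. Every airway starts uniformly collapsed to `C` times its
equilibrium area; the slow liquid-pressure readjustment such a state would
drive is not modelled.

## Reopening laws (reduced-order reconstructions)

The single-airway physics is represented by closed-form laws chosen to
satisfy, simultaneously, the orderings the underlying peeling mechanics
imposes; the exact functional forms are the package's own reduced-order
choices and are isolated behind `ventnet.reopening` (a variant registry) so
they can be replaced without touching the engine.

**Yield pressure.** `P_c = β F(a_init) + c_y P₁ λ^(−1/2)` with defaults
β = 0.2, c_y = 2.124. The first term is the fraction of the stored elastic
recoil of the collapsed wall available to drive the tip (more collapse →
more stored energy → lower yield); the second is an adhesive threshold
proportional to the airway's buckled-branch elastic pressure scale, reduced
for wider, more compliant airways. The constraint set that fixes the two
constants: yield strictly decreasing along generations 11→16 for all
C ∈ [0.1, 1] (requires c_y > 9β with the shipped constants table); strictly
increasing in C; strictly decreasing in λ; the generation-11 constant-speed
recruitment pressure at C = 0.2 and 10 ml kg⁻¹ over 2.5 s equal to the
worked-example value 0.822 cm H₂O (requires c_y − 4β ≈ 1.324); and
yield(gen 11, C = 0.5) above that initial pressure, so weakly collapsed
networks start below threshold and must be pressurised before the first
avalanche. A longitudinal-tension correction hook `c_T·T/ℓ_T²` is provided
with `c_T = 0` by default. Surface tension and viscosity enter the velocity
and tip-stress laws; whether they should also enter the yield directly is
left to the variant hook.

**Peeling velocity.** `U = (m₀/μ) r_eq (P − P_c) λ^(−q)` above yield, zero
at and below it (continuous threshold); defaults m₀ = 1, q = 1. Linear
dependence on excess pressure follows channel-peeling models; the λ^(−q)
factor makes stiffer airways recruit faster once yielded, despite their
higher yield pressure (the two laws cross roughly 2 P₁-units above the
stiffer airway's yield; below that the compliant airway's head start in
excess pressure dominates).

**Tip pressure gradient (damage proxy).**
`G = (P − F(a_init) + 2γ/r_c)/(w r_c)`, reported per micrometre, with
`r_c = sqrt(C α₀ A_max,ref/π)` the generation's reference collapsed radius
and w = 0.3 the tip-length fraction. The numerator is the normal-stress
jump from air to the static liquid ahead of the tip, including the
capillary jump across the meniscus, which dominates in the narrowest
airways and makes generation 16 the consistent site of the network maximum.
Freezing the radius at the initial collapsed geometry keeps G strictly
increasing in pressure; using the generation-reference (λ-free) radius
keeps within-generation damage variation governed by the pressure history
(avalanche timing) rather than tied deterministically to the airway's own
scale parameter. w is set so that the damage scale straddles the
classification threshold 10^3.5 dyn cm⁻² µm⁻¹ across generations at
baseline (peripheral generations above, proximal below), mirroring the
spatially confined damage pattern the threshold is meant to expose.

## Acinus and proximal compartment

Each generation-16 airway feeds one acinus with a modified
Salazar–Knowles pressure–volume law `V = V_A(1 − exp(−K_A(P − P_A)))` above
the acinar opening pressure, zero below; defaults V_A = 0.0778 cm³,
K_A = 0.14 (cm H₂O)⁻¹, P_A = 2 cm H₂O. The acinus is non-hysteretic within
the inflation: once its parent airway is recruited its volume follows the
law whenever `P > P_A` (it may transiently shrink if the pressure dips).
Generations 0–10 are always open and are lumped into a proximal compliance
compartment: one subtree's share (2^j/2048 airways of generation j) of
tube-law volume at λ = 1, which lets the pressure rise when every tip is
stalled.

## Ventilation engine

Air is treated as inviscid and incompressible, so the connected air phase
has one gauge pressure P. Opened airway segments equilibrate instantly to
the tube law; liquid films and the liquid displaced ahead of tips carry no
volume. With delivered volume `Q·t` prescribed, P(t) solves

    V_finger(P, s) + V_acini(P) + ΔV_prox(P) = Q·t,

a strictly increasing function of P, by a bracketed Illinois iteration to a
residual below the configured tolerance (10⁻¹¹ cm³ by default; every
recorded step keeps the audit column `residual_cm3`).

Time stepping is implicit first order: within a step the trial recruited
fractions `s_i(P) = min(1, s_i + dt·U_i(P)/L_i)` are substituted into the
conservation equation and the step's end pressure is found as a single
root. This lets the pressure "ride" the frontier yield pressures during
avalanches without the stall/peel chatter of explicit schemes and permits
large steps during stalls. Steps on which an airway would cross `s = 1` are
re-solved at the earliest crossing time, so completions (which unlock the
two children) are sharp; when an acinus switches on while `P > P_A` the
pressure is re-solved at fixed state to redistribute volume into the new
compartment (the physical pressure dip at acinar opening). Menisci never
retract: s is nondecreasing, and a stalled airway resumes exactly when P
re-crosses its yield (resolved inside the implicit step, so no event search
is needed). Simultaneous completions are processed in airway-index order —
a pure bookkeeping tie-break; exact simultaneity only occurs in the
homogeneous d = 0 case.

The adaptive controller limits the per-step recruited-fraction advance
(10% of an airway length), the per-step pressure change (0.05 cm H₂O) and
the absolute step (20 ms); all caps scale together through
`Numerics.dt_scale`, and halving that scale changes the recruitment time by
under 1% at baseline. The inner loop is compiled with numba; a pure-python
reference path (`subtree_air_volume`, `solve_pressure`, `advance`) mirrors
the kernel's semantics step for step and is cross-checked against it and
against dense pressure-scan oracles in the test suite.

Initial pressure: the PEEP value when one is prescribed; otherwise the
constant-speed recruitment pressure of the homogeneous reference network at
C = 0.2 (the worked-example anchor, used regardless of the simulation's
actual C, so weakly collapsed networks genuinely start below yield).

## Protocol defaults and sizes

Tidal volume 10 ml kg⁻¹, body mass 70 kg (adult; the tidal volume is
specified per kg, so an absolute mass is needed to set the flow — it scales
Q directly and is configurable), inflation interval T_Q = 2.5 s, subtree
share 1/2048 (generation-11 subtrees in a whole lung; also the whole-lung
extrapolation factor for reported lung volumes), γ = 30 dyn cm⁻¹,
μ = 0.01 dyn s cm⁻², T = 3000 dyn cm⁻¹. Ensembles use seeds
`seed_base … seed_base + n − 1`; sweeps share one seed list across
conditions so cross-condition ratios compare matched network ensembles.
Reported ensembles use n = 100 for the heterogeneity-ratio grid, n = 30 for
trend checks and the baseline recruitment-time mean — sizes at which the
assessed means are stable to well within the asserted margins. Where a run
fails to recruit fully within T_Q its recruitment time is censored at T_Q
(a lower bound, which only ever biases the heterogeneity ratio downward,
i.e. conservatively).

## What the synthetic networks do and do not emulate

The generator reproduces the study conditions: independent unit-mean
Gaussian λ per airway, uniform collapse fraction across the network, fixed
acinar properties. It does not emulate spatial correlation of airway
properties, variability in airway length or acinar parameters, gravity,
branching-angle geometry, surfactant transport, non-Newtonian lining
rheology, or patient-derived collapse maps — so passing tests demonstrate
the internal consistency of the model under idealised heterogeneity, not
fidelity to any measured lung.

## Numerical and design notes

* The tube law is evaluated in closed form for any real pressure; the
  inverse and the stiffness are analytic, so round trips are exact to
  floating-point (tests assert 10⁻¹⁰ relative).
* The conservation residual is strictly increasing and continuous in P,
  including through trial completions (the min-cap is continuous), so the
  bracketed solve cannot fail on a sign-definite function; bracket
  expansion is geometric from the previous pressure.
* Determinism: identical seed and configuration give bit-identical traces;
  the kernel is single-threaded.
* Degenerate inputs: d = 0 gives λ ≡ 1 exactly; zero tidal volume requires
  an explicit PEEP and produces a static run; collapse fractions outside
  (0, 1] and non-positive material constants are rejected at the boundary.

## Known limitations

* The reopening laws are reduced-order reconstructions constrained by
  orderings and one quantitative anchor, not derived from the
  two-dimensional tip flow field; quantities that depend on their fine
  structure (absolute damage magnitudes, the exact shape of the
  velocity–pressure curve) are only order-of-magnitude.
* At strong heterogeneity (d = 0.5) the stiffness–relative-damage
  correlation over single events is moderately positive (~+0.4): the
  stiffest airways are the last to open, at stall-end pressures, so their
  recorded maximal gradients are elevated. A damage proxy that records the
  maximum pressure while peeling makes this coupling intrinsic; weak or
  negative correlations would require the tip stress to relax with local
  opening, which the frozen-radius law deliberately omits.
* The PEEP effect on the mean maximal tip gradient is weak (~1%) for
  C ≥ 0.5, because the avalanche riding pressure is yield-set; only the
  end-to-end (2→5 cm H₂O) increase is a robust prediction here.
* Expiration, cyclic recruitment/derecruitment and pressure-controlled
  ventilation are out of scope (a fixed-pressure mode would be a small
  extension of the same engine but is untested).
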