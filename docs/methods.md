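# Methods

## Model

### Continuous layer: polymerases under torque

Each loaded polymerase i is described by its genomic position zᵢ (nm),
nascent-RNA length xᵢ (nm), local DNA excess twist φᵢ (rad), and rotation
angle θᵢ (rad). Two relations close the dynamics:

* groove tracking, ω₀ żᵢ = θ̇ᵢ + φ̇ᵢ, with ω₀ = 1.85 rad/nm the relaxed
  helical twist density;
* torque balance at the polymerase, τ_net + χ φ̇ᵢ = η xᵢⁿ θ̇ᵢ, where
  τ_net = τ(σ_ahead) − τ(σ_behind) is the net DNA torque across the
  polymerase, χ the viscous resistance of DNA to local twisting, and
  η xⁿ the rotational drag of the nascent transcript.

Solving the linear pair gives the closed form used by the integrator:
θ̇ = (τ_net + χ ω₀ ż)/(η xⁿ + χ) and φ̇ = ω₀ ż − θ̇. Two limits fix the
sign conventions: a freshly loaded polymerase (x = 0) on relaxed DNA
rotates freely and injects no twist; an infinitely long transcript freezes
rotation and deposits all ω₀ v as supercoiling. The torque sign is the
unique choice for which accumulated twist drives polymerase rotation
rather than further twist injection (negative feedback), for both strands.

Between barriers (polymerases and walls) the supercoiling density is
pseudo-steady and piecewise constant, σ = Δφ/(ω₀ Δz). Linear domains pin
φ = 0 at both walls; circular domains close the barrier list around an
origin, and a lone polymerase on a circle generates no net supercoiling.
The segment-length-weighted integral of σ telescopes to zero identically;
every operator (insertion, termination, topoisomerase action) preserves
this exactly, and the property suite asserts it after randomized runs.

### Torque response

τ(σ) follows the two-phase description of stretched supercoiled DNA:
elastic twisting (τ = k_BT·c_s·ω₀·σ) up to σ_s, a constant coexistence
torque τ₀ while plectonemes nucleate (σ_s ≤ |σ| ≤ σ_p), and a softer
linear plectonemic branch beyond. c_s, σ_s, σ_p and τ₀ are derived in
closed form from four mechanical constants — twist persistence length
c = 95 nm, plectoneme twist stiffness p = 24 nm, bending persistence
length A = 50 nm, and stretching force f — via a common-tangent
construction on the two phase free energies. The default f = 0.2 pN
(intracellular DNA is under weak tension) puts the buckling transition at
σ_s ≈ 0.009 and the plateau at τ₀ ≈ 4.7 pN·nm. The nucleosome-buffered
variant returns zero torque on a positive band σ ∈ [0, 0.031] (nucleosomes
absorb positive supercoiling by unwrapping) and translates the positive
branch right by the band width; the translation, rather than a plain
clamp, keeps the curve continuous everywhere, which the integrator and the
property tests both rely on.

### Stalling and steric exclusion

Translocation speed is v = v₀ / [(1+e^{(|τ_f|−τ_s)/τ_w})(1+e^{(|τ_b|−τ_s)/τ_w})]
with v₀ = 17 nm/s (0.05 kb/s), τ_s = 12 pN·nm, τ_w = 3 pN·nm: either a
large front or a large rear torque stalls the enzyme independently. In
addition, velocity ramps linearly to zero as the gap to the neighbor ahead
closes from two footprints down to one (footprint 35 bp): polymerases are
physical objects that cannot overlap. This steric term is also what keeps the
ODE system integrable — without it, convoys pressing against a stalled
leader drive segment lengths toward zero and the explicit stepper's
stable step collapses.

### Supercoiling-dependent initiation

Loading a polymerase displaces ~1.2 helical turns, so the binding energy
carries E_sc = 1.2·2π·τ(σ) evaluated just upstream of the TSS; the
second-order model adds α·τ₀·σ² (α = 0.025), which penalizes extreme
densities without changing behavior near σ = 0; the hyper-penalty variant
returns a large finite energy (10³ k_BT) outside σ ∈ (−0.06, 0.125),
making initiation numerically impossible where stable non-B structures
(R-loops, G-quadruplexes) would form. Rates follow
r = r_base(S)·e^{−E_sc/k_BT}, where the base rate may depend on species
counts (constant, Hill repression r₀/(1+(R/K)ⁿ), or binary dimer
occupancy). The Boltzmann factor is capped at `max_enhancement` (default
40): beyond that fold-change, promoter output is recruitment-limited, not
binding-limited. While a polymerase occupies the TSS footprint the
promoter is gated shut (there is no binding site to fire).

With the Marko-derived torque scale, the quadratic correction is small at
α = 0.025: the rate-vs-σ curve is non-monotone only through the
coexistence plateau (where the first-order term is flat). An interior rate
maximum on the negative branch — a qualitatively different shape — appears
once α·τ₀ exceeds 1.2·2π·k_BT·p·ω₀/(2|σ|); the tests probe that
transition through the derived critical coefficient rather than a fixed α,
since the critical α depends on the configured torque constants.

## Hybrid integration

All polymerase coordinates form one ODE system advanced by an explicit
adaptive Dormand–Prince 4(5) stepper (rtol 10⁻⁶, atol 10⁻⁸, max step
30 s), JIT-compiled. Stochastic channels are layered on it by the
integrated-hazard method: each promoter's cumulative intensity ∫r dt is an
extra ODE state, an event fires when it crosses an Exp(1) draw, and the
crossing is localized by bisection on the step's cubic Hermite
interpolant. Thinning was rejected because the σ-dependent rates have no
a-priori bound. Termination (z crossing the TES) and footprint clearance
are localized the same way. Discrete-reaction propensities only change at
events, so their hazards advance analytically between legs, and
first-order decay of species that nothing depends on is drawn as
per-molecule exponential lifetimes on a heap — distributionally identical
to a propensity channel, but it never interrupts the ODE. With no
polymerases loaded every rate is constant and the simulator jumps
analytically from event to event. A fixed seed reproduces the event log
bit-for-bit; replicate k of an ensemble is seeded from (base_seed, k).

Correctness of this machinery is checked against an independent
fixed-small-step classical RK4 path through the same event rules (same
hazard draws ⇒ same event sequence; trajectories agree to integration
tolerance) and against the feedback-free limit, where mRNA is a
birth–death process with mean r/d and Poisson event counts.

Trajectory tables are reconstructed exactly from the event log on a
uniform grid (default 10 s); supercoiling-profile snapshots are collected
on the same grid when requested.

## Synthetic systems and parameter choices

Standard operating defaults of the presets: basal rate r₀ = 1/160 s⁻¹,
Hill cooperativity n = 2, induction of the second gene at 10,000 s
(2.8 h), burst threshold 30 s (20/60 s presets for sensitivity; 10 s
shreds bursts), two-gene spacing range 500 bp–10 kb, output normalization
250 mRNAs (linear) / 10 (circular).

Free choices, made once and documented here:

* Geometry: gene bodies 1 kb, spacing 3 kb, wall margins 6 kb. Convergent
  and divergent pairs are built as exact mirror images so the two genes
  compete on equal terms; the reporter is always the forward gene. No
  published coordinates pin these constructs down, so the layouts are
  this package's own design.
* Drag and twist-viscosity coefficients (η = 6×10⁻⁴ pN·nm·s/nm²,
  χ = 1 pN·nm·s) and the enhancement cap (40) were calibrated jointly so
  that the uninduced linear reporter settles near the 250-mRNA
  normalization value with intermittent ON/OFF convoy dynamics, and so
  that the baseline is insensitive to wall geometry (a single
  normalization constant across all four syntaxes presupposes that
  insensitivity). The calibration used only the single-gene system; the
  two-gene correlation, burst, toggle, and clock readouts were left free.
* k_BT = 4.11 pN·nm (298 K); drag exponent n = 1 (drag linear in
  transcript length).
* mRNA half-life 20 min for the synthetic-circuit presets.
* Toggle: repression acts directly on the partner's mRNA count (no
  explicit proteins). K defaults to 250 (≈ the single-gene steady state)
  and can be calibrated by `calibrate_K`, which runs single-gene-enabled
  ensembles under the full supercoiling model, checks the last two
  quarters of the run for a residual trend, and divides K by any fold
  increase in the degradation rate.
* her1–her7: divergent promoters 1.5 kb apart inside a 25 kb linear
  domain (walls standing in for the nearest flanking genes); the unpaired
  control moves her7 1 Mb away. The translation / dimerization /
  promoter-occupancy rate table is synthetic (three-minute mRNA and
  protein turnover, fast dimerization, minute-scale promoter occupancy),
  chosen to give minute-scale pulsatile dynamics; all conclusions drawn
  from this preset are comparative (paired vs unpaired, topoisomerase on
  vs off), never rate-quantitative.
* Topoisomerase relaxation, when enabled, fires at 1/300 s⁻¹: the
  intergenic mode zeroes every non-genic segment by rotating the boundary
  polymerases of each gene (the last gene absorbs the residual as a
  uniform intragenic shift), the intragenic mode homogenizes σ across a
  gene's polymerases; both conserve the domain twist integral exactly.

## What the generator does and does not emulate

The synthetic circuits reproduce the study conditions of the source
system: constitutive reporter + inducible neighbor in four syntaxes under
linear or circular boundaries, equal-induction protocols, mutual-repression
toggles, and the paired/unpaired clock. Emergent behaviors — twin-domain σ
profiles (mean σ ≈ −0.014 upstream / +0.014 downstream of an active
gene), ON/OFF transcriptional bursting, convergent either-or alternation
with ~2 h period, divergent co-activation, upstream dominance in tandem
pairs, order-of-magnitude inter-burst-time contrasts between syntax
groups, ~50/50 late-time basin occupancy of the convergent toggle, and
supercoiling-coupled clock oscillations — arise from the physics, not from
fitted targets.

Passing tests on these circuits says nothing about sequence-dependent
initiation, pausing and premature termination, explicit nucleosome or
R-loop particles, polymerase collisions beyond steric exclusion, 3D loop
domains, or finite-rate supercoiling diffusion: all are outside the model.
One known qualitative deviation: at full equal induction the
tandem-downstream reporter is suppressed almost completely, so its
ensemble standard deviation falls after induction instead of rising; the
other three syntaxes reproduce the expected noise-shift directions.

## Numerical notes

* Tolerances: rtol 10⁻⁶ / atol 10⁻⁸; event bisection to 10⁻¹² of a step.
* Degenerate segments (coincident barriers) are prevented by the steric
  velocity ramp; if polymerase order ever inverts at the minimum step the
  integrator raises a diagnostic error rather than continuing.
* Footprint-occupancy comparisons carry a 10⁻⁶ nm slack so a gate opened
  by a root-found clearance event cannot immediately re-close on
  interpolation error.
* Exponentials in the stall and Boltzmann factors are clamped before
  overflow; enhancement is capped as described above.
* Problem sizes in the test-suite and acceptance script (ensembles of
  8–20 replicates, 15,000–60,000 s horizons) were chosen as the smallest
  ensembles at which the reported contrasts are stable across seeds.
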