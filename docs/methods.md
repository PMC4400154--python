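# Methods

## The model

`dlcact` simulates the nucleocytoplasmic dynamics of the transcription factor
Dorsal (dl, an NF-κB homolog) and its inhibitor Cactus (Cact, an IκB homolog)
in the syncytial *Drosophila* embryo across nuclear cycles (NC) 10–14, and
the interpretation of the resulting nuclear dl gradient by its earliest
target genes along the dorsal–ventral (DV) axis.

One half of a DV cross-section is discretized into a linear array of
rectangular-prism compartments, one nucleus each, from the ventral midline
(index 0) to the dorsal midline.  Three species — free dl (U), free Cact (Z)
and the dl/Cact complex (W) — occupy nuclear and cytoplasmic pools of each
compartment.  The processes are:

* first-order nuclear import/export per species (ζ_s, ξ_s), scaled by the
  nuclear surface area;
* slow first-order exchange between neighboring compartments (λ_s) through
  their shared face, with no-flux boundaries at both midlines;
* mass-action dl/Cact association (γ) and basal dissociation (β₀);
* Toll-signal-driven dissociation of *cytoplasmic* complex with a Gaussian
  rate profile β·exp(−z²/2φ′²) peaked at the ventral midline (the footprint
  of active Toll receptors); nuclear complex dissociates only at β₀;
* Cact turnover in the cytoplasm: degradation (α) and constant production
  (fixed at 1 by the Cact nondimensionalization; a `cact_production` switch
  turns it off for sensitivity checks).

Concentrations are nondimensional (dl species by total dl, Cact by total
Cact, with ψ their ratio), time is in minutes, and geometry is scaled by the
NC14 nucleus.  These are the 15 free parameters held in `ModelParameters`;
all are non-negative rates except the dimensionless width φ′ and ratio ψ.

Each cycle is an interphase followed by a mitosis.  At mitosis onset every
nucleus is mixed into its compartment's cytoplasm (volume-weighted average;
exact per-compartment mass conservation), the cytoplasm-only equations are
integrated with the cytoplasm occupying the full prism, and the next
interphase begins with roughly twice as many compartments.  Two variants
differ in how nascent nuclei start:

* **extended** (default): reforming nuclear envelopes enclose cytoplasm, so
  nuclei inherit the cytoplasmic concentrations of all three species — Cact
  and dl/Cact complex can reside in nuclei;
* **classic**: nuclei start interphase empty and only free dl shuttles; this
  variant structurally cannot produce the observed slow interphase decline
  of dorsal nuclear signal, which is the point of the contrast.

The fluorescence observable is taken to be total nuclear dl, U_nuc + W_nuc
(both carry the tag); only free U_nuc is transcriptionally active.  The gap
between the two is what the downstream analyses quantify.

## Geometry

Per-cycle nucleus counts follow round-half-up halving from the NC14 count
(e.g. 50 → 25 → 13 → 7 → 4), the inverse of "doubling to the nearest
integer".  Defaults (all overridable in `build_schedule`): NC14 count 50,
spherical nuclear radii 3.3/3.7/4.2/4.9/5.5 µm for NC10–14, compartment
height 35 µm, half-axis length 280 µm (≈ half the circumference of a
~180 µm-diameter embryo cross-section), interphase durations 8/10/12/14/60
min, mitoses 3/3/3/4 min.  These are order-of-magnitude realistic values,
not measurements; every result here is checked to be robust to sane
overrides.

The compartment depth (the direction normal to the modeled cross-section)
defaults to a constant L/n₁₄ so the modeled volume is identical in every
cycle; total dl is then conserved exactly through mixing and redistribution,
which is used as an integration audit.  `width_mode="per_cycle"` instead
sets depth = length (square footprint, a thinning slab), which changes
per-cycle volume ratios slightly but none of the qualitative behavior.

## Numerics

The stiff-capable LSODA integrator (banded Jacobian; the compartment-major
state layout has bandwidth 6) integrates each phase with rtol 1e−6 and
atol 1e−9 by default; phase boundaries are hard restarts because the state
dimension changes.  Output is sampled on a 1-minute grid.  Reported samples
are clipped at zero; the integrator state never is, and undershoot beyond
10·atol warns.  Redistribution onto the doubled grid is cell-averaged
piecewise-constant resampling, which preserves the spatial integral to
machine precision even when rounding breaks exact doubling (e.g. 13 → 25).

Fitting objectives cap the integrator at 10,000 steps per phase — far above
what well-posed parameter sets need — so pathologically stiff corners of
parameter space fail fast and score +inf instead of stalling a run.

Initial conditions at NC10 onset: free dl 0, complex 1, Cact at the steady
state of its production/degradation/transport balance with U = 0, W = 1
frozen and basal dissociation only (a 2×2 linear solve in the extended
variant); α = 0 is rejected since production then has no steady state.

## Fitting the dynamics

A candidate parameter set is simulated, the nuclear signal is sampled on the
dataset's (nucleus, time) grid — data nuclei are indexed at NC14 resolution
and mapped position-proportionally into the coarser early-cycle compartments
— a single global scale factor S = ⟨XY⟩/⟨Y²⟩ absorbs fluorescence units, and
the score is the uncertainty-weighted residual sum Σ((X − SY)/dX)².
Mitosis intervals carry no data (nuclear signal undefined).

The optimizer is a (λ+μ) evolution strategy: λ individuals initialized from
the discrete grid {1..9}×10^{−2,−1,0} (exchange rates and β₀ damped 100-fold
to avoid starting with unrealistically fast transport), the top μ grouped
five-at-a-time by rank, children built per-parameter from two random parents
of the group, then multiplicatively mutated in log space with a bias toward
the group leader, survivors the best μ of parents ∪ children.  The
configuration of record is λ=500, μ=100, 25 generations for the dynamics and
λ=250, μ=50 for gene fits; the reduced desk-scale configuration used in the
shipped tests and the acceptance script is λ=50, μ=10, 10 generations.

Mutation defaults are leader bias 0.1, per-parameter mutation probability
0.25 and log-normal scale 0.5 natural-log units.  They were chosen on
internal optimizer benchmarks (a 15-D sphere, fits to the surrogate
dataset, and a synthetic parameter-recovery problem with known ground
truth): a high mutation probability rewrites most coordinates of every
child and destroys good parameter combinations, a strong leader bias
collapses the population onto whichever basin the early leader occupies,
and half-log-unit moves are large enough to cross between basins for rate
constants spanning four decades.  Selection is rank-based, so these knobs
change only the proposal distribution; all are exposed in `EAConfig`
(including an optional geometric annealing of the scale via
`mutation_sigma_final`).  Dynamics fits additionally enable success-rule
step-size control (the classic one-fifth rule in spirit): the scale grows
1.5× whenever more than 20% of a generation's children enter the elite and
shrinks otherwise, so runs that find a basin refine into it while stalled
runs keep searching broadly.  Because independent runs still land in
different basins at desk-scale budgets, fits are run as several independent
optimizations and the run with the lowest RSS is used
(`fit_dynamics_multi`), mirroring the standard many-runs protocol.

Runs are summarized by inverse-RSS-weighted parameter means and standard
deviations (w_i ∝ 1/rss_i), the weighted median RSS, and nuclear
import/export equilibrium constants log₁₀(ζ_s/ξ_s) per species across runs.
Scores are deterministic given the seed and independent of evaluation order.

## Gene expression

Four targets — *sna* (high-threshold activation), *vnd* and *sog* (lower
thresholds, both repressed by sna above gene-specific thresholds), *zen*
(repressed by dl, dorsal domain) — each follow
d[mRNA]/dt = (f − [mRNA])/τ per nucleus with f a product of Hill switches
(exponent n_H = 100 by default; computed in log space to avoid overflow).
Read-out noise perturbs the input multiplicatively, U_eff = U(1 + ηN(0,1))
clipped at zero, drawn independently per nucleus, per gene, per 1-minute
step (redraw cadence configurable: per-step, per-interphase or single-draw);
it models the stochastic arrival of dl at enhancer sites, not fluctuations
of nuclear dl itself.  Within a step sna is updated first and its new level
feeds the vnd/sog repression.  mRNA persists across divisions (daughters
inherit via the position-proportional mapping); production is gated off
during mitosis while decay continues.  Profiles are averaged over 10
replicate noise histories by default.

Gene fits minimize the unweighted squared difference between the
replicate-averaged final NC14 profiles and FISH-like targets, summed over
nuclei and genes; thresholds and lifetimes initialize uniformly in [0, 3]
(lifetimes may evolve out of that range).  The per-individual noise seed is
derived from a hash of the parameter vector and the run seed, keeping the
stochastic objective reproducible and order-independent.

Boundaries are half-max crossings linearly interpolated between nucleus
centers; for sna/vnd/sog the dorsal edge of the domain, for zen the ventral
edge.  An exact on/off step between nuclei therefore reports the physical
on/off edge (one half internuclear distance dorsal of the last expressing
nucleus center).

## Positional error

k*(x) = η(c − B)/(|dc/dx|·D_n) counts the nearest-neighbor nuclei whose
positions are indistinguishable under read-out noise η for a gradient c with
internuclear distance D_n and a constant background B < min(c).  Derivatives
are centered differences (one-sided at the midlines); slopes below 1e−12
report k* = ∞ rather than huge finite values.  Subtracting the inactive
dl/Cact component lowers c while leaving the slope unchanged, which is how
the free-dl gradient conveys position beyond 40% DV where raw fluorescence
cannot.

## Synthetic data

No live-imaging or FISH dataset is publicly deposited for this system, so
the package generates surrogates that encode the documented features of the
data — they are study conditions, not measurements:

* **fluorescence surrogate**: X = A_i(t)·exp(−z²/2σ²) + b_i(t) + ε on the
  NC14 nucleus grid at 1-minute cadence, σ = 0.15; amplitude A rises
  linearly within each interphase from 45% of its end value (saw tooth,
  end values 0.25/0.40/0.55/0.75/1.0 across NC10–14), basal b declines
  within each interphase and resets higher at the next cycle start
  (0.40 → 0.115 across the full span; the NC14 end value leaves a ~20% drop
  of the total signal between 40% DV and the dorsal midline); ε is 5%
  multiplicative Gaussian noise and dX = 0.05·X floored at 0.01.  Mitoses
  are gaps.
* **FISH-like targets**: logistic profiles with half-max borders at 20%
  (sna), 33% (vnd), 50% (sog) and 55% (zen, dorsal-filling) DV; vnd and sog
  are bands whose ventral edges sit at the sna border, matching the
  sna-repression logic.
* **truth datasets**: model-generated, scaled and noised, with the
  generating parameters recorded for recovery scoring.

What the surrogates do *not* emulate: imaging point-spread functions,
photobleaching, embryo-to-embryo registration error, or any deviation of the
true gradient from a Gaussian-plus-offset shape.  Tests passing against
surrogates therefore validate the machinery and the qualitative mechanisms,
not quantitative agreement with real embryos.

## Problem sizes

The shipped test suite and the acceptance script run everything at desk
scale: 50 (or 20) NC14 nuclei, reduced EA budgets (λ=50, μ=10, 10
generations), and 10 expression replicates.  The full-scale configurations
(λ=500/250, 25 generations, 254 independent runs) are available through the
same interfaces.

## Known limitations

* The reduced EA budget (≈550 objective evaluations for 15 parameters
  spanning four decades) finds good but not noise-floor fits; parameter
  ensembles at this scale are dispersed, which is itself the expected
  sloppy-model behavior.
* Early-cycle comparison maps NC14-resolution data nuclei onto coarse
  compartments (4 at NC10), leaving an irreducible staircase residual.
* The gene model excludes Twist/Zelda co-regulation, transcriptional
  bursting, and mRNA transport; sna mRNA itself is the repressor proxy.
* Nuclear dimensions, cycle durations and the half-axis length are
  plausible defaults, not measurements.
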