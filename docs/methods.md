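# Methods

`phasecell` couples a two-dimensional phase-field description of a single
crawling cell to a stochastic polarity field, confines the cell to adhesive
micropatterns, and reconstructs the cell's deterministic equation of motion
from the simulated center-of-mass trajectories. This note records the
model, the numerical choices, and the design decisions taken where the
formulation left genuine freedom.

## The cell model

**Shape.** The cell is the region where a smooth field ϕ(r, t) ≈ 1; the
boundary is the ϕ = 1/2 level set. ϕ evolves by energy relaxation and
interface advection,

    ∂ϕ/∂t + v·∇ϕ = −ℳ δF/δϕ,        F = F_int + F_area,

with an interfacial (Cahn–Hilliard-type) energy

    F_int = ∫ γ [ (c/λ) ϕ²(1−ϕ)² + (λ/2)|∇ϕ|² ] d²r,     c = 16,

and a soft area constraint F_area = κ (1 − A/πR0²)² with A = ∫ϕ² d²r.
The interface constant `c_well = 16` is exposed as a named constant; with
the energy written this way the relaxed 1D profile is the logistic front
ϕ(x) = 1/(1 + e^(−kx)) with k = √(2c)/λ, which the test suite verifies
against the first integral ϕ′ = k·ϕ(1−ϕ) under grid refinement.

**Force balance.** The velocity field entering the advection term comes
from overdamped local force balance per unit area,

    η v = (δF/δϕ)∇ϕ + α P ϕ²(1−ϕ)² (1−χ) n̂,      n̂ = −∇ϕ/|∇ϕ|,

so active propulsion exists only where the interface (ϕ²(1−ϕ)² > 0)
touches adhesive substrate (χ < 1). Both force densities act along the
interface normal, so internally the advection is treated as normal motion
with a scalar speed.

**Micropattern.** χ(r) is a static field: 0 on the adhesive region, 1
outside, logistic in the signed distance to the pattern polygon with
smoothing width w_χ = λ/4 = 1.2 μm (the transition width is not pinned
down by the formulation; λ/4 keeps the transition narrow but resolved at
the default grid spacing). The built-in geometries are the two-state
pattern (two 38×38 μm basins joined by a 35 μm long, 10 μm tall bridge),
the 111×38 μm rectangle, a fully adhesive plane, and arbitrary composite
polygon lists from config.

**Polarity.** P(r, t) summarizes front (P > 0) / rear (P < 0) chemistry:

    ∂P/∂t = β f(|r−θ|; σ) δ(t mod τf) ϕ  −  (χϕ)/τχ
            − (1/τs)(s/s0)² H(s−s0) ϕ  −  P/τ,

with Gaussian activity patches f = e^(−|r−θ|²/2σ²) of random amplitude
β ~ N(μβ, σβ) delivered once per period τf at a contour point θ drawn
from the filopodial probability p(θ) ∝ (1 − χ(θ + ℓn̂))·max(P(θ), 0).
The perimeter s is measured as ∫|∇ϕ| d²r (exact for a unit-height front
and cheap enough for every step); the perimeter-triggered inhibition is
localized to the cell by the ϕ factor, reading "uniform" as uniform
within the cell. P is not advected with the boundary (the polarity is
pictured as substrate-anchored).

Design decisions in the polarity model, where the formulation is open:

* Negative polarity carries zero sampling weight (max(P, 0)): p(θ) must
  be a distribution, and positive feedback should not reward contracting
  regions. If every weight vanishes (a fully depolarized cell) the
  scheduler falls back to uniform sampling over the contour to avoid
  deadlock.
* Patch timing: τf need not divide the time step; patches fire at the
  first step whose clock crosses the next multiple of τf, so a duration
  T delivers exactly ⌊T/τf⌋ patches.
* The pulse train δ(t mod τf) is realized as an instantaneous impulse
  (the full β·f·ϕ added at the firing time). An alternative reading —
  the patch acting as a sustained rate β·f·ϕ over its τf window — is
  available as `patch_mode: sustained`. The two readings produce polarity
  fields of very different magnitude (peak P of order a few hundred vs a
  few tens at default parameters). The impulse reading is the default:
  it is the literal reading of the Dirac comb, it is consistent with the
  observation that lengthening τf weakens polarity, and it reproduces
  persistent basin-to-basin hopping on the two-state pattern. Its known
  cost is discussed under "Known limitations".

## Default parameters

Internal units are μm and minutes; tensions are in an arbitrary scale γ0.
The default cell: γ = 0.8 γ0, λ = 4.8 μm, κ = 6000 γ0·μm, R0 = 18 μm,
η = 0.67 γ0·min·μm⁻³, ℳ = 0.75 μm·γ0⁻¹·min⁻¹, α = 1.4 γ0·μm⁻²,
μβ = 7.5, σβ = 37.5, σ = 6.7 μm, s0 = 2π(1.5R0), τf = 2.2 s,
τχ = 9.6 s, τs = 8 min, τ = 4 min, ℓ = 6 μm. Config files accept τf and
τχ in seconds (their conventional units) and convert to minutes.
Knockout flags remove the filopodial substrate factor (p(θ) ∝ P(θ)), the
χ-coupling (τχ → ∞), or the perimeter inhibition (s0 → ∞).

## Numerics

* Uniform grid, dx = 1 μm by default: the logistic interface (10–90%
  width ≈ 3.7 μm) is resolved by ~4 nodes; behavior was checked to be
  stable against refinement to dx = 0.75 μm.
* Explicit Euler in time, dt = 0.01 min, validated against the diffusive
  stability bound dx²/(4ℳγλ) ≈ 0.087 min.
* The advection term is discretized with Godunov upwinding of |∇ϕ|
  (level-set style). Central differencing is spatially unstable here:
  polarity bursts push the local cell Péclet number v·dx/ℳγλ well above
  1, and the resulting grid oscillations nucleate spurious pinch-offs.
* Steps whose normal speed would move ϕ by more than 0.15 per step are
  subdivided adaptively (deterministically, preserving bit
  reproducibility). A step that cannot complete within 400 subdivisions
  marks the run failed rather than continuing silently.
* ϕ is never clipped; overshoot beyond ε_ϕ = 0.02 raises a warning, since
  silent clipping would break the gradient-flow (energy non-increase)
  property that the tests assert.
* n̂ is zeroed where |∇ϕ| < 10⁻⁶/dx; the motility prefactor vanishes
  there anyway.
* The domain extends 20 μm beyond the pattern bounding box with no-flux
  boundaries; the cell is confined by polarity inhibition, not by the
  box, so the boundary condition is a bookkeeping choice. The padding is
  generous because strong polarity bursts can push a protrusion
  temporarily off-pattern (see limitations).
* Initial cells are logistic disks with the level-set radius inflated by
  1/k so that the quadratic area ∫ϕ² starts within ~0.3% of πR0².
* Runs are bit-reproducible given (parameters, pattern, duration, seed);
  ensembles derive run seeds as base_seed + index.
* Rupture: if a second connected ϕ > 1/2 component larger than 5% of
  πR0² appears at a recording instant, the run is flagged ruptured;
  flagged runs stay in the ensemble container but are excluded from
  downstream inference. An escape flag marks centroids leaving the
  pattern bounding box by more than R0/2.

## Trajectory inference

The center-of-mass dynamics are modeled as v̇ = F(x, v) + σ(x, v)η(t) and
F is estimated as the binned conditional mean acceleration. Velocities
and accelerations are forward differences of x(t) downsampled to
Δt_sample = 10 min (matching the cadence of the migration snapshots the
model is compared against); a_k is conditioned on (x_k, v_k) — the
simplest Euler-consistent pairing; the convention is isolated in one
function so it can be switched. Defaults: 36 x-bins over the pattern
extent (or the central 98% of the data), 30 v-bins over the central 98%
of v, bins with fewer than 20 samples masked.

**Discretization bias.** For coarsely sampled underdamped dynamics the
finite-difference velocity shares noise with the acceleration it
conditions, so for a linear (Ornstein–Uhlenbeck) drift −ξv the apparent
slope of F(0, v) is (ρ(ξΔ)−1)/Δ, where ρ(u) = (1−e^(−u))²/[2(u−1+e^(−u))]
is the lag-one autocorrelation of position increments (ρ → 1 − 2u/3 for
small u, reproducing the classical 2/3 attenuation). The helper
`implied_friction_coefficient` inverts this exact relation to recover the
continuous-time friction coefficient from a measured slope; the
qualitative sign of the slope (normal vs "negative" friction) is
unaffected by the bias.

**Streamlines and classification.** Streamlines follow Euler iterates
(x, v) ← (x + v·dt, v + F·dt) with bilinear interpolation that refuses to
read masked bins (a point is supported only if its four surrounding bin
centers are trusted). They terminate where |v| < ε_v and |F| < ε_F
(defaults: 5% of the respective RMS scales), leave the supported region,
or reach the step cap, in which case a loop-closure test (revisit within
one bin diagonal plus net winding about the tail centroid) marks cycling
orbits. Labels: `limit_cycle` if ≥25% of streamlines cycle; `bistable`
if the terminals form two dominant, tight (point-like) clusters at v ≈ 0
separated in x by more than a quarter of the populated x-extent;
`stationary` if terminals lie along v ≈ 0 spread over more than four
x-bins without two such point attractors; `other` otherwise. The
tightness requirement distinguishes genuine fixed-point pairs from chains
of termination points strung along a stationary v = 0 line. Separatrices
are the boundaries, in the seed lattice, between basins of attraction of
different terminal groups. Whole-trajectory bootstrap (resampling runs
with replacement and re-running the full pipeline) quantifies the
sampling variability of labels, terminal points, and separatrices.

## Synthetic fixtures

`synthetic_sde` integrates underdamped SDEs with exactly known drift by
Euler–Maruyama, vectorized over the ensemble: Ornstein–Uhlenbeck
(F* = −ξv, stationary), van der Pol (limit cycle), and a damped double
well (bistable; minima at ±x0). Default scales mimic the cell problem
(x of order tens of μm, v of order 1 μm/min, ξ = 0.2 min⁻¹, noise
0.4 μm·min^(−3/2)) so inference defaults transfer. These fixtures
emulate only the coarse statistical structure of migration data — they
have no shape, no pattern geometry, and additive white noise — so tests
built on them validate the inference machinery, not the cell model.

## Observables

* Friction cut F(x→0, v): count-weighted average of F over x-bins within
  a window (default 10 μm) of the symmetry axis, with a weighted
  least-squares slope over the small-|v| half of the populated range. A
  positive slope is the negative-friction signature (slow cells tend to
  accelerate).
* Hopping times: a hysteretic two-threshold state machine (threshold =
  half bridge length − R0/2, hysteresis 4 μm) detects left↔right
  transitions; dwell times are gaps between successive observed hops, so
  the censored first and last residence periods never enter. Pooled
  histograms use 30-min bins.
* Occupancy: P_left = (T_L/A_L)/(T_L/A_L + T_R/A_R) with basin areas from
  the pattern polygons; bridge transits are excluded from basin time by
  default (the accounting convention for transits is not standardized, so
  it is a parameter).

## Problem sizes used in the checks

The automated checks run the model at desk scale, chosen so the full
suite completes on one CPU: single 75-minute two-state runs for the area
constraint, a 6×12 h two-state ensemble for hopping and the sign of the
friction cut, 100–200 × 48 h synthetic SDE ensembles for drift recovery,
and ~12 replicates of the shape-frozen polarity solve. Production-scale
campaigns (thousands of 48 h runs) use the same code paths through the
CLI and config files; nothing in the package is specific to the reduced
sizes.

## Known limitations

* With the default impulse patch delivery, polarity at an active front
  reaches several hundred (patch arrival ~27/min, mean amplitude 7.5,
  memory τ = 4 min). The resulting propulsion bursts deform the cell
  strongly: the soft area constraint then admits transient area
  deviations of 1–5% (the force-balance offset scales with the front
  thrust), protrusions occasionally coast off-pattern before the
  χ-inhibition (bounded by τ·χϕ/τχ = 25 in polarity units) can reverse
  them, and pinch-off events (a fragment separating and evaporating
  within ~15 min) occur every few simulated hours. These are properties
  of this parameter reading, not of the discretization: they persist
  unchanged under dx and dt refinement. The sustained reading
  (`patch_mode: sustained`) caps polarity near 35, keeps the area within
  ~0.6% and never ruptures, but hops only rarely — the two readings
  bracket the target behavior (persistent hopping together with a
  tightly held area), and neither delivers all of it simultaneously at
  these parameter values. The package keeps the impulse reading as the
  default because persistent hopping is the phenomenon of interest.
* A further consequence of the impulse reading: mid-bridge crossings
  frequently stall and retreat, so the friction cut F(x→0, v) measured
  from desk-scale ensembles decreases monotonically in v — normal
  friction, where the default cell is expected to show a
  negative-friction (rising) segment at small |v|. The corresponding
  check in the test suite is expected to fail and is kept failing rather
  than weakened.
* The center of mass stands in for the nucleus; ϕ-weighting vs
  ϕ²-weighting of the centroid differs negligibly for sharp interfaces.
* No adhesive energy between cell and pattern, no nucleus field, no
  multi-cell interactions, and no advection of P with the boundary.
* The classifier is a set of geometric heuristics on terminal structure;
  near the boundaries between categories (e.g. weakly bistable fields
  under resampling) labels can flip, which is precisely what the
  bootstrap quantifies.
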