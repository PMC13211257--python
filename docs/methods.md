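# Methods

## The model

`ktwsim` simulates *n* microbial species competing for space on a
toroidal hexagonal lattice, with an immune-surveillance rule that
implements kill-the-winner dynamics: whenever the community as a whole
is large and any single taxon is disproportionately abundant, a fixed
fraction of that taxon's cells is removed. The question the model
answers is structural, not quantitative: is a two-threshold,
dominance-directed suppression rule sufficient to maintain high
taxonomic diversity that would otherwise collapse under competitive
exclusion?

### Lattice and state

Sites live on a `width x height` rhombus in axial coordinates
`(col, row)` with periodic boundaries in both axes, so every site has
exactly six neighbors (offsets `(±1,0)`, `(0,±1)`, `(1,−1)`, `(−1,1)`)
and no site is special. Wrap-around eliminates edge effects; lattices
smaller than 3×3 are rejected because wrap-around would duplicate
neighbors. Each site holds at most one cell; state is a flat integer
array with 0 = empty and 1..n = species id. The default lattice is
60×60 (3 600 sites): large enough that all three regimes below are
well resolved, small enough that a 1 000-step run takes about a
second.

### Stochastic update

Each step applies, in order:

1. **Mortality.** Every occupied cell is independently vacated with
   probability *d* (default 0.05 per step). Mortality is what keeps
   space turning over: without it the lattice fills and freezes, and
   neither competitive exclusion nor surveillance-maintained diversity
   can play out. `d = 0` remains available in the config.
2. **Replication.** Surviving cells are visited in a uniformly random
   order; a cell of species *i* replicates with probability *p_i* into
   one empty neighbor chosen uniformly. Cells with no empty neighbor
   cannot replicate (space limitation is the only interaction between
   species). The sequential random order resolves conflicts over shared
   empty sites without bias; cells born within a step do not replicate
   until the next step, so per-step growth is bounded by the current
   population.
3. **Surveillance** (when the schedule is active). The trigger is
   evaluated once per step, after the dynamics; at most one
   penalization event fires per step. Abundances, Hill numbers and the
   event flag are recorded after this check, so a cull is visible in
   the same step's record.

The default roster is four species with replication probabilities
(0.3, 0.5, 0.7, 0.9) — distinct rates with a strong gradient, so that
without surveillance exclusion completes within 1 000 steps.

### The surveillance rule

Two thresholds, both read strictly ("exceeded" means `>`):

- **load**: occupied fraction of *all* lattice sites > 0.70, and
- **dominance**: largest relative abundance among *occupied* sites
  > 0.30.

When both hold, `round(0.80 × count)` cells of the dominant taxon
(ties broken toward the lowest species id; rounding is half away from
zero) are removed uniformly at random. Directing the cull at the
dominant taxon is the kill-the-winner reading of the rule; an
alternative `whole_community` policy that removes 80% of all occupied
cells indiscriminately is retained for sensitivity analysis. Load is
measured against total capacity and dominance against the community
because the two thresholds sense different things: overall microbial
biomass versus within-community imbalance.

Temporal activation is a schedule: `off`, `always`, or half-open
windows `[start, end)` in 0-based step indices, so the intermittent
regime with windows 200–400 and 600–800 is active at steps 200..399
and 600..799 exactly.

### Diversity

Community diversity is reported as Hill numbers — effective numbers of
equally abundant species — at orders q = 0 (richness), 1 (exponential
Shannon), 2 (inverse Simpson):

    D_q = (Σ p_i^q)^(1/(1−q)),  D_1 = exp(−Σ p_i ln p_i)

with zero-abundance species excluded (equivalently 0·ln 0 = 0). Raw
Shannon entropy and Simpson concentration are exposed as secondary
outputs. An empty community has diversity 0 at every order by
convention, so post-collapse trajectories remain representable. The
three defining invariants — scale invariance, non-increase in q with
equality only for uniform abundances, and permutation invariance — are
property-tested.

### Mean-field counterpart

The deterministic twin tracks real-valued abundances under shared
logistic competition with mortality, as a discrete Euler map with step
size 1 (matching the lattice's step semantics):

    x_i ← max(0, x_i + x_i (r_i (1 − S/K) − m)),   S = Σ x_j

followed by the same two-threshold rule: if `S/K` exceeds the load
threshold and the top share exceeds the dominance threshold, the
dominant taxon is multiplied by (1 − removal fraction). A discrete map
was chosen over an ODE because the cull is an instantaneous discrete
event; a smaller Euler step is available as a knob. The shared-capacity
form is the minimal reading of "competitive interactions" — a full
pairwise interaction matrix is deliberately out of scope.

Mortality `m > 0` is essential here too, and for a sharper reason:
with `m = 0` the shared-logistic equilibrium is neutral (any
composition summing to K is stationary) and exclusion never completes.
With `m > 0` and suppression off, the fastest grower excludes all
others and settles at the closed form `S* = K (1 − m/r_max)`; every
other taxon then has strictly negative per-step growth and decays
geometrically. Defaults mirror the lattice: r = (0.3, 0.5, 0.7, 0.9),
m = 0.1, K = 1000, x_i(0) = 25, 1 000 steps. Because multiplicative
decay never reaches exact zero in floating point, survivors are
counted against an extinction tolerance of 1e-6·K, and the recorded
Hill numbers apply the same tolerance.

## The three regimes

With the defaults above:

- **Collapse** (surveillance off): competitive exclusion by the
  fastest replicator; over a 20-seed ensemble the median final
  inverse-Simpson diversity falls below 2 and median richness to 1–2.
- **Maintenance** (surveillance always on): repeated culls of whichever
  taxon approaches dominance hold all four species; median final Hill
  q = 1 and q = 2 stay above 3 and richness stays 4. The same holds
  when replication probabilities are redrawn uniformly in (0.2, 0.95),
  so the outcome does not depend on fine-tuned rates.
- **Intermittency** (windows [200, 400) and [600, 800)): ensemble-median
  q = 2 diversity rises within each active window and declines again in
  the gaps — diversity is a dynamic equilibrium that decays when the
  extrinsic constraint is lifted.

These are ensemble-median properties at fixed, seeded conditions, not
fitted results; the acceptance script recomputes all of them from
scratch.

## Initialization, randomness, reproducibility

Runs start from `round(fraction × sites)` occupied sites (default 10%)
drawn uniformly without replacement and split equally among species
(±1 cell; the remainder goes to the lowest ids) — an unbiased start.
One master seed is expanded via `numpy.random.SeedSequence.spawn` into
five named substreams (initialization, mortality, replication order,
replication target, penalization sampling), so adding draws to one
phase never shifts another phase's stream, and identical config + seed
gives bit-identical trajectories. Every run writes a JSON sidecar with
the fully resolved configuration; re-running from the sidecar alone
reproduces the trajectory exactly.

The replication pass is JIT-compiled with numba when available; the
pure-Python fallback is bit-identical (a dedicated test compares the
two paths on the same draws).

## What the simulations do and do not show

The generator *is* the study system: an abstract spatial community
with identical cells, fixed per-species rates, and a memoryless
surveillance rule. It captures space limitation, demographic
stochasticity and threshold-triggered suppression. It does not emulate
real microbiome data: no strain-level variation or evolution, no
resource or metabolite fields, no migration, no measurement noise or
compositional sampling artifacts, and the suppression rule is a sharp
threshold rather than a graded immune response. Passing tests
therefore demonstrate the *logical sufficiency* of dominance-directed
suppression for maintaining diversity in this idealized setting — not
a quantitative fit to any observed community.

## Numerical and design choices

- Strict inequalities at both thresholds make boundary behavior
  testable: a community at exactly 70% load / 30% dominance is not
  penalized.
- Removal counts use round-half-away-from-zero, so a single-cell
  target (0.8 → 1) is removed and local extinction by penalization is
  possible.
- Trigger evaluation happens once per step after the dynamics; at most
  one penalization event per step.
- Problem sizes in the test and acceptance suites: 20-seed ensembles
  on the default 60×60 lattice for regime properties; 10 000 one-step
  replicates for the binomial-thinning check; brute-force adjacency
  enumeration on lattices up to 5×5; mean-field runs of 1 000–3 000
  steps. These sizes resolve every property cleanly while keeping the
  whole suite around a minute.

## Known limitations

- One organism per site and a fixed lattice; no growth of the habitat.
- The mean-field map is Euler with dt = 1; stability is parameter
  dependent (overshoot past capacity is floored at zero rather than
  integrated accurately). The defaults are well inside the stable
  range.
- The `whole_community` policy is implemented and unit-tested but the
  regime analyses all use the dominant-taxon policy.
- Trajectory recording starts after the first step; the initial state
  is recoverable from the seed but not written as a row.
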