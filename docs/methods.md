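# Methods

## Model

The trail is a ring of `L` unit cells with hard-core exclusion (at most one
ant per cell, no overtaking, no backward motion), descended from the
totally asymmetric simple exclusion process. Ants carry continuous
positions in `[0, L)` and continuous velocities; an ant occupies
`floor(position)` and its "next cell" is the following cell on the ring
(half-open cell convention `[c, c+1)`, cells indexed `0 … L−1`).

Each time step is a two-stage parallel update:

1. **Motion.** Every ant's velocity is computed from the *time-t*
   occupancy and pheromone of its next cell by the four-case rule (blocked
   → 0; meager pheromone `σ < 1` → stochastic slowdown toward `v_min`;
   differentiable pheromone → `v_min + a·σ`; saturating pheromone →
   `v_min + a·σ_sat`), then every position advances by its velocity mod
   `L`. Because all velocities are below 1 and only the unique ant
   immediately behind an empty cell can enter it, the parallel update
   cannot create collisions; the stepper still asserts one-ant-per-cell
   every step and aborts on violation, since a duplicate would indicate a
   bug rather than bad luck.
2. **Pheromone.** Every cell evaporates by the factor `(1 − r_e)`; then
   cells occupied at time *t* and still below `σ_sat` receive a deposit
   `τ`, clamped at `σ_sat`. Evaporation strictly precedes deposition, so a
   cell at `σ′ = 79.5` after evaporation ends the step at exactly 80, not
   80.5.

After stage II a new ant may be injected into the entry cell (cell 0) if it
is empty, with probability `inflow`, id `N`, position at the cell's left
edge and velocity `v_min`. Runs start from a single ant and a pheromone-free
trail and stop at gridlock (`N = L`) or at a hard step cap
(`max_steps`, default 5·10⁶), in which case the partial sweep is flagged
truncated.

### The deposit rule

The published description of this model family gates the deposit on the
occupant having moved (`v_j(t) > 0`). We provide that variant
(`deposit_rule="moving"`) but default to deposition by **every** occupant
of an unsaturated cell (`deposit_rule="occupied"`), for two reasons that we
checked quantitatively:

* The aggregation calculus (below) models a zero-gap platoon passing one
  cell with one deposit per step for `M` consecutive steps. Under
  exclusion, ants with zero headway are blocked most of the time, so a
  motion-gated deposit cannot realise that scenario even approximately:
  in simulation the pheromone of jam-phase cells stalls near ~17 p units
  (at `r_e = 0.02`), far below the converged value
  `τ(1−r_e)/r_e = 49` on which the state boundaries are built.
* With occupancy-gated deposits the jam-phase pheromone approaches the
  converged value, the average velocity stays near-constant through the
  free-flow phase, the rise-up spike appears at the free-flow/jamming
  junction, and the critical density peaks at `r_e ≈ 0.02` with values
  approaching 0.8 as `L` grows — the behaviour this model family is known
  for. Under the motion-gated variant the velocity plateau collapses near
  density 0.62 and the critical-density optimum flattens.

A blocked ant re-entering the meager-pheromone case uses `v_min` as its
carried velocity (the rule's "previous velocity" is ill-defined after a
stop, and `v_min` is the only natural resting value given the slowdown
floor).

### Randomness and reproducibility

One seeded PCG64 generator drives a run. Each step consumes exactly `N`
uniforms (one per ant in id order, consulted only in the meager-pheromone
case) followed by one uniform for the injection gate — also when the entry
cell is occupied — so trajectories are bit-reproducible from the seed. The
production `run()` loop is a numba kernel whose scalar arithmetic uses the
same expressions and draw order as the granular numpy stepper; the test
suite verifies bit-identical trajectories between the two, and against a
deliberately naive per-ant/per-cell Python stepper, over thousands of
steps at three evaporation rates.

## Pheromone calculus

With deposits every step and evaporation in between, the concentration a
follower senses after an `M`-step platoon passage is the geometric sum
`σ(M) = τ·Σ_{k=1..M}(1−r_e)^k` — each of the `M` deposits has evaporated
at least once by the time the cell is read. The single-cell fixture
(`aggregation_fixture`) therefore records two views of the deterministic
recurrence: the post-stage-II value (`deposited`, e.g. constantly `τ` when
`r_e = 1`) and the value after the following step's evaporation
(`sensed`), whose final entry equals the series term-for-term.

For an unbounded platoon the series converges to `τ(1−r_e)/r_e`, clamped
at `σ_sat`. Depletion of a concentration `σ₀` to the differentiable level
1 takes `D = −ln σ₀ / ln(1−r_e)` steps (0 if already at or below 1). Two
boundaries follow:

* **Active/inactive**: `τ(1−r_e)/r_e = σ_sat`, i.e.
  `r_e = τ/(σ_sat+τ)` — exactly `1/81 ≈ 0.01235` at the defaults, printed
  as 0.012. Its algebraic inverse `τ = σ_sat·r_e/(1−r_e)` gives the
  emission rate at which aggregation first saturates (1.6327 at
  `r_e = 0.02`, printed 1.63).
* **Active/minimal**: the converged aggregation must decay below 1 within
  the one-cell traversal time `1/v_min` of a follower (the tightest
  exclusion headway): `τ(1−r_e)/r_e · (1−r_e)^{1/v_min} = 1`. The root is
  found by bisection on `(10⁻⁶, 1−10⁻⁶)` with absolute tolerance `10⁻⁸`
  on a log-scaled residual (monotone in `r_e`); at the defaults it is
  0.19307, printed 0.19. The exponent uses the exact `1/0.15 = 6.667`
  rather than the two-decimal truncation 6.66; both round to 0.19.

Boundary values themselves are classified *active* (closed interval).
Note that 0.012 is a rounding of `1/81`: the rate `r_e = 0.012` is
strictly below the exact boundary (its converged aggregation, 82.3,
exceeds `σ_sat = 80`) and is therefore classified inactive.

## Measurement conventions

Per-step observables are the paper-standard triple: density `N/L`, average
velocity = mean displacement over **all** ants including blocked ones, and
flow = density × average velocity (an exact identity in the output,
re-derivable from the CSV because floats are written with 17 significant
digits). Density bins are right-closed intervals of width 0.005 covering
`(0, 1]`; the **critical density** is the centre of the bin maximising the
binned mean flow after a centred 5-bin moving average, ties broken toward
lower density. The slow-inflow protocol leaves the system long at each
density, so the default burn-in is 0 (retained as a knob). Platoons are
maximal runs of ants whose inter-ant gaps on the ring are at most
`gap_threshold` empty cells (default 2, configurable and reported).

## Problem sizes

The reference protocol (`L = 1000`, inflow 0.001) is directly runnable but
long; the package's standard experiments use proportionally scaled trails,
which preserve the protocol (inflow × trail length held fixed):

* `L = 200`, inflow 0.005 — one gridlock sweep ≈ 2·10⁵ steps, a second or
  two of compute. Critical density at `r_e = 0.02`: 0.68 ± 0.01 across
  seeds.
* `L = 600`, inflow 0.00167 — ≈ 3·10⁶ steps. Critical density 0.7525 on
  each of three seeds.

The junction density rises with trail length (0.69 → 0.74 → 0.75 at
`L = 200, 400, 600`), approaching the reference-scale value ≈0.8 from
below; the evaporation-rate optimum (`r_e = 0.02` on the coarse grid
{0.005, 0.01, 0.02, 0.05, 0.1}) is already stable at `L = 200`.

## What the generator does and does not emulate

The simulator *is* the study system — there is no external data. It
captures exclusion, chemotaxis with antenna saturation, stochastic
slowdown under meager pheromone, evaporation and slow recruitment onto a
closed trail. It does not model open boundaries, backward motion,
overtaking, heterogeneous cell resistance, multi-lane or bidirectional
traffic, or the receptor response threshold (the smallest concentration
change an ant can act on); passing tests therefore say nothing about
those aspects of real trails. The periodic boundary also makes the
inactive state an artefact of recirculation — on a natural open trail
pheromone would not accumulate without bound at low evaporation.

## Numerical choices and limitations

* Velocities live in `{0} ∪ [v_min, v_min + a·σ_sat]`; parameter
  validation enforces `v_min + a·σ_sat ≤ 1`, which also guarantees at most
  one cell-boundary crossing per step.
* Pheromone is clamped to `[0, σ_sat]` every step; the clamp applies to
  every occupied cell regardless of the occupant's velocity.
* The minimal-state boundary solver raises if the residual has no sign
  change in `(0, 1)` (e.g. extreme `τ`), and the classifier raises when
  the two boundaries cross (no active window).
* Critical-density estimates are quantised to the bin width (0.005); seed
  spread at the scales above is a few bins.
* The fundamental diagram near gridlock is sampled heavily (the last hole
  takes the longest to fill), which slightly weights the jamming tail;
  this does not affect the argmax-based junction estimate.
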