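# anttrail

Agent-based simulation and closed-form analysis of pheromone-mediated ant
traffic on a periodic one-dimensional trail.

Foraging ants on a trail maintain a near-constant average velocity over a
wide density range and so avoid the stop-and-go congestion typical of
vehicular traffic. The mechanism is stigmergic: each ant deposits pheromone
as it travels, and each ant sets its speed from the pheromone concentration
in the cell ahead — a proxy for the traffic flow of the recent past.
`anttrail` implements a stochastic lattice model of this system (an
exclusion process with chemotactic velocities) together with the
geometric-series calculus of pheromone aggregation and depletion that
delimits the trail's three communication regimes. It is aimed at
researchers in collective animal behaviour and traffic physics who want a
reproducible, tested reference implementation of the model and its
analytic boundaries.

## Model

A ring of `L` unit cells holds at most one ant per cell (hard-core
exclusion; no overtaking). Ant *j* carries a continuous position `p_j` and
velocity `v_j`. Writing `s_i ∈ {0,1}` for the occupancy and `σ_i ≥ 0` for
the pheromone of cell *i*, each time step first updates all ants in
parallel (stage I), then the pheromone field (stage II):

**Stage I — motion.** With cell `i+1` ahead of ant *j*:

```
v_j(t) = 0                        if s_{i+1} = 1
       = max(v_j(t−1) − 0.1, v_min)  w.p. P,  else v_j(t−1)
                                  if s_{i+1} = 0 and σ_{i+1} < 1
       = v_min + a·σ_{i+1}        if s_{i+1} = 0 and 1 ≤ σ_{i+1} < σ_sat
       = v_min + a·σ_sat          if s_{i+1} = 0 and σ_{i+1} ≥ σ_sat

p_j(t+1) = (p_j(t) + v_j(t)) mod L
```

**Stage II — pheromone.** Every cell evaporates, `σ_i ← σ_i(1 − r_e)`;
then every cell occupied at time *t* receives a deposit `τ`, clamped at the
antenna saturation `σ_sat`. (A `deposit_rule="moving"` variant restricts
deposits to ants with `v_j(t) > 0`; see `docs/methods.md` for why the
occupancy-gated rule is the default.) Finally, a new ant enters the empty
entry cell with probability `inflow`, so a single run sweeps density from
`1/L` to gridlock and traces the entire fundamental diagram.

Defaults: `L=1000, r_e=0.02, τ=1, σ_sat=80, v_min=0.15, a=0.01, P=0.7,
inflow=0.001`.

**Communication states.** Behind a long platoon the pheromone of a cell is
the geometric sum `σ(M) = τ·Σ_{k=1..M}(1−r_e)^k → τ(1−r_e)/r_e`, and once
the platoon has passed it depletes to the differentiable level 1 in
`D = −ln σ₀ / ln(1−r_e)` steps. Comparing these scales with the one-cell
traversal time `1/v_min` splits the evaporation-rate axis into three
regimes: **minimal** (`r_e` above ≈0.19 — information erased before the
next ant can read it), **active** (pheromone encodes recent-past flow;
congestion-free traffic, critical density maximal near `r_e ≈ 0.02`) and
**inactive** (`r_e` below `τ/(σ_sat+τ) ≈ 0.012` — pheromone saturates and
becomes uninformative).

## Worked example

Closed-form report for the default active-state parameters:

```
$ anttrail analytics --re 0.02 --tau 1 --sigma-sat 80 --vmin 0.15
{
  "converged_aggregation": 49.0,          # τ(1−re)/re: pheromone behind a long platoon
  "depletion_time": 192.64,               # steps for 49 to evaporate below 1
  "one_cell_traversal_time": 6.67,        # 1/vmin, printed as 6.66 truncated
  "boundary_minimal": 0.1931,             # active/minimal boundary (≈0.19)
  "boundary_inactive": 0.01235,           # active/inactive boundary (≈0.012)
  "saturation_tau": 1.6327,               # τ at which aggregation saturates (≈1.63)
  "state": "active"
}
```

A full density sweep on a scaled trail (one fifth of the reference length,
inflow scaled accordingly) and its fundamental diagram:

```
$ anttrail simulate --L 200 --inflow 0.005 --seed 1 --out-metrics metrics.csv
steps=214316 termination=gridlock metrics=metrics.csv
$ anttrail fd --in metrics.csv --bin-width 0.005
critical_density=0.6925
```

The run injects ants one by one until gridlock (214,316 steps here), and
the flow-density diagram peaks at density 0.69 — the free-flow/jamming
junction, preceded by the characteristic "rise-up" velocity spike. On
longer trails the junction moves toward the reference value ≈0.8 (0.75 at
`L=600`); at this scale it is depressed by a finite-size effect.

The deterministic single-cell aggregation scenario, which the simulator's
pheromone stage reproduces exactly:

```
$ anttrail scenario aggregation -M 3 --re 0.02
 step  deposited   sensed
    1     1.0000 0.980000
    2     1.9800 1.940400
    3     2.9404 2.881592
final_sensed=2.881592        # = τ·Σ_{k=1..3}(0.98)^k
```

`anttrail sweep --param re --grid 0.005,0.01,0.02,0.05,0.1 --seeds 1,2,3`
repeats the protocol over an evaporation-rate grid; the critical density is
maximal at `r_e = 0.02`.

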