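# Methods

## Model

The simulation couples two state sets: per-agent antisocial levels
`e_i(t) ∈ [0, 1]` and a directed weighted peer network
`A_ij(t) ∈ [0, 1]` with a fixed zero diagonal. Time is synchronous and
discrete; one tick evaluates, strictly from time-`t` values,

1. the antisocial history `h_i(t)` — the running mean of `e_i` over
   steps `0..t` inclusive;
2. peer influence `d_ij = c A_ij (e_j − e_i)`, `j ≠ i`;
3. the reward `a_i(t) = min(γt/(r_i T), γt_p/(r_i T), 1)` with
   `r_i = 1 − e_i(0)` the intrinsic prosocial level, fixed at
   construction;
4. the commitment cost `b_i(t) = (1 − h_i(t)) f(t)`, with
   `f(t) = 1/(e^{−(t−t_p)/k} + 1)`;
5. the net reward `g_i = a_i − b_i ∈ (−1, 1)`;
6. the network update: `ΔA_ij = (g_i/Δe)(e_j − e_i)` inside the mimicry
   window `|e_j − e_i| < Δe`, zero outside (the boundary `= Δe` is
   outside); applied as `A += ΔA(1 − A)` when `ΔA ≥ 0` and
   `A += ΔA·A` otherwise, which maps `[0, 1]` into itself for any
   `ΔA ∈ [−1, 1]`;
7. the level update `e_i(t+1) = e_i(t) + (1/N) Σ_j d_ij(t)` with the
   self contribution `d_ii = g_i(1 − e_i)` if `g_i ≥ 0`, else `g_i e_i`
   on the diagonal.

The network is updated (step 6) before the levels (step 7), and both
read only time-`t` quantities, so the ordering of 6 and 7 does not
feed back within a tick.

Assumptions worth making explicit: the cohort is closed (agents enter
or leave only via the transplant operation); the network is complete
and weighted, with no topology generation; the dynamics are
deterministic — all randomness lives in the initial condition; and the
reward/cost constructs are dimensionless indices, not calibrated to any
empirical offending scale.

## Parameters

| name | symbol | default | meaning |
|---|---|---|---|
| `n_agents` | N | 30 | cohort size (one school class) |
| `n_steps` | T | 300 | horizon; 1 step ≈ 1 month, ages ≈ 7–32 |
| `turning_point` | t_p | 120 | step of assuming adult roles (≈ age 17); reward plateau and cost-sigmoid midpoint |
| `sigmoid_steepness` | k | 20 | time scale (steps) of the cost switch-on |
| `influence_rate` | c | 0.1 | peer-imitation rate per unit weight |
| `reward_rate` | γ | 0.2 | growth rate of the maturity-gap reward |
| `mimicry_window` | Δe | 0.2 | maximum level difference for network adaptation |

The benchmark values are the studied operating point; the sensitivity
machinery perturbs `k, c, γ, Δe` by ±50% (`δ = 10, 0.05, 0.1, 0.1`).
The configuration layer warns — but does not refuse — outside these
ranges, because the model's behavior is only characterized within them.
With the benchmark values the level update is provably bounded:
`((N−1)c + 1)/N < 1`, so `e` can never leave `[0, 1]`; the update
asserts this rather than clipping, and a violation (possible when
`c > 1`) raises loudly.

## Initialization (the synthetic-data generator)

Initial antisocial levels are Normal(0.5, 0.1) draws rejection-sampled
into `[0, 1]` (at five standard deviations from both bounds the
truncation is negligible). Connections get one Uniform(0, 1) draw per
unordered pair, mirrored to both directions, then rescaled once by
`r_i r_j` — never again — so the initially antisocial agents start
peripheral. Draw order is fixed (levels first, then pair weights in
row-major upper-triangle order), making the entire initial condition a
pure function of one seed. Every ensemble member, network search
attempt and transplant uses fresh draws from an explicitly passed
generator; no global RNG state is touched.

What the generator emulates: a single-classroom cohort with mildly
heterogeneous dispositions and dense, disposition-biased friendships.
What it does not: demographic turnover, external (out-of-class)
contacts, assortative or sparse topologies, measurement noise, or any
empirically calibrated distribution of dispositions. Passing tests
therefore demonstrate internal consistency of the mechanism, not
predictive validity for real cohorts.

## Outcome definitions

* An agent is **life-course-persistent** iff its final level strictly
  exceeds the classification threshold (default 0.5, the value the
  intervention protocol uses; 0.6 and 0.7 behave equivalently because
  the two final groups are separated by a wide gap). Everyone else is
  **adolescence-limited**.
* The **offending curve** counts agents with `e_i(t) > threshold` at
  each recorded step, strict inequality.
* The **largest-gap rule** sorts final levels ascending and takes the
  adjacent pair with the maximum difference; ties break toward the
  lowest sorted position (deterministic and seed-independent). All
  levels identical is an error — there is no gap.
* Ensemble outcomes are binned by the adolescence-limited *count*
  (`N + 1` bins of width `1/N`; a fraction of exactly 1 is the top
  bin). Counts are integers, so the binning is exact, with no
  floating-point edge cases.

## Divergences

The Kullback-Leibler divergence uses the convention that a term with a
zero denominator bin contributes zero (the log argument is treated
as 1); zero-numerator terms vanish as usual. The Jensen-Shannon
divergence is the standard symmetric form,
`JSD(p, q) = [KLD(p‖m) + KLD(q‖m)]/2` with `m = (p + q)/2`; its
reference mixture is nonzero wherever either argument is, so the
convention never fires there, and the value is bounded by `ln 2`.
Gradients are one-sided differences: `JSD(F(p0), F(p±))/δ`. The
benchmark distribution `F(p0)` is computed once per study and shared
across all eight comparisons.

## Intervention protocol

Rough (≥ 5 persistent agents) and mild (none) networks are found by
rejection sampling over fresh initial conditions; every accepted
network's seed is recorded, and the search error reports the observed
persistent-count distribution when it exhausts its attempt budget.
Focal agents are selected on **final** levels of the rough run (the
gap rule is defined on end-of-run grouping; the guaranteed agents are
the argmin/argmax, which almost always coincide with the initial-level
extremes). Only the focal agent's **initial** level is transplanted.
The mild network's own initial condition is replayed exactly; the
transplant's connections are fresh uniform draws rescaled with the
`t = 0` intrinsic prosocial levels of the mild agents, and the enlarged
run uses `N + 1` everywhere, including the level-update divisor. The
four scenarios of one pair share the mild base but draw the
transplant's connections independently. Reported intervals are sample
standard deviations over pairs, not standard errors.

## Numerical choices

* **History divisor.** The antisocial history is a true mean over the
  `t + 1` recorded steps `0..t` (including the current one). A divisor
  of `t` would be undefined at `t = 0` and could push the history above
  1 (and the cost below 0); the mean keeps both quantities in `[0, 1]`
  at every step. This is the one place the implementation deliberately
  regularizes the model's printed form; the effect is `O(1/t)` and
  negligible after the first few steps.
* Branch conditions (`g ≥ 0`, the window comparison) use exact
  floating-point comparisons; no tolerance-based branching.
* The cost sigmoid is evaluated in its numerically stable split form,
  exact for all arguments.
* All state is double precision; trajectories store `T + 1` level rows
  (row 0 is the initial condition) and `T` diagnostic rows.
* Seeds handed to search attempts are drawn below `2^31`; ensemble
  generators derive from an explicit master seed.

## Problem sizes

The test suite runs single benchmark trajectories (milliseconds each),
100-run ensembles for emergence checks, 1000-run ensembles per
parameter set for the sensitivity study, and 50 network pairs for the
intervention experiment — the sizes at which the headline quantities
are defined. The acceptance script uses the same sizes (1000 ensemble
runs, 50 pairs). Unit tests use cohorts of 2–10 agents and short
horizons where only the mechanism, not the regime, is under test.

## Known limitations

* The emergent split is razor-sensitive to the balance between the
  reward plateau `γ t_p/(r_i T)` and the late-time cost `1 − h_i`: the
  survival boundary in initial-level space moves substantially for
  modest changes in effective reward scale (the sensitivity study
  quantifies this — the reward rate dominates the JSD gradient by more
  than an order of magnitude in the forward direction). Conclusions
  about the *size* of the persistent group are therefore far less
  robust than conclusions about its *existence*, the bimodal gap, the
  offending-curve shape, or the ordering of intervention effects.
* Peer influence acts through all connections at all times; only the
  network adaptation is windowed. Distant groups therefore keep
  exerting pull through whatever weight remains frozen between them.
* The intervention is purely structural (a network swap); it does not
  model any programmatic intervention content.
* With benchmark parameters, rough networks are rare under the
  baseline dynamics, so the rejection search — not the simulation — is
  the dominant cost of the intervention experiment.
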