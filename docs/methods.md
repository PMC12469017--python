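# Methods

## The generalized SI model

The epidemic state is the set `B ⊆ V` of infected nodes. Each
susceptible node `u` carries an exponential clock with hazard `λ_u(B)`;
the hazards satisfy `λ_u(∅) = 0` and `λ_u(B′) ≤ λ_u(B)` for
`B′ ⊆ B`. Because every clock is exponential and clocks are
independent across `(u, B)`, only the clock for the *current* infected
set matters: the process is a continuous-time Markov chain on infected
sets, with total outflow `Λ(B) = Σ_{v∉B} λ_v(B)` and jump probabilities
`λ_w(B)/Λ(B)`. We implement this memoryless reading directly; whether
clocks "persist" across state changes is unobservable, since
re-sampling an exponential clock leaves the law of the process
unchanged. For the same reason the argmin over competing clocks is
almost surely unique, and the simulator (`si.simulate`, a standard
Gillespie scheme) draws the next node categorically without any tie
handling.

Two hazard representations are provided. `GraphRateModel` is the
classical per-edge-clock SI process (`λ_u(B)` = sum of incident edge
rates from `B`); `TableRateModel` stores explicit hazards for every
`(u, B)` pair and is intended for ground sets of a handful of nodes.
Querying the hazard of an already-infected node raises instead of
returning 0, and a missing table entry raises instead of defaulting —
both silent conventions have hidden caller bugs in our experience.
Random number generators are never implicit: `simulate` requires a seed
(or a `numpy` `Generator`).

## Exact snapshot likelihoods

The probability that exactly the set `S` is infected at time `t`, given
source set `W`, is a finite sum over permitted infection sequences
(orderings of `S \ W` whose every step has positive hazard). One
sequence `u_1, …, u_k` visits states `B_1 = W, B_2, …, B_k` and then
sits at `S`; its contribution is the `(1, k+1)` entry of `exp(Q t)` for
the upper-bidiagonal generator

```
diag(Q) = (−Λ(B_1), …, −Λ(B_k), −Λ(S)),   Q[l, l+1] = λ_{u_l}(B_l).
```

Two numerical choices deserve comment.

* **The terminal diagonal.** After the last infection the snapshot is
  only observed if no node *outside* `S` fires before `t`; this
  survival factor is `exp(−Λ(S) t)` and is encoded by the last diagonal
  entry. It equals 1 exactly when `S = V`, where it silently
  disappears — a partial-snapshot subtlety that the independent CTMC
  oracle (below) confirmed. A formulation that sets the recursion's
  base case to the constant 1 is correct only for `S = V`.
* **Matrix exponential, not partial fractions.** The sequence term is a
  hypoexponential-with-leakage probability. The classical
  distinct-rate partial-fraction formula is numerically explosive when
  total rates repeat or nearly repeat (they do whenever hazards are
  symmetric), so we evaluate the matrix exponential of the bidiagonal
  generator instead (`scipy.linalg.expm`, k ≤ 10 states), and clamp the
  ~1e-16 roundoff into [0, 1].

`ctmc_likelihood` is a deliberately independent second route: it builds
the dense generator of the Markov chain on the sublattice `[W, S]`,
pools every infection outside `S` into one absorbing escape state, and
exponentiates. The two routes share no code beyond hazard evaluation
and agree to 1e-9 on random non-modular hazard tables; this dual-route
check is the backbone of the likelihood test suite. The enumeration
route is guarded at `|S \ W| ≤ 10` (factorial growth), the lattice
route at 14 (2^m states).

## Source estimators

* `ml_first_k` scores `W` by the embedded jump-chain probability that
  the first `|S \ W|` infections are exactly `S \ W` — holding times
  cancel, so the score is a sum of products `λ/Λ` over permitted
  sequences.
* `jml` scores `W` by `sup_t P[set(U(t)) = S]`. The supremum is taken
  over a log-spaced grid `10^{-3}…10^3` (50 points) refined by bounded
  scalar minimization around the best grid point, then compared with
  the analytic `t → ∞` limit: the absorption probability of `S`
  (equal to the first-k score) when `Λ(S) = 0`, else 0. Ties resolve
  toward the larger value, reporting `t = ∞` when the limit dominates.
* `ml_random_time` integrates the snapshot likelihood against an
  observation-time law (point mass, exponential, uniform, or tabulated
  density; adaptive quadrature at tolerance 1e-8). Estimators return
  *all* maximizers within relative tolerance 1e-9 plus a `degenerate`
  flag — reporting a single argmax would hide exactly the failure mode
  the likelihood analysis exposes. Default hypotheses are the
  singletons of `S` (single-source detection).

On the 3-node unit-rate path with everything infected, both classical
estimators score exactly 1 for all three singletons (the first because
every permitted sequence from an endpoint has jump probabilities 1,
and the two sequences from the center have probability ½ each; the
second because the snapshot probability of the full set tends to 1 for
any source on a connected graph). The random-time estimator strictly
prefers the center at every finite `t` — `(1−e^{−t})² >
1−e^{−t}−te^{−t}` for all `t > 0` — hence under every observation-time
law.

## Linking functions and multicast capacities

Capacity is expressed through a linking function `λ(B, C)`; the
weighted-digraph case is the modular sum of arc capacities from `B` to
`C`. Normalization, monotonicity, bisubmodularity, and submodularity of
the incut `f(C) = λ(V∖C, C)` are implemented as *checkers*, not
enforced invariants: verifying them is exponential, so the checkers are
exhaustive only on tiny ground sets (quadruple checks at `|V| ≤ 3`,
pair checks at `|V| ≤ 8`) and seeded-random elsewhere. Non-graph
oracles enter through an opaque callable interface; only evaluation is
assumed.

The four directed capacities:

* `ρ_ms` and `ρ_ma` are linear programs over nonnegative per-node rate
  vectors, with one cut constraint per qualifying subset (`B` not
  covering the sink set, or `B` disjoint from it). Constraints are
  enumerated explicitly; the guard is `|V| ≤ 16`, which keeps the
  enumeration to seconds at desk scale. A constraint-generation mode
  with a min-cut separation oracle would lift this but is out of scope.
  Solved with HiGHS via `scipy.optimize.linprog`; determinism of
  results is obtained by *verifying the witness* (the optimal rate
  vector is checked against every constraint at tolerance 1e-9), not by
  pinning solver internals.
* `ρ_ss` contracts the source set to a supernode and takes the minimum
  over sinks outside `S` of an s–j max-flow (`networkx`); sinks already
  inside `S` are trivially served and skipped, and the value is `+∞`
  when `S` covers all sinks. An exhaustive subset-minimization route is
  kept for general oracles and as the fast path's test oracle.
* `ρ_uc` contracts both sides and solves one max-flow; `+∞` when
  source and sink sets intersect.

`+∞` is an explicit sentinel (`math.inf`, serialized as `"inf"`);
boundary conventions are `ρ(∅, A) = 0` and `ρ(S, ∅) = ∞`. Unit-capacity
instances produce integral optima up to 1e-9, and the test suite
asserts them as integers after rounding within that tolerance.

### Undirected networks

An undirected edge has a total capacity that must be divided between
its two directions. The package's default (`method="orientation"`)
assigns each link a single direction and optimizes all directions
jointly with the rate vector (for `ms`/`ma`) or jointly with the worst
qualifying cut (for `ss`/`uc`) — one mixed-integer LP with a binary
variable per edge, solved by HiGHS (`scipy.optimize.milp`). This is the
reading under which the worked butterfly values hold: re-directing
links lets the single source 3 route 2 bits to both sinks, while
source 1, with only two incident links that must also serve each other's
sink, is capped at 1.

A fractional relaxation (`method="fractional"`) splits each edge
capacity into two nonnegative directed parts — a point of the
orientation base polytope — and solves the joint LP. The relaxation
upper-bounds the integral value and the gap is real: from source {1} on
the unit butterfly the split LP attains 1.5 (time-sharing two
orientations), versus 1 for any single orientation. We keep the
integral reading as the default because it reproduces the worked
routing/coding examples that anchor the rest of the package and because
a physical link carries traffic in one direction at a time at the
granularity the worked examples assume; users studying time-shared or
coded undirected operation should use the relaxation deliberately. Both
report the chosen split and rate vector as a verifiable witness.

## Source selection

All selection routines take the capacity kind and orientation as
parameters and count every capacity evaluation.

* **Backward elimination** starts from `V`, scans nodes in ascending
  ground order, and drops a node whenever the remainder stays feasible
  (`ρ ≥ r − ε`, ε = 1e-9). Monotonicity of `ρ` in the source set makes
  the survivor inclusion-minimal, at ≤ |V|+1 evaluations. The survivor
  depends on scan order; `minimal_feasible_sources` (exhaustive over
  the subset lattice, guarded at 12 nodes, pruning supersets of found
  minimal sets — sound again by monotonicity) is the order-free ground
  truth.
* **Greedy forward search** runs exactly `k` rounds and evaluates every
  remaining node each round — `k·|V| − k(k−1)/2` evaluations — adding
  the node of maximal marginal gain, smallest label on ties (an
  incumbent rule that lets later equal-gain candidates overwrite would
  make the output order-dependent for no benefit). When the capacity is
  submodular in the source set (the unicast capacity is), the selected
  set achieves at least `1 − 1/e` of the exhaustive size-`k` optimum.
* **Lazy greedy** seeds a priority queue with the singleton capacities
  and re-evaluates an entry only when it reaches the top of the queue
  with a stale cached gain; a fresh top entry is selected immediately.
  Each node is re-evaluated at most once per round, so the call count
  never exceeds plain greedy's, and under monotone submodular
  capacities the selected set and tie-breaking match greedy exactly.
  For the non-submodular multi-source LP the equality is checked on
  fixtures rather than guaranteed.
* **Degenerate candidates.** Under the colluding kinds a candidate
  source set that already contains sinks has capacity `+∞` — the cut
  family is empty, and the query certifies nothing about spreading
  ability. Selection routines still *evaluate* such candidates (keeping
  the call-count formula exact) but never *select* them, and
  `brute_force_optimum` skips them. Backward elimination needs no
  special case: `∞ ≥ r` simply lets elimination proceed.

## Synthetic graphs and experiments

The generators produce Barabási–Albert (`m = 2` by default),
Watts–Strogatz (`k = 4`, `p = 0.1`), and Erdős–Rényi (`p = 0.2`)
graphs, cleaned for connectivity (ER resamples with an incremented
seed; the WS variant used is the connected one), converted to directed
graphs with arcs from lower to higher index and unit capacities. These
defaults are plain community conventions for "a sparse scale-free /
small-world / homogeneous random graph"; every parameter is
overridable and every record carries its seed. Under the low→high
orientation only higher-indexed nodes are reachable, so experiment
drivers place sinks at the highest indices by default — a sink no
source can reach makes every capacity query trivially zero.

Two drivers reproduce the qualitative large-graph diagnostics:
`run_rate_sweep` (achieved rate versus budget `k`; nondecreasing, and
saturating at the min-cut bound `ρ_uc(V∖A, A)` into the sinks) and
`run_scaling` (oracle calls versus graph size at fixed `k`; plain
greedy is exactly linear by the closed-form count, lazy greedy is
bounded by it and empirically several times smaller). The shipped tests
run these at up to 400 nodes with `k = 10`, sizes chosen to exercise
the linear regime while keeping the default suite in a couple of
minutes.

What the synthetic setup does *not* emulate: real contact networks
(degree correlations, communities, weights), observation noise (false
positive/negative infections), multiple interacting cascades, or
non-exponential waiting times. Passing tests therefore certify the
estimators and algorithms against their stated models, not robustness
to model misspecification.

## Known limitations

* Likelihood computations are exact but exponential in `|S \ W|`; they
  are tools for small snapshots and for validating approximations, not
  for hundred-node cascades.
* `ρ_ms`/`ρ_ma` enumerate `2^{|V|}` constraints (guard 16 nodes);
  `ρ_ss`/`ρ_uc` scale to large graphs through max-flow.
* The undirected MILP grows with `2^{|V|}` constraint rows as well; at
  desk scale (≤ 16 nodes) HiGHS solves it in milliseconds.
* Checker functions sample rather than prove structural properties on
  all but tiny ground sets.
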