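# sourceflow

Contagion source detection on networks, for epidemiologists and network
scientists who observe *where* an infection (or rumor) has spread but not
*when* each node was reached. The package answers two questions:

1. **Likelihood-based detection.** Given a snapshot `S` of infected nodes
   at observation time `t`, which source hypothesis `W` maximizes
   `P[infected set at t = S | source = W]` under a
   susceptible–infectious (SI) model? The package computes this
   likelihood *exactly*, exposes why the classical estimators are
   degenerate, and provides the random-observation-time estimator that
   fixes them.
2. **Rate-constrained detection.** If the rumor is known to reach a sink
   set `A` at rate at least `r`, which source sets `S` have multicast
   capacity `ρ(S, A) ≥ r`? The package computes the four standard
   multicast capacities on directed and undirected networks and finds
   minimal feasible or budget-optimal source sets.

## The models

**Generalized SI model.** For a finite node set `V`, each susceptible
node `u` is infected after an exponential time with set-dependent hazard
`λ_u(B)` given the infected set `B`, with `λ_u(∅) = 0` and `λ_u`
monotone. On a weighted graph, `λ_u(B) = Σ_{w∈B} λ_wu` recovers the
classical per-edge-clock SI process. The snapshot likelihood is a finite
sum over *permitted infection sequences* (orderings of `S \ W` with
positive hazard at every step); each sequence contributes a phase-type
probability, evaluated as a matrix exponential of the bidiagonal
generator with diagonal `−Λ(B_1), …, −Λ(B_k), −Λ(S)` and off-diagonal
`λ_{u_l}(B_l)`, where `Λ(B) = Σ_{v∉B} λ_v(B)`.

Three estimators are built on this likelihood:

| estimator | score of hypothesis `W` |
|---|---|
| first-k ML | `P[first k infected nodes = S]` (jump-chain probability) |
| joint ML (JML) | `sup_t P[infected set at t = S]` |
| random-time ML | `E_T P[infected set at T = S]` for an observation-time law `T` |

On the 3-node path `0–1–2` with all nodes infected, both classical
scores equal exactly 1 for *every* candidate source — the estimators
are degenerate — while the random-time score uniquely identifies the
center at every fixed `t` and for every observation-time distribution.

**Multicast capacities.** On a capacitated digraph with cut function
`λ(B, V∖B)`, four source-to-sink capacities are computed, distinguished
by collusion: `ρ_ms` (independent per-node rates; an LP with one
constraint `r(B) ≤ λ(B, V∖B)` per subset `B` not covering the sinks),
`ρ_ss` (colluding sources; a min over sinks of max-flows after
contracting the source set), `ρ_ma` (colluding sinks), and `ρ_uc` (both;
a single s–t max-flow). They satisfy `ρ_ss, ρ_ma ∈ [ρ_ms, ρ_uc]`.
Undirected networks additionally optimize the direction of every link
(solved as one mixed-integer LP; a fractional-split LP relaxation is also
provided). Source selection uses backward elimination (inclusion-minimal
feasible set in ≤ |V|+1 capacity calls), exhaustive enumeration, and
greedy / lazy-greedy forward search with the `1 − 1/e` guarantee when
the capacity is submodular in the source set (the unicast capacity is).

## Worked example

```sh
python examples/butterfly_capacity.py
```

prints, for the unit-capacity butterfly network (nodes 1–6, arcs
1→3, 2→3, 1→5, 2→6, 3→4, 4→5, 4→6, sinks {5,6}):

```
directed butterfly, sinks {5,6}:
  rho_ms([1, 2]) = 2   (47 cut evaluations)
  rho_ms([1]) = 1   (47 cut evaluations)
  ...
undirected butterfly (optimally directed links), sinks {5,6}:
  rho([3]) = 2   (fractional-split relaxation: 2)
  rho([1]) = 1   (fractional-split relaxation: 1.5)
```

Sources {1,2} jointly deliver 2 bits by network coding while every
useful singleton delivers 1 by routing — so observing a rumor rate
above 1 identifies {1,2} unambiguously. When links can be re-directed,
the single source {3} also achieves 2, and the feasible-source family
changes accordingly. The other scripts in `examples/` demonstrate the
estimator degeneracy (`degenerate_estimators.py`), feasible-source
search (`feasible_sources.py`), greedy versus lazy-greedy selection
(`greedy_selection.py`), and simulation plus snapshot scoring
(`simulate_and_score.py`).

A thin CLI mirrors the library:

```sh
sourceflow capacity --graph butterfly.tsv --sources 1,2 --sinks 5,6 --kind ms
sourceflow detect --graph path3.tsv --infected 0,1,2 --time-dist exp:1.0
```

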