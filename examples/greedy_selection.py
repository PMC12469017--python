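"""Size-constrained source selection: greedy versus lazy greedy.

On a 100-node Erdos-Renyi graph (unit capacities, edges oriented from
lower to higher index, sinks = the two highest-indexed nodes) both
algorithms pick the same sources and achieve the same unicast rate, but
the lazy variant re-evaluates only stale cached gains and makes far
fewer capacity-oracle calls.
"""

import sourceflow as sf
from sourceflow.experiments import greedy_call_count, saturation_bound

model = sf.build_fixture("er", n=100, p=0.06, seed=7)
A = set(model.ground.nodes[-2:])
k = 10

greedy = sf.greedy_forward(model, A, k, "uc")
lazy = sf.lazy_greedy(model, A, k, "uc")

print(f"sinks {sorted(A)}, budget k={k}")
print(f"greedy: rate {greedy.rate:g}, sources {sorted(greedy.selected)}, "
      f"{greedy.oracle_calls} oracle calls "
      f"(= k*n - k(k-1)/2 = {greedy_call_count(100, k)})")
print(f"lazy:   rate {lazy.rate:g}, sources {sorted(lazy.selected)}, "
      f"{lazy.oracle_calls} oracle calls")
print(f"min-cut bound into the sinks: {saturation_bound(model, A):g}")

report = sf.run_rate_sweep(model, A, range(1, 11), "uc", "lazy")
print("\nrate versus budget:", [rec["rate"] for rec in report.records])
print(
    "\nThe achieved rate is nondecreasing in k and saturates at the min-cut"
    "\nbound; lazy greedy reaches the identical answer with a fraction of"
    "\nthe capacity evaluations."
)
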