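"""Simulate an SI outbreak, then score source hypotheses on the snapshot.

A Gillespie simulation spreads an infection from a hidden source on a
small ring-with-shortcuts graph; the snapshot (infected set at the
observation time, timestamps discarded) is then scored with the
random-observation-time ML estimator.
"""

import sourceflow as sf

edges = [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (3, 4, 1.0),
         (4, 5, 1.0), (5, 0, 1.0), (0, 2, 0.5), (3, 5, 0.5)]
model = sf.GraphRateModel.from_edges(edges, directed=False)

true_source = 3
t_obs = 0.5
traj = sf.simulate(model, {true_source}, t_max=t_obs, seed=12)
S = traj.infected
print(f"true source: {true_source}, observation time: {t_obs}")
print(f"infection order: {traj.sequence}  ->  snapshot {sorted(S)}")

res = sf.ml_random_time(
    model, S, sf.ObservationTimeDistribution.point(t_obs)
)
print("\nhypothesis scores (snapshot likelihood at the observation time):")
for W, score in sorted(res.scores.items(), key=lambda kv: -kv[1]):
    marker = " <- argmax" if W in res.argmax else ""
    print(f"  source {sorted(W)}: {score:.6f}{marker}")
print(
    "\nThe estimator ranks candidate sources by how probable the observed"
    "\nsnapshot is; with enough spread the true source need not win every"
    "\nrun, but scores concentrate around it."
)
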