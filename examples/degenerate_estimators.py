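"""Why classical snapshot source estimators fail on a 3-node path.

Nodes 0-1-2 are joined by unit-rate edges; all three are observed
infected.  The first-k ML score and the sup-over-time JML score are
exactly 1 for *every* candidate source, so neither can tell the true
center apart from the endpoints.  Scoring the snapshot likelihood at the
(possibly random) observation time instead gives the center a strictly
larger score at every finite time.
"""

import sourceflow as sf

model = sf.path3()
S = {0, 1, 2}

print("candidate  first-k ML   JML (sup over t)")
for s in sorted(S):
    mlk = sf.ml_first_k(model, S, {s})
    jml_value, _ = sf.jml(model, S, {s})
    print(f"  {{{s}}}        {mlk:.6f}     {jml_value:.6f}")

for dist in (
    sf.ObservationTimeDistribution.point(1.0),
    sf.ObservationTimeDistribution.exponential(1.0),
    sf.ObservationTimeDistribution.uniform(0.2, 3.0),
):
    res = sf.ml_random_time(model, S, dist)
    scores = {min(W): round(v, 6) for W, v in res.scores.items()}
    label = dist.kind + (f"(t={dist.t})" if dist.kind == "point" else "")
    print(f"\nobservation time ~ {label}: scores {scores}")
    print(f"  argmax = {[sorted(W) for W in res.argmax]}, "
          f"degenerate = {res.degenerate}")

print(
    "\nBoth classical estimators score 1 for every candidate (degenerate);"
    "\nthe random-observation-time estimator uniquely recovers the center {1}."
)
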