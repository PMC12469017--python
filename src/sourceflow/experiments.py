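"""Experiment drivers: rate-vs-budget sweeps and oracle-call scaling.

These reproduce, qualitatively, the two standard diagnostics for greedy
source selection: (i) the achieved multicast rate as a function of the
source budget ``k``, which is nondecreasing and saturates at the min-cut
bound into the sink set; and (ii) the number of capacity-oracle calls as
a function of the graph size at fixed ``k``, which is exactly
``k·n − k(k−1)/2`` for plain greedy and no larger for lazy greedy.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

from .capacity import rho_uc
from .fixtures import ba_graph, er_graph, ws_graph
from .selection import greedy_forward, lazy_greedy
from .si import Node

__all__ = ["ExperimentReport", "run_rate_sweep", "run_scaling", "greedy_call_count"]


@dataclasses.dataclass
class ExperimentReport:
    experiment: str
    records: list[dict]

    def to_dict(self) -> dict:
        recs = []
        for r in self.records:
            rec = {}
            for k, v in r.items():
                if isinstance(v, (set, frozenset)):
                    rec[k] = sorted(map(str, v))
                elif isinstance(v, float) and math.isinf(v):
                    rec[k] = "inf"
                else:
                    rec[k] = v
            recs.append(rec)
        return {"experiment": self.experiment, "records": recs}


def greedy_call_count(n: int, k: int) -> int:
    """Exact oracle-call count of plain greedy: ``k·n − k(k−1)/2``."""
    return k * n - k * (k - 1) // 2


def run_rate_sweep(
    model,
    A: Iterable[Node],
    k_range: Sequence[int],
    kind: str = "ms",
    algorithm: str = "lazy",
    orientation: str = "directed",
    seed: int | None = None,
) -> ExperimentReport:
    """Achieved rate versus source budget ``k`` for one graph and sink set."""
    algo = {"greedy": greedy_forward, "lazy": lazy_greedy}[algorithm]
    records = []
    for k in k_range:
        res = algo(model, A, k, kind, orientation)
        records.append(
            {
                "k": k,
                "rate": res.rate,
                "selected": res.selected,
                "oracle_calls": res.oracle_calls,
                "algorithm": res.algorithm,
                "seed": seed,
            }
        )
    return ExperimentReport("rate_sweep", records)


def saturation_bound(model, A: Iterable[Node]) -> float:
    """Min-cut from all non-sink nodes into the sink set — the rate any
    selection strategy saturates at."""
    V = set(model.ground)
    A = model.ground.validate(A)
    return rho_uc(model, V - A, A).value


def run_scaling(
    sizes: Sequence[int],
    k: int = 10,
    kind: str = "uc",
    graph: str = "ba",
    seed: int = 0,
    n_sinks: int = 2,
    **graph_params,
) -> ExperimentReport:
    """Oracle-call counts of greedy vs lazy greedy across graph sizes.

    Sinks are the ``n_sinks`` highest-indexed nodes, which are reachable
    under the low→high edge orientation the generators use.
    """
    gen = {"ba": ba_graph, "ws": ws_graph, "er": er_graph}[graph]
    records = []
    for n in sizes:
        model = gen(n, seed=seed, **graph_params)
        A = set(model.ground.nodes[-n_sinks:])
        for algo_name, algo in (("greedy", greedy_forward), ("lazy", lazy_greedy)):
            res = algo(model, A, k, kind)
            records.append(
                {
                    "n": n,
                    "k": k,
                    "algorithm": algo_name,
                    "oracle_calls": res.oracle_calls,
                    "rate": res.rate,
                    "seed": seed,
                }
            )
    return ExperimentReport("scaling", records)
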