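"""File I/O: TSV edge lists, JSON hazard tables, trajectories, reports.

Edge lists are tab-separated with a mandatory ``u<TAB>v<TAB>w`` header;
capacities/rates must be nonnegative, duplicate arcs are summed with a
logged notice, and malformed lines are reported with their line number.
Node labels that parse as integers are read as integers, otherwise kept
as strings.  The infinite capacity sentinel serializes to the JSON string
``"inf"``.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable

from .linking import DirectedGraphLinking, UndirectedGraphLinking
from .si import GraphRateModel, GroundSet, InfectionTrajectory, TableRateModel

logger = logging.getLogger(__name__)

__all__ = [
    "read_edges",
    "read_graph",
    "read_rate_model",
    "read_table_rate_model",
    "write_graph",
    "write_report",
    "write_trajectory",
]


def _parse_label(tok: str):
    try:
        return int(tok)
    except ValueError:
        return tok


def read_edges(path: str | Path) -> list[tuple]:
    """Parse a TSV edge list ``u v w`` (header required)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or [t.strip() for t in lines[0].split("\t")] != ["u", "v", "w"]:
        raise ValueError(f"{path}: missing required header 'u\\tv\\tw'")
    edges: list[tuple] = []
    seen: set[tuple] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
        u, v = _parse_label(parts[0].strip()), _parse_label(parts[1].strip())
        try:
            w = float(parts[2])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: capacity {parts[2]!r} is not a number")
        if w < 0:
            raise ValueError(f"{path}:{lineno}: negative capacity {w}")
        if (u, v) in seen:
            logger.info("%s:%d: duplicate arc %r->%r summed", path, lineno, u, v)
        seen.add((u, v))
        edges.append((u, v, w))
    return edges


def read_graph(path: str | Path, directed: bool = True):
    """Read a capacity graph: directed or undirected linking model."""
    edges = read_edges(path)
    if directed:
        return DirectedGraphLinking.from_edges(edges)
    return UndirectedGraphLinking.from_edges(edges)


def read_rate_model(path: str | Path, directed: bool = False) -> GraphRateModel:
    """Read an SI infection-rate graph (per-edge exponential clock rates)."""
    return GraphRateModel.from_edges(read_edges(path), directed=directed)


def read_table_rate_model(path: str | Path) -> TableRateModel:
    """Read an explicit hazard table:
    ``{"nodes": [...], "hazard": [{"u":..., "B": [...], "rate":...}, ...]}``."""
    data = json.loads(Path(path).read_text())
    ground = GroundSet(data["nodes"])
    table = {
        (entry["u"], tuple(entry["B"])): entry["rate"] for entry in data["hazard"]
    }
    return TableRateModel(ground, table)


def write_graph(model, path: str | Path) -> None:
    """Write a linking model back to canonical TSV (ground-order sorted)."""
    path = Path(path)
    lines = ["u\tv\tw"]
    if isinstance(model, UndirectedGraphLinking):
        items = sorted(model.edges.items(), key=lambda kv: model.ground.sort(kv[0]))
        for e, cap in items:
            u, v = model.ground.sort(e)
            lines.append(f"{u}\t{v}\t{cap!r}")
    else:
        key = lambda kv: (model.ground.index(kv[0][0]), model.ground.index(kv[0][1]))
        for (u, v), cap in sorted(model.arcs.items(), key=key):
            lines.append(f"{u}\t{v}\t{cap!r}")
    path.write_text("\n".join(lines) + "\n")


def _sanitize(obj):
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(map(str, obj))
    return obj


def write_report(obj, path: str | Path) -> None:
    """JSON-dump any report object (``to_dict`` honored, inf -> "inf")."""
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    Path(path).write_text(json.dumps(_sanitize(obj), indent=2) + "\n")


def write_trajectory(traj: InfectionTrajectory, path: str | Path) -> None:
    write_report(traj.to_dict(), path)
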