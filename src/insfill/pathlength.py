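"""Exact path-length search on a de Bruijn graph.

The path-length problem: given a directed graph, a source ``s``, a target
``t``, a per-edge cost, and a cost interval ``[cost_lo..cost_hi]``, find a
path from ``s`` to ``t`` whose total cost falls in the interval.  On a de
Bruijn graph every edge costs 1, so a path's cost is the number of bases it
appends to its first k-mer.

The solver fills a table ``M[v][i]`` = number of walks from ``s`` reaching
``v`` at total cost exactly ``i``, layer by layer up to ``cost_hi``, then
traces any witness path back from ``t``.  Counts saturate at 2**31 - 1:
the traceback only needs positivity, and exact counts can grow
exponentially with cost.

Walk semantics: vertices may repeat along a path, which is what the
recurrence counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from insfill.debruijn import KmerGraph

__all__ = [
    "SATURATION",
    "PathLengthInstance",
    "PathCountTable",
    "count_paths",
    "traceback",
    "spell",
]

SATURATION = 2**31 - 1


@dataclass(frozen=True)
class PathLengthInstance:
    """One path-length query.

    ``edge_cost`` maps ``(u, v)`` pairs to positive integer costs; when
    ``None`` every edge costs 1 (the de Bruijn case).  Zero-cost edges are
    rejected: the layered search assumes every step strictly increases the
    accumulated cost.
    """

    graph: KmerGraph
    source: str
    target: str
    cost_lo: int
    cost_hi: int
    edge_cost: Optional[Mapping[Tuple[str, str], int]] = None

    def __post_init__(self) -> None:
        if not (0 <= self.cost_lo <= self.cost_hi):
            raise ValueError(
                f"need 0 <= cost_lo <= cost_hi, got [{self.cost_lo}..{self.cost_hi}]"
            )
        if self.source not in self.graph or self.target not in self.graph:
            raise KeyError("source and target must be vertices of the graph")
        if self.edge_cost is not None and any(
            c < 1 for c in self.edge_cost.values()
        ):
            raise ValueError("edge costs must be positive integers")

    def cost(self, u: str, v: str) -> int:
        if self.edge_cost is None:
            return 1
        return self.edge_cost[(u, v)]


@dataclass
class PathCountTable:
    """Saturating walk counts ``M[v][i]``, stored sparsely per cost layer.

    ``layers[i]`` maps a vertex to the number of walks from the source that
    reach it at cost exactly ``i``; vertices absent from a layer have count
    zero.
    """

    cost_hi: int
    layers: List[Dict[str, int]] = field(default_factory=list)

    def count(self, v: str, i: int) -> int:
        if 0 <= i < len(self.layers):
            return self.layers[i].get(v, 0)
        return 0

    def write_tsv(self, path) -> None:
        """Debug dump of nonzero entries as ``cost vertex count`` lines."""
        with open(path, "w") as fh:
            for i, layer in enumerate(self.layers):
                for v in sorted(layer):
                    fh.write(f"{i}\t{v}\t{layer[v]}\n")


def count_paths(instance: PathLengthInstance) -> PathCountTable:
    """Fill ``M[v][i]`` for all vertices and costs ``i in [0..cost_hi]``.

    ``M[v][i]`` is the exact number of source-to-``v`` walks of total cost
    ``i``, saturated at :data:`SATURATION`.  An unreachable target simply
    yields all-zero rows; no error is raised.
    """
    g = instance.graph
    hi = instance.cost_hi
    layers: List[Dict[str, int]] = [dict() for _ in range(hi + 1)]
    layers[0][instance.source] = 1
    unit = instance.edge_cost is None
    for i in range(hi):
        layer = layers[i]
        if not layer:
            continue
        for v, cnt in layer.items():
            for w in g.successors(v):
                j = i + 1 if unit else i + instance.cost(v, w)
                if j > hi:
                    continue
                tgt = layers[j]
                tgt[w] = min(tgt.get(w, 0) + cnt, SATURATION)
    return PathCountTable(cost_hi=hi, layers=layers)


def _pick_cost(table: PathCountTable, instance: PathLengthInstance) -> Optional[int]:
    lo, hi = instance.cost_lo, instance.cost_hi
    valid = [i for i in range(lo, hi + 1) if table.count(instance.target, i) > 0]
    if not valid:
        return None
    mid = (lo + hi) / 2
    # Prefer the cost closest to the interval midpoint (the estimated gap
    # length maps there); break ties toward the smaller cost.
    return min(valid, key=lambda i: (abs(i - mid), i))


def traceback(
    table: PathCountTable, instance: PathLengthInstance
) -> Optional[List[str]]:
    """Trace a witness path of cost in ``[cost_lo..cost_hi]``, or ``None``.

    Deterministic tie-breaks: the realized cost is the valid cost closest
    to the interval midpoint (ties toward smaller), and at each backward
    step the lexicographically smallest eligible predecessor is taken.
    """
    cost = _pick_cost(table, instance)
    if cost is None:
        return None
    g = instance.graph
    path = [instance.target]
    v, i = instance.target, cost
    while i > 0:
        step = None
        for u in g.predecessors(v):  # sorted, so first hit is lexicographic min
            c = instance.cost(u, v)
            if i - c >= 0 and table.count(u, i - c) > 0:
                step = u
                i -= c
                break
        if step is None:  # pragma: no cover - table invariant violated
            raise RuntimeError("traceback dead end; inconsistent count table")
        path.append(step)
        v = step
    if v != instance.source:  # pragma: no cover
        raise RuntimeError("traceback did not reach the source")
    path.reverse()
    return path


def spell(path: Sequence[str], k: int) -> str:
    """Spell the DNA string of a vertex path.

    Consecutive vertices overlap by k-1, so an n-vertex path spells
    ``k + (n - 1)`` characters: the first vertex followed by the last
    character of every subsequent vertex.
    """
    if not path:
        raise ValueError("empty path")
    out = [path[0]]
    prev = path[0]
    for v in path[1:]:
        if len(v) != k or prev[1:] != v[:-1]:
            raise ValueError(f"malformed path: {prev} -> {v} lacks k-1 overlap")
        out.append(v[-1])
        prev = v
    if len(path[0]) != k:
        raise ValueError("first vertex is not a k-mer")
    return "".join(out)
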