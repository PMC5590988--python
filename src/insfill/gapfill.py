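"""Gap filling between two flanking sequences on a de Bruijn graph.

A gap of estimated length ``d`` between a left and a right flank is filled
by searching for a path from a k-mer of the left flank to a k-mer of the
right flank whose length is close to ``d``.  Because the flanks themselves
may contain errors, the source and target k-mers are not fixed at the gap
boundaries: offsets up to ``fuzz`` bases into each flank are tried, and the
bases skipped by an offset are re-spelled from the graph path rather than
taken from the (possibly erroneous) flank.

Cost arithmetic.  A path of cost ``c`` from a source k-mer to a target
k-mer spells ``c + k`` characters.  With the source shifted ``a`` bases
into the left flank and the target shifted ``b`` bases into the right
flank, that spelled string consists of the source k-mer, ``a`` re-spelled
left-flank bases, the ``m`` bases strictly between the original flank
boundaries, ``b`` re-spelled right-flank bases, and the target k-mer;
hence ``m = c - k - a - b``.  The search therefore accepts costs ``c`` with
``c - k - a - b`` inside the accepted length interval around ``d``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from insfill.debruijn import KmerGraph
from insfill.pathlength import PathCountTable, PathLengthInstance, count_paths, spell, traceback

__all__ = [
    "GapSpec",
    "FillResult",
    "default_slack",
    "make_interval",
    "fill_gap",
    "count_fill_paths",
]

DEFAULT_FUZZ = 10


def default_slack(est_length: int) -> int:
    """Default half-width of the accepted length interval.

    ``max(10, ceil(0.1 * d))`` tolerates length-estimate noise from
    insert-size inference while keeping the dynamic program small.
    """
    return max(10, math.ceil(0.1 * est_length))


def make_interval(est_length: int, slack: int) -> Tuple[int, int]:
    """Accepted insertion-length interval ``[d - slack, d + slack]``.

    The lower bound is clamped at 0; whenever no clamping occurs the
    midpoint of the interval is the estimated gap length itself.
    """
    if est_length < 0 or slack < 0:
        raise ValueError("est_length and slack must be non-negative")
    return max(0, est_length - slack), est_length + slack


@dataclass(frozen=True)
class GapSpec:
    """A gap to fill: flanking sequences plus a length estimate.

    ``slack`` is the half-width of the accepted length interval (``None``
    selects :func:`default_slack`); ``fuzz`` is the maximum offset searched
    inward into each flank.
    """

    left_flank: str
    right_flank: str
    est_length: int
    slack: Optional[int] = None
    fuzz: int = DEFAULT_FUZZ

    def resolved_slack(self) -> int:
        return default_slack(self.est_length) if self.slack is None else self.slack


@dataclass(frozen=True)
class FillResult:
    """A successful fill.

    ``insertion`` contains only the bases strictly between the original
    flank boundaries; ``left_offset``/``right_offset`` record how far into
    each flank the witness path was anchored, and ``cost`` is the graph
    cost of the witness path.
    """

    insertion: str
    left_offset: int
    right_offset: int
    cost: int
    n_paths: int


def _source_kmer(left: str, k: int, a: int) -> Optional[str]:
    # rightmost k-mer of the left flank, shifted a bases leftward
    if len(left) < k + a:
        return None
    end = len(left) - a
    return left[end - k : end]


def _target_kmer(right: str, k: int, b: int) -> Optional[str]:
    if len(right) < k + b:
        return None
    return right[b : b + k]


def fill_gap(
    graph: KmerGraph,
    spec: GapSpec,
    max_cost: Optional[int] = None,
) -> Optional[FillResult]:
    """Fill one gap; returns ``None`` when no acceptable path exists.

    Flank offsets ``(a, b)`` are tried in ascending ``a + b`` order (then
    ascending ``a``) and the first success is returned, which makes the
    result deterministic.  ``max_cost`` optionally caps the number of cost
    layers the dynamic program may fill.
    """
    k = graph.k
    if len(spec.left_flank) < k or len(spec.right_flank) < k:
        raise ValueError(f"flanks must be at least k={k} long")
    slack = spec.resolved_slack()
    len_lo, len_hi = make_interval(spec.est_length, slack)
    fuzz = spec.fuzz
    # One forward DP per left offset a covers every right offset b.
    tables: Dict[int, Tuple[PathCountTable, str]] = {}
    for total in range(0, 2 * fuzz + 1):
        for a in range(max(0, total - fuzz), min(fuzz, total) + 1):
            b = total - a
            s = _source_kmer(spec.left_flank, k, a)
            t = _target_kmer(spec.right_flank, k, b)
            if s is None or t is None or s not in graph or t not in graph:
                continue
            cost_lo = k + a + b + len_lo
            cost_hi = k + a + b + len_hi
            if max_cost is not None:
                cost_hi = min(cost_hi, max_cost)
            if cost_hi < cost_lo:
                continue
            if a not in tables:
                table_hi = k + a + fuzz + len_hi
                if max_cost is not None:
                    table_hi = min(table_hi, max_cost)
                inst_a = PathLengthInstance(graph, s, s, 0, table_hi)
                tables[a] = (count_paths(inst_a), s)
            table, _ = tables[a]
            inst = PathLengthInstance(graph, s, t, cost_lo, cost_hi)
            path = traceback(table, inst)
            if path is None:
                continue
            spelled = spell(path, k)
            cost = len(spelled) - k
            insertion = spelled[k + a : len(spelled) - k - b]
            n_paths = sum(table.count(t, i) for i in range(cost_lo, cost_hi + 1))
            return FillResult(
                insertion=insertion,
                left_offset=a,
                right_offset=b,
                cost=cost,
                n_paths=n_paths,
            )
    return None


def count_fill_paths(graph: KmerGraph, spec: GapSpec) -> int:
    """Number of acceptable paths at zero flank offsets (saturating).

    A return value of exactly 1 certifies that the boundary-anchored fill
    is unique in the graph over the whole accepted length interval.
    """
    k = graph.k
    slack = spec.resolved_slack()
    len_lo, len_hi = make_interval(spec.est_length, slack)
    s = _source_kmer(spec.left_flank, k, 0)
    t = _target_kmer(spec.right_flank, k, 0)
    if s is None or t is None or s not in graph or t not in graph:
        return 0
    inst = PathLengthInstance(graph, s, t, k + len_lo, k + len_hi)
    table = count_paths(inst)
    return sum(table.count(t, i) for i in range(inst.cost_lo, inst.cost_hi + 1))
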