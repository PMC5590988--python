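"""De Bruijn graph construction from short reads.

The k-th order de Bruijn graph of a read set is a directed graph whose
vertices are the k-mers observed in the reads and whose edges are the
observed (k+1)-mers: an edge runs from the k-mer prefix of a (k+1)-mer to
its k-mer suffix, so consecutive vertices always overlap by k-1 bases.

By default the read set is augmented with the reverse complement of every
read before k-mer extraction, so both strands of the sampled molecule are
represented.  The graph remains a plain directed graph (no canonical-k-mer
collapsing), which keeps the path-length dynamic program unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

__all__ = [
    "KmerGraph",
    "EmptyGraphError",
    "KTooLargeError",
    "reverse_complement",
    "kmer_counts",
    "graph_from_counts",
    "build_graph",
]

_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")
_AMBIGUOUS = re.compile(r"[^ACGT]+")


class EmptyGraphError(ValueError):
    """No k-mer survived abundance thresholding."""


class KTooLargeError(ValueError):
    """k exceeds the length of every read fragment."""


def reverse_complement(seq: str) -> str:
    """Return the reverse complement of a DNA string."""
    return seq.translate(_RC_TABLE)[::-1]


def _fragments(read: str) -> Iterable[str]:
    # Ambiguous bases split a read into unambiguous fragments; each
    # fragment contributes its own k-mers and no k-mer spans an N.
    return _AMBIGUOUS.split(read.upper())


def kmer_counts(
    reads: Iterable[str],
    k: int,
    include_rc: bool = True,
) -> Tuple[Dict[str, int], Dict[str, int]]:
    """Count k-mers and (k+1)-mers in a read set.

    Returns ``(vertex_counts, edge_counts)`` where edge keys are the raw
    (k+1)-mer strings.  With ``include_rc`` (the default) the reverse
    complement of every read is counted as well.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    vcounts: Dict[str, int] = {}
    ecounts: Dict[str, int] = {}
    max_len = 0
    for read in reads:
        for frag in _fragments(read):
            n = len(frag)
            if n > max_len:
                max_len = n
            if n < k:
                continue
            seqs = (frag, reverse_complement(frag)) if include_rc else (frag,)
            for seq in seqs:
                for i in range(n - k + 1):
                    km = seq[i : i + k]
                    vcounts[km] = vcounts.get(km, 0) + 1
                for i in range(n - k):
                    e = seq[i : i + k + 1]
                    ecounts[e] = ecounts.get(e, 0) + 1
    if not vcounts and max_len and max_len < k:
        raise KTooLargeError(f"k={k} exceeds every read length (max {max_len})")
    return vcounts, ecounts


@dataclass
class KmerGraph:
    """A k-th order de Bruijn graph.

    ``abundance`` maps each vertex (k-mer) to its observation count;
    ``edge_abundance`` maps (k+1)-mer strings to counts.  Adjacency is
    stored as sorted successor tuples so traversal order is deterministic.
    """

    k: int
    abundance: Dict[str, int]
    edge_abundance: Dict[str, int]
    _adj: Dict[str, Tuple[str, ...]] = field(repr=False, default_factory=dict)
    _pred: Dict[str, Tuple[str, ...]] | None = field(repr=False, default=None)

    @property
    def vertices(self):
        return self.abundance.keys()

    @property
    def edges(self):
        for e in self.edge_abundance:
            yield (e[:-1], e[1:])

    @property
    def n_vertices(self) -> int:
        return len(self.abundance)

    @property
    def n_edges(self) -> int:
        return len(self.edge_abundance)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.abundance

    def successors(self, v: str) -> Tuple[str, ...]:
        return self._adj.get(v, ())

    def predecessors(self, v: str) -> Tuple[str, ...]:
        if self._pred is None:
            pred: Dict[str, list] = {}
            for u, w in self.edges:
                pred.setdefault(w, []).append(u)
            self._pred = {w: tuple(sorted(us)) for w, us in pred.items()}
        return self._pred.get(v, ())

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, ())

    def write_edge_list(self, path) -> None:
        """Debug dump: one tab-separated ``u v count`` line per edge."""
        with open(path, "w") as fh:
            for e, c in sorted(self.edge_abundance.items()):
                fh.write(f"{e[:-1]}\t{e[1:]}\t{c}\n")


def graph_from_counts(
    vertex_counts: Mapping[str, int],
    edge_counts: Mapping[str, int],
    k: int,
    min_abundance: int = 1,
) -> KmerGraph:
    """Assemble a :class:`KmerGraph` from precomputed k-mer/(k+1)-mer counts.

    Vertices and edges below ``min_abundance`` are dropped; an edge is also
    dropped when either endpoint was dropped, so every edge endpoint is a
    graph vertex.
    """
    if min_abundance < 1:
        raise ValueError("min_abundance must be >= 1")
    vkeep = {v: c for v, c in vertex_counts.items() if c >= min_abundance}
    if not vkeep:
        raise EmptyGraphError(
            f"no k-mer with abundance >= {min_abundance}; graph is empty"
        )
    ekeep: Dict[str, int] = {}
    adj: Dict[str, list] = {}
    for e, c in edge_counts.items():
        if c < min_abundance:
            continue
        u, w = e[:-1], e[1:]
        if u in vkeep and w in vkeep:
            ekeep[e] = c
            adj.setdefault(u, []).append(w)
    adj_sorted = {u: tuple(sorted(ws)) for u, ws in adj.items()}
    return KmerGraph(k=k, abundance=vkeep, edge_abundance=ekeep, _adj=adj_sorted)


def build_graph(
    reads: Iterable[str],
    k: int,
    min_abundance: int = 1,
    include_rc: bool = True,
) -> KmerGraph:
    """Build the k-th order de Bruijn graph of a read set.

    Parameters
    ----------
    reads
        DNA strings; ambiguous bases split a read into fragments.
    k
        Graph order (vertex k-mer length), >= 2.
    min_abundance
        Minimum observation count for a k-mer/(k+1)-mer to be kept.  Use 1
        for error-free data; 2 or more suppresses singleton k-mers produced
        by sequencing errors.
    include_rc
        Augment the read set with reverse complements (default).
    """
    reads = list(reads)
    if not reads:
        raise ValueError("read set is empty")
    vcounts, ecounts = kmer_counts(reads, k, include_rc=include_rc)
    if not vcounts:
        raise EmptyGraphError("no k-mer extracted from reads")
    return graph_from_counts(vcounts, ecounts, k, min_abundance=min_abundance)
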