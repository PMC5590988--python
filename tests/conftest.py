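"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from collections import Counter
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pytest

from insfill.debruijn import KmerGraph, graph_from_counts
from insfill.simulate import SimulationConfig, SimulatedDataset, simulate_dataset

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


def debruijn_from_edges(edges: Iterable[str]) -> KmerGraph:
    """Build a k=3 graph directly from a set of 4-mer edge labels."""
    edges = list(edges)
    vcounts: Counter = Counter()
    for e in edges:
        vcounts[e[:-1]] += 1
        vcounts[e[1:]] += 1
    return graph_from_counts(dict(vcounts), dict(Counter(edges)), k=3)


def random_debruijn_instance(
    rng: np.random.Generator, edge_prob: float = 0.5
) -> Tuple[KmerGraph, str, str]:
    """Random small de Bruijn graph over {A, C} (up to 8 vertices, cycles
    allowed) plus random source/target vertices."""
    candidates = ["".join(p) for p in itertools.product("AC", repeat=4)]
    while True:
        chosen = [e for e in candidates if rng.random() < edge_prob]
        if chosen:
            break
    g = debruijn_from_edges(chosen)
    verts = sorted(g.vertices)
    s = verts[rng.integers(0, len(verts))]
    t = verts[rng.integers(0, len(verts))]
    return g, s, t


def enumerate_walk_counts(
    graph: KmerGraph, source: str, max_cost: int
) -> List[Dict[str, int]]:
    """Exhaustive walk enumeration oracle: ``layers[i][v]`` is the number of
    source-to-v walks with exactly ``i`` edges, counted by extending every
    walk one edge at a time (no recurrence, no saturation)."""
    layers: List[Dict[str, int]] = [dict(Counter([source]))]
    walks = [source]  # one entry per distinct walk, keyed by its endpoint
    for _ in range(max_cost):
        walks = [w for v in walks for w in graph.successors(v)]
        if len(walks) > 500_000:  # pragma: no cover - guard for dense draws
            raise RuntimeError("oracle blow-up; lower edge density")
        layers.append(dict(Counter(walks)))
    return layers


def tile_reads(s: str, read_len: int) -> List[str]:
    """Every substring of length ``read_len`` of ``s`` (full tiling)."""
    if len(s) <= read_len:
        return [s]
    return [s[i : i + read_len] for i in range(len(s) - read_len + 1)]


@pytest.fixture(scope="session")
def small_dataset() -> SimulatedDataset:
    """10 planted insertions in a 120 kb reference, error-free 30x pairs
    with the Normal(1500, 150) library."""
    return simulate_dataset(
        SimulationConfig(reference_length=120_000, n_insertions=10, seed=7)
    )
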