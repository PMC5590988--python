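import numpy as np
import pytest

from conftest import (
    debruijn_from_edges,
    enumerate_walk_counts,
    random_debruijn_instance,
)
from insfill.debruijn import build_graph
from insfill.pathlength import (
    SATURATION,
    PathLengthInstance,
    count_paths,
    spell,
    traceback,
)

LINE = build_graph(["ACGTAC"], k=3, include_rc=False)  # ACG->CGT->GTA->TAC


def test_line_graph_counts():
    inst = PathLengthInstance(LINE, "ACG", "TAC", 0, 3)
    table = count_paths(inst)
    assert table.count("TAC", 3) == 1
    assert all(table.count("TAC", i) == 0 for i in range(3))


def test_source_equals_target_empty_path():
    inst = PathLengthInstance(LINE, "ACG", "ACG", 0, 2)
    table = count_paths(inst)
    assert table.count("ACG", 0) == 1


# A "diamond": two distinct cost-4 routes AAA..CAA (note: in a de Bruijn
# graph a path of cost <= k is fully determined by its endpoints, so path
# multiplicity needs cost > k).
DIAMOND_EDGES = ["AAAA", "AAAC", "AACA", "ACAA", "AACC", "ACCA", "CCAA"]


def test_diamond_counts_both_branches():
    g = debruijn_from_edges(DIAMOND_EDGES)
    inst = PathLengthInstance(g, "AAA", "CAA", 0, 4)
    table = count_paths(inst)
    assert table.count("CAA", 4) == 2  # AAA,AAA,AAC,ACA,CAA and AAA,AAC,ACC,CCA,CAA
    oracle = enumerate_walk_counts(g, "AAA", 4)
    for i in range(5):
        assert table.count("CAA", i) == oracle[i].get("CAA", 0)


def test_traceback_line_graph():
    inst = PathLengthInstance(LINE, "ACG", "TAC", 3, 3)
    path = traceback(count_paths(inst), inst)
    assert path == ["ACG", "CGT", "GTA", "TAC"]


def test_traceback_failure_zero_cost_distinct_vertices():
    inst = PathLengthInstance(LINE, "ACG", "TAC", 0, 0)
    assert traceback(count_paths(inst), inst) is None


def test_traceback_deterministic_tie_break():
    g = debruijn_from_edges(DIAMOND_EDGES)
    inst = PathLengthInstance(g, "AAA", "CAA", 4, 4)
    table = count_paths(inst)
    assert table.count("CAA", 4) == 2
    path = traceback(table, inst)
    # lexicographically smallest predecessor at each backward step
    assert path == ["AAA", "AAA", "AAC", "ACA", "CAA"]
    assert traceback(table, inst) == path  # stable


def test_unreachable_target_all_zero():
    g = build_graph(["ACGT", "TTTT"], k=3, include_rc=False)
    inst = PathLengthInstance(g, "ACG", "TTT", 0, 5)
    table = count_paths(inst)
    assert all(table.count("TTT", i) == 0 for i in range(6))
    assert traceback(table, inst) is None


def test_invalid_interval_rejected():
    with pytest.raises(ValueError):
        PathLengthInstance(LINE, "ACG", "TAC", 3, 2)
    with pytest.raises(KeyError):
        PathLengthInstance(LINE, "ACG", "GGG", 0, 2)


def test_spell_examples():
    assert spell(["ACG", "CGT", "GTA"], 3) == "ACGTA"
    assert spell(["ACG"], 3) == "ACG"
    assert spell(["AAA", "AAA"], 3) == "AAAA"  # self-loop


def test_spell_rejects_broken_overlap():
    with pytest.raises(ValueError):
        spell(["ACG", "GTA"], 3)


def test_saturation_cap_on_self_loop():
    g = debruijn_from_edges(["AAAA"])  # self-loop: one walk per cost
    inst = PathLengthInstance(g, "AAA", "AAA", 0, 5)
    table = count_paths(inst)
    assert all(table.count("AAA", i) == 1 for i in range(6))
    assert table.count("AAA", 3) <= SATURATION


def test_counts_match_exhaustive_enumeration():
    """DP counts equal brute-force walk enumeration on random graphs."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        g, s, t = random_debruijn_instance(rng)
        hi = int(rng.integers(1, 11))
        table = count_paths(PathLengthInstance(g, s, t, 0, hi))
        oracle = enumerate_walk_counts(g, s, hi)
        for i in range(hi + 1):
            for v in g.vertices:
                assert table.count(v, i) == oracle[i].get(v, 0)


def test_traceback_path_is_valid_and_monotone():
    """Traced paths are edge-valid with cost in range; widening the interval
    never turns a success into a failure."""
    rng = np.random.default_rng(7)
    successes = 0
    for _ in range(100):
        g, s, t = random_debruijn_instance(rng)
        hi = int(rng.integers(1, 11))
        lo = int(rng.integers(0, hi + 1))
        inst = PathLengthInstance(g, s, t, lo, hi)
        table = count_paths(inst)
        path = traceback(table, inst)
        wide = PathLengthInstance(g, s, t, 0, hi + 3)
        wide_path = traceback(count_paths(wide), wide)
        if path is None:
            continue
        successes += 1
        assert wide_path is not None
        assert path[0] == s and path[-1] == t
        assert lo <= len(path) - 1 <= hi
        for u, v in zip(path, path[1:]):
            assert g.has_edge(u, v)
        assert len(spell(path, g.k)) == g.k + (len(path) - 1)
    assert successes > 5  # the sweep actually exercised successful cases
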