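import numpy as np
import pytest
from statistics import NormalDist

from insfill.readfilter import (
    AlignmentIndex,
    InsertSizeModel,
    ReadAlignmentRecord,
    apply_unmapped_fallback,
    filter_reads,
    filter_reads_for_insertion,
    insert_size_bounds,
    mate_regions,
    precision_recall,
)

MODEL_1500 = InsertSizeModel(read_length=100, mean_insert=1500, sd_insert=150)


def test_critical_value_is_1_96_at_95_percent():
    assert round(MODEL_1500.z, 2) == 1.96


@pytest.mark.parametrize(
    "mu,sigma,expected",
    [
        (1500, 150, (1206, 1794)),
        (150, 15, (120, 180)),  # 120.6 / 179.4 rounded outward
        (200, 0, (200, 200)),  # degenerate distribution
    ],
)
def test_insert_size_bounds(mu, sigma, expected):
    assert insert_size_bounds(InsertSizeModel(100, mu, sigma)) == expected


def test_insert_size_bounds_clamped_at_zero():
    lo, hi = insert_size_bounds(InsertSizeModel(100, 50, 100))
    assert lo == 0 and hi > 0


def test_mate_regions_printed_formulas():
    s_left, s_right = mate_regions((5000, 5100), MODEL_1500)
    assert s_left == (3006, 3794)
    assert s_right == (6306, 6994)


def test_mate_regions_degenerate_model_hugs_the_gap():
    # min = max = 0 and the smallest legal read length: the regions collapse
    # to within one read length of the gap boundaries
    s_left, s_right = mate_regions((500, 600), InsertSizeModel(1, 0, 0))
    assert s_left == (500 - 2, 600 - 1)
    assert s_right == (500 + 1, 600 + 1)


def test_mate_regions_negative_coordinates_clamped_empty():
    m = InsertSizeModel(100, 150, 15)  # min=120, max=180
    s_left, s_right = mate_regions((100, 200), m)
    assert s_left == (0, 0)  # raw [-280..-20] clamps to an empty-ish region
    assert s_right == (320, 480)


def test_mate_regions_independent_rederivation():
    """Cross-check against a from-scratch evaluation of the region formulas
    using the stdlib normal quantile (independent of the implementation)."""
    rng = np.random.default_rng(2024)
    for _ in range(12):
        l = int(rng.integers(36, 250))
        mu = float(rng.integers(200, 4000))
        sigma = float(rng.integers(0, mu // 5 + 1))
        s = int(rng.integers(5000, 100000))
        e = s + int(rng.integers(0, 2000))
        z = NormalDist().inv_cdf(0.975)
        mn = max(0, int(np.floor(mu - z * sigma)))
        mx = int(np.ceil(mu + z * sigma))
        expect_left = (max(0, s - (mx + 2 * l)), max(0, e - (mn + l)))
        expect_right = (s + (mn + l), e + (mx + l))
        got = mate_regions((s, e), InsertSizeModel(l, mu, sigma))
        assert got == (expect_left, expect_right)


def test_mate_regions_monotone_in_confidence():
    wide = InsertSizeModel(100, 1500, 150, confidence=0.99)
    narrow = InsertSizeModel(100, 1500, 150, confidence=0.90)
    (nl, nr) = mate_regions((5000, 5100), narrow)
    (wl, wr) = mate_regions((5000, 5100), wide)
    assert wl[0] <= nl[0] and wl[1] >= nl[1]
    assert wr[0] <= nr[0] and wr[1] >= nr[1]


def _records():
    return [
        # mapped read overlapping the gap [5000..5100)
        ReadAlignmentRecord("a/1", True, 4950, 5050, True, 3500),
        # mapped read far away
        ReadAlignmentRecord("b/1", True, 100, 200, True, 1700),
        # unmapped, mate inside S_left=[3006..3794]
        ReadAlignmentRecord("c/2", False, mate_mapped=True, mate_start=3100),
        # unmapped, mate outside both regions
        ReadAlignmentRecord("d/2", False, mate_mapped=True, mate_start=100),
        # unmapped, mate inside S_right=[6306..6994]
        ReadAlignmentRecord("e/2", False, mate_mapped=True, mate_start=6500),
        # unmapped, mate unmapped too: only reachable via fallback
        ReadAlignmentRecord("f/1", False, mate_mapped=False),
        # unmapped, mate flagged mapped but without coordinates: skipped
        ReadAlignmentRecord("g/2", False, mate_mapped=True, mate_start=None),
    ]


def test_filter_reads_selection_rules():
    fr = filter_reads(_records(), (5000, 5100), MODEL_1500)
    assert fr.selected_ids == {"a/1", "c/2", "e/2"}
    assert fr.n_skipped == 1
    assert fr.region_length == 100 + 2 * 100
    assert fr.realized_coverage == pytest.approx(3 * 100 / 300)


def test_fallback_fires_below_threshold():
    fr = filter_reads(_records(), (5000, 5100), MODEL_1500)
    out = apply_unmapped_fallback(fr, {"c/2", "d/2", "e/2", "f/1", "g/2"}, 25)
    assert out.fallback_fired
    assert out.pre_fallback_coverage == fr.realized_coverage
    assert out.pre_fallback_coverage < 25
    assert "f/1" in out.selected_ids and "d/2" in out.selected_ids


def test_fallback_unchanged_above_threshold():
    fr = filter_reads(_records(), (5000, 5100), MODEL_1500)
    out = apply_unmapped_fallback(fr, {"f/1"}, 0.5)
    assert out is fr or out == fr
    assert not out.fallback_fired


def test_fallback_zero_threshold_never_fires():
    fr = filter_reads(_records(), (5000, 5100), MODEL_1500)
    assert not apply_unmapped_fallback(fr, {"f/1"}, 0).fallback_fired


def test_insertion_filter_matches_gapped_coordinates():
    """The breakpoint variant must agree with running the plain filter on
    explicitly projected (gapped) coordinates."""
    rng = np.random.default_rng(5)
    p, d, l = 20_000, 700, 100
    model = InsertSizeModel(l, 1500, 150)
    records, projected = [], []
    for i in range(400):
        start = int(rng.integers(0, 40_000))
        mapped = rng.random() < 0.8
        mate_start = int(rng.integers(0, 40_000))
        mate_mapped = rng.random() < 0.9
        rid = f"r{i}"
        if mapped:
            rec = ReadAlignmentRecord(rid, True, start, start + l, mate_mapped,
                                      mate_start if mate_mapped else None)
            # projection: positions at/after the breakpoint shift by d
            ps = start + d if start >= p else start
            # a read crossing p straddles the gap; keep its ungapped span
            pe = ps + l
            prec = ReadAlignmentRecord(rid, True, ps, pe, mate_mapped,
                                       (mate_start + d if mate_start >= p else mate_start)
                                       if mate_mapped else None)
        else:
            rec = ReadAlignmentRecord(rid, False, mate_mapped=mate_mapped,
                                      mate_start=mate_start if mate_mapped else None)
            prec = ReadAlignmentRecord(rid, False, mate_mapped=mate_mapped,
                                       mate_start=(mate_start + d if mate_start >= p else mate_start)
                                       if mate_mapped else None)
        records.append(rec)
        projected.append(prec)
    got = filter_reads_for_insertion(records, p, d, model)
    ref = filter_reads(projected, (p, p + d), model)
    # mapped reads crossing the breakpoint are the one intentional difference:
    # in gapped coordinates they overlap the gap only if they cross p
    assert got.selected_ids == ref.selected_ids
    assert got.region_length == ref.region_length


def test_precision_recall_examples():
    assert precision_recall({"a", "b"}, {"a", "b"}) == (1.0, 1.0)
    sel = {f"s{i}" for i in range(10)}
    truth = {f"s{i}" for i in range(8)}
    p, r = precision_recall(sel, truth)
    assert (p, r) == (0.8, 1.0)


def test_precision_recall_undefined_markers():
    p, r = precision_recall(set(), {"x"})
    assert p is None and r == 0.0
    p, r = precision_recall({"x"}, set())
    assert p == 0.0 and r is None


def test_precision_recall_universe_check():
    with pytest.raises(ValueError):
        precision_recall({"a"}, {"b"}, universe={"b"})


def test_mapped_record_requires_interval():
    with pytest.raises(ValueError):
        ReadAlignmentRecord("x", True, 100, 100)


def test_rescue_monotone_in_confidence():
    """Widening the insert-size interval never shrinks the selected set."""
    recs = _records()
    narrow = filter_reads(recs, (5000, 5100), InsertSizeModel(100, 1500, 150, 0.80))
    wide = filter_reads(recs, (5000, 5100), InsertSizeModel(100, 1500, 150, 0.999))
    assert narrow.selected_ids <= wide.selected_ids
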