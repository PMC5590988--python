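import math

import numpy as np
import pytest

from insfill.debruijn import reverse_complement
from insfill.simulate import (
    GroundTruth,
    SimulationConfig,
    align_truth,
    make_reference,
    plant_insertions,
    simulate_reads,
    truth_read_ids,
)


def test_reference_deterministic_by_seed():
    assert make_reference(10, seed=1) == make_reference(10, seed=1)
    assert make_reference(10, seed=1) != make_reference(10, seed=2)


def test_reference_single_base():
    assert make_reference(1, seed=0) in "ACGT"


def test_reference_base_composition():
    ref = make_reference(100_000, seed=3)
    n = len(ref)
    sd = math.sqrt(n * 0.25 * 0.75)  # binomial sd per base
    for b in "ACGT":
        assert abs(ref.count(b) - n / 4) < 3 * sd


SMALL = SimulationConfig(
    reference_length=60_000,
    n_insertions=5,
    length_range=(50, 400),
    mean_insert=1500,
    sd_insert=150,
    seed=13,
)


def test_plant_zero_insertions_identity():
    ref = make_reference(5000, seed=0)
    cfg = SimulationConfig(reference_length=5000, n_insertions=0, seed=0)
    donor, truth, sites = plant_insertions(ref, cfg)
    assert donor == ref and sites == [] and truth.n == 0


def test_plant_length_conservation_and_coordinates():
    ref = make_reference(SMALL.reference_length, seed=13)
    donor, truth, sites = plant_insertions(ref, SMALL, np.random.default_rng(13))
    assert len(donor) == len(ref) + int(truth.insertion_lengths.sum())
    for j in range(truth.n):
        s, e = truth.donor_interval(j)
        assert donor[s:e] == truth.insertion_sequences[j]
        assert sites[j].est_length == len(truth.insertion_sequences[j])
    # insertion sites are separated enough that filters cannot interact
    sep = 2 * (SMALL.mean_insert + 4 * SMALL.sd_insert)
    assert np.all(np.diff(truth.insertion_positions) >= sep)


def test_plant_capacity_error():
    ref = make_reference(10_000, seed=0)
    with pytest.raises(ValueError, match="too short"):
        plant_insertions(ref, SimulationConfig(reference_length=10_000, n_insertions=50))


def test_read_counts_match_coverage_formula():
    donor = make_reference(100_000, seed=5)
    cfg = SimulationConfig(reference_length=100_000, coverage=30, read_length=100, seed=5)
    pairs = simulate_reads(donor, cfg)
    assert pairs.n_pairs == math.ceil(30 * 100_000 / (2 * 100))  # 15000


def test_error_free_reads_are_donor_substrings():
    donor = make_reference(20_000, seed=6)
    cfg = SimulationConfig(reference_length=20_000, coverage=5, seed=6)
    pairs = simulate_reads(donor, cfg)
    for rid in list(pairs.sequences)[:200]:
        seq = pairs.sequences[rid]
        a, b = pairs.read_interval(rid)
        expect = donor[a:b]
        if rid.endswith("/2"):
            expect = reverse_complement(expect)
        assert seq == expect


def test_empirical_insert_size_mean():
    donor = make_reference(200_000, seed=7)
    cfg = SimulationConfig(reference_length=200_000, coverage=10,
                           mean_insert=1500, sd_insert=150, seed=7)
    pairs = simulate_reads(donor, cfg)
    inner = pairs.r2_starts + cfg.read_length - pairs.r1_starts - 2 * cfg.read_length
    n = len(inner)
    assert n >= 10_000
    assert abs(inner.mean() - 1500) < 4 * 150 / math.sqrt(n)


def _toy_truth():
    # one insertion of length 200 at reference position 1000
    return GroundTruth(
        insertion_positions=np.array([1000]),
        insertion_lengths=np.array([200]),
        insertion_donor_starts=np.array([1000]),
        insertion_sequences=["X" * 200],
    )


class _FakePairs:
    read_length = 100

    def __init__(self, r1, r2):
        self.r1_starts = np.array(r1)
        self.r2_starts = np.array(r2)
        self.n_pairs = len(r1)


def test_align_truth_projection_rules():
    truth = _toy_truth()
    pairs = _FakePairs(
        r1=[100, 1050, 950, 1150],  # flank / inside insertion / crossing left / crossing right
        r2=[1600, 2000, 2000, 2000],  # right flank (donor) -> ref 1400 etc.
    )
    records = {r.read_id: r for r in align_truth(pairs, truth)}
    assert records["sim0/1"].mapped and records["sim0/1"].start == 100
    assert not records["sim1/1"].mapped  # wholly inside the insertion
    assert not records["sim2/1"].mapped  # crosses the left breakpoint
    assert not records["sim3/1"].mapped  # crosses the right breakpoint
    # donor coordinate 1600 lies after the 200 bp insertion: ref 1400
    assert records["sim0/2"].mapped and records["sim0/2"].start == 1400
    # mate linkage is projected consistently
    assert records["sim1/1"].mate_mapped and records["sim1/1"].mate_start == 1800
    assert records["sim0/1"].mate_start == 1400


def test_truth_read_ids_overlap_rule():
    truth = _toy_truth()
    pairs = _FakePairs(r1=[100, 950, 1050, 1200], r2=[2000, 2100, 2200, 2300])
    ids = truth_read_ids(pairs, truth, 0)
    assert ids == {"sim1/1", "sim2/1"}  # overlap [1000..1200) by >= 1 bp
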