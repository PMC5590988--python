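"""Synthetic data: references with planted insertions and paired-end reads.

The generator emulates a resequencing experiment for insertion genotyping:
a random reference, a donor genome carrying ``n`` planted insertions with
lengths drawn uniformly from a range, and error-free (or uniformly
substituted) paired-end reads sampled from the donor at a target fold
coverage, with inner mate distances drawn from Normal(mu, sigma).

Alignments can be produced without an external aligner: ground-truth
projection marks any read that overlaps an inserted segment as unmapped (a
conservative stand-in for an aligner's soft clipping) and places every
other read at its projected reference coordinate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from insfill.debruijn import reverse_complement
from insfill.genotype import InsertionSite
from insfill.readfilter import ReadAlignmentRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ReadPairSet",
    "SimulatedDataset",
    "make_reference",
    "plant_insertions",
    "simulate_reads",
    "align_truth",
    "simulate_dataset",
    "truth_read_ids",
]

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated data set.

    Defaults follow the simulation protocol the package is evaluated
    under: 100 insertions of 10-1000 bp planted in the reference, 100 bp
    paired reads at 30x coverage, insert sizes Normal(1500, 150) (the
    middle of the three library settings 150/15, 1500/150, 3000/300), and
    error-free reads.
    """

    reference_length: int = 1_000_000
    n_insertions: int = 100
    length_range: Tuple[int, int] = (10, 1000)
    read_length: int = 100
    coverage: float = 30.0
    mean_insert: float = 1500.0
    sd_insert: float = 150.0
    error_rate: float = 0.0
    seed: int = 0
    chrom: str = "ref"

    def __post_init__(self) -> None:
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must satisfy 1 <= lo <= hi")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.sd_insert < 0:
            raise ValueError("sd_insert must be non-negative")


@dataclass
class GroundTruth:
    """Planted-insertion coordinates on both reference and donor."""

    insertion_positions: np.ndarray  # breakpoints p on the reference, sorted
    insertion_lengths: np.ndarray
    insertion_donor_starts: np.ndarray
    insertion_sequences: List[str]

    @property
    def n(self) -> int:
        return len(self.insertion_sequences)

    def donor_interval(self, j: int) -> Tuple[int, int]:
        """Half-open donor interval occupied by insertion ``j``."""
        s = int(self.insertion_donor_starts[j])
        return s, s + int(self.insertion_lengths[j])


@dataclass
class ReadPairSet:
    """Simulated paired reads with their true donor coordinates.

    Pair ``i`` has reads ``sim{i}/1`` (fragment start, forward) and
    ``sim{i}/2`` (fragment end, reverse-complemented); both true intervals
    are recorded as forward donor coordinates.
    """

    sequences: Dict[str, str]
    r1_starts: np.ndarray
    r2_starts: np.ndarray
    read_length: int

    @property
    def n_pairs(self) -> int:
        return len(self.r1_starts)

    def read_interval(self, read_id: str) -> Tuple[int, int]:
        base, mate = read_id.rsplit("/", 1)
        i = int(base[3:])
        start = int(self.r1_starts[i] if mate == "1" else self.r2_starts[i])
        return start, start + self.read_length


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def make_reference(length: int, seed: int | np.random.Generator) -> str:
    """Uniform random A/C/G/T string, reproducible by seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _random_dna(rng, length)


def plant_insertions(
    reference: str,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[str, GroundTruth, List[InsertionSite]]:
    """Plant random insertions into the reference.

    Breakpoints are spaced at least ``2 * (mu + 4*sigma)`` apart (and away
    from the contig ends) so per-site read filters cannot interact; the
    spacing is guaranteed by construction: breakpoints are laid out on a
    minimum-separation grid and jittered by sorted random offsets.  Sites
    carry the exact planted lengths as their estimates.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    L = len(reference)
    n = config.n_insertions
    if n == 0:
        truth = GroundTruth(
            np.empty(0, int), np.empty(0, int), np.empty(0, int), []
        )
        return reference, truth, []
    sep = int(2 * (config.mean_insert + 4 * config.sd_insert))
    margin = sep // 2 + 2 * config.read_length
    slack_total = L - 2 * margin - (n - 1) * sep
    if slack_total < 0:
        raise ValueError(
            f"reference of length {L} too short for {n} insertions "
            f"with separation {sep}"
        )
    jitter = np.sort(rng.integers(0, slack_total + 1, n))
    positions = margin + np.arange(n) * sep + jitter
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, n)
    sequences = [_random_dna(rng, int(m)) for m in lengths]

    pieces: List[str] = []
    donor_starts = np.empty(n, dtype=np.int64)
    prev = 0
    inserted = 0
    for j, p in enumerate(positions):
        pieces.append(reference[prev : int(p)])
        donor_starts[j] = p + inserted
        pieces.append(sequences[j])
        inserted += int(lengths[j])
        prev = int(p)
    pieces.append(reference[prev:])
    donor = "".join(pieces)

    sites = [
        InsertionSite(
            chrom=config.chrom,
            position=int(positions[j]),
            est_length=int(lengths[j]),
            id=f"ins{j}",
        )
        for j in range(n)
    ]
    truth = GroundTruth(
        insertion_positions=positions.astype(np.int64),
        insertion_lengths=lengths.astype(np.int64),
        insertion_donor_starts=donor_starts,
        insertion_sequences=sequences,
    )
    return donor, truth, sites


def simulate_reads(
    donor: str,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> ReadPairSet:
    """Sample paired-end reads from the donor.

    The number of pairs is ``ceil(coverage * |donor| / (2 * l))``.
    Fragment starts are uniform; the inner mate distance is drawn from
    Normal(mu, sigma), rounded and truncated at 0 (mates overlap when the
    draw would be negative).  The second mate is reverse-complemented.
    Substitution errors are applied uniformly at ``error_rate``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    l = config.read_length
    L = len(donor)
    if 2 * l > L:
        raise ValueError("donor shorter than one fragment")
    if config.mean_insert - 3 * config.sd_insert < 0:
        logger.warning(
            "insert distribution Normal(%g, %g) is heavily truncated at 0",
            config.mean_insert,
            config.sd_insert,
        )
    n_pairs = math.ceil(config.coverage * L / (2 * l))
    inner = np.rint(rng.normal(config.mean_insert, config.sd_insert, n_pairs))
    inner = np.clip(inner, 0, None).astype(np.int64)
    frag = np.minimum(2 * l + inner, L)
    starts = np.floor(rng.random(n_pairs) * (L - frag + 1)).astype(np.int64)
    r2_starts = starts + frag - l

    sequences: Dict[str, str] = {}
    for i in range(n_pairs):
        x1 = int(starts[i])
        x2 = int(r2_starts[i])
        sequences[f"sim{i}/1"] = donor[x1 : x1 + l]
        sequences[f"sim{i}/2"] = reverse_complement(donor[x2 : x2 + l])
    if config.error_rate > 0:
        _apply_errors(sequences, config.error_rate, rng)
    return ReadPairSet(
        sequences=sequences,
        r1_starts=starts,
        r2_starts=r2_starts,
        read_length=l,
    )


def _apply_errors(
    sequences: Dict[str, str], rate: float, rng: np.random.Generator
) -> None:
    for rid, seq in sequences.items():
        k = rng.binomial(len(seq), rate)
        if k == 0:
            continue
        pos = rng.choice(len(seq), size=k, replace=False)
        chars = list(seq)
        for p in pos:
            # substitute with one of the three other bases
            chars[p] = "ACGT".replace(chars[p], "")[rng.integers(0, 3)]
        sequences[rid] = "".join(chars)


def align_truth(
    pairs: ReadPairSet,
    truth: GroundTruth,
    chrom: str = "ref",
) -> List[ReadAlignmentRecord]:
    """Project true donor coordinates onto the reference.

    A read overlapping any inserted segment by >= 1 bp (including reads
    wholly inside an insertion) is marked unmapped; every other read maps
    at its donor coordinate minus the total inserted length to its left.
    """
    l = pairs.read_length
    ins_starts = truth.insertion_donor_starts
    ins_ends = ins_starts + truth.insertion_lengths
    cum = np.concatenate([[0], np.cumsum(truth.insertion_lengths)])

    def project(starts: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        # index of first insertion ending strictly after the read start
        j = np.searchsorted(ins_ends, starts, side="right")
        overlaps = (j < len(ins_starts)) & (
            ins_starts[np.minimum(j, len(ins_starts) - 1)] < starts + l
        )
        if len(ins_starts) == 0:
            overlaps = np.zeros(len(starts), dtype=bool)
        ref_starts = starts - cum[j]
        return ~overlaps, ref_starts

    m1, p1 = project(pairs.r1_starts)
    m2, p2 = project(pairs.r2_starts)

    records: List[ReadAlignmentRecord] = []
    for i in range(pairs.n_pairs):
        for mate, (mapped, pos, o_mapped, o_pos) in (
            ("1", (m1[i], p1[i], m2[i], p2[i])),
            ("2", (m2[i], p2[i], m1[i], p1[i])),
        ):
            records.append(
                ReadAlignmentRecord(
                    read_id=f"sim{i}/{mate}",
                    mapped=bool(mapped),
                    start=int(pos) if mapped else None,
                    end=int(pos) + l if mapped else None,
                    mate_mapped=bool(o_mapped),
                    mate_start=int(o_pos) if o_mapped else None,
                    chrom=chrom,
                )
            )
    return records


def truth_read_ids(
    pairs: ReadPairSet,
    truth: GroundTruth,
    j: int,
    records: Optional[Sequence[ReadAlignmentRecord]] = None,
    require_mate_mapped: bool = False,
) -> Set[str]:
    """Ids of reads whose true donor interval overlaps insertion ``j``.

    This is the evaluation truth for the read filter: the reads that
    overlap the gap when placed on the ungapped (donor) genome.  With
    ``require_mate_mapped`` the set is restricted to reads whose mate maps
    to the reference, i.e. pairs that straddle the insertion.
    """
    s, e = truth.donor_interval(j)
    l = pairs.read_length
    ids: Set[str] = set()
    for mate, starts in (("1", pairs.r1_starts), ("2", pairs.r2_starts)):
        hit = np.nonzero((starts < e) & (starts + l > s))[0]
        ids.update(f"sim{i}/{mate}" for i in hit)
    if require_mate_mapped:
        if records is None:
            raise ValueError("records needed to check mate mapping")
        mate_ok = {
            r.read_id for r in records if r.mate_mapped and r.mate_start is not None
        }
        ids &= mate_ok
    return ids


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces."""

    config: SimulationConfig
    reference: str
    donor: str
    sites: List[InsertionSite]
    truth: GroundTruth
    pairs: ReadPairSet
    records: List[ReadAlignmentRecord] = field(default_factory=list)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: reference, donor, reads, truth alignments."""
    rng = np.random.default_rng(config.seed)
    reference = make_reference(config.reference_length, rng)
    donor, truth, sites = plant_insertions(reference, config, rng)
    pairs = simulate_reads(donor, config, rng)
    records = align_truth(pairs, truth, chrom=config.chrom)
    return SimulatedDataset(
        config=config,
        reference=reference,
        donor=donor,
        sites=sites,
        truth=truth,
        pairs=pairs,
        records=records,
    )
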