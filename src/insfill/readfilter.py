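"""Insert-size-based read filtering for gap filling.

Given a gap interval ``[s..e)`` and paired-end alignments, the filter
selects (i) mapped reads overlapping the gap and (ii) unmapped reads whose
mapped mate starts inside one of two rescue regions flanking the gap,

    S_left  = [s - (max + 2*l) .. e - (min + l)],
    S_right = [s + (min + l)   .. e + (max + l)],

where ``l`` is the read length and ``min``/``max`` bound the insert size
(by default the two-sided 95% normal interval, mu +/- 1.96*sigma).  Here
the *insert size* is the inner mate distance -- the number of bases between
the two reads of a pair (fragment length minus ``2*l``); with that
convention the rescue regions cover exactly the mate positions of pairs
whose other read can touch the gap.

When the selected reads' fold coverage over the gap region falls below a
threshold (set close to, but below, the sequencing coverage), the filter is
assumed to be missing unmapped reads and all unmapped reads are added as a
fallback.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, replace
from typing import FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
from scipy.stats import norm

__all__ = [
    "InsertSizeModel",
    "ReadAlignmentRecord",
    "AlignmentIndex",
    "FilterResult",
    "insert_size_bounds",
    "mate_regions",
    "filter_reads",
    "filter_reads_for_insertion",
    "apply_unmapped_fallback",
    "precision_recall",
]

logger = logging.getLogger(__name__)

Interval = Tuple[int, int]


@dataclass(frozen=True)
class InsertSizeModel:
    """Paired-end library model.

    ``mean_insert``/``sd_insert`` describe the inner mate distance in
    nucleotides (Normal(mu, sigma)); ``confidence`` sets the two-sided
    interval used to derive the min/max insert bounds.
    """

    read_length: int
    mean_insert: float
    sd_insert: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.sd_insert < 0:
            raise ValueError("sd_insert must be non-negative")
        if not (0 < self.confidence < 1):
            raise ValueError("confidence must be in (0, 1)")

    @property
    def z(self) -> float:
        """Two-sided normal critical value at the configured confidence."""
        return float(norm.ppf(0.5 + self.confidence / 2))

    @property
    def min_insert(self) -> int:
        return insert_size_bounds(self)[0]

    @property
    def max_insert(self) -> int:
        return insert_size_bounds(self)[1]


def insert_size_bounds(model: InsertSizeModel) -> Tuple[int, int]:
    """Min/max insert sizes ``mu -/+ z*sigma``, rounded outward.

    The lower bound is clamped at 0 (with a warning) since an inner mate
    distance cannot be negative.
    """
    z = model.z
    lo = math.floor(model.mean_insert - z * model.sd_insert)
    hi = math.ceil(model.mean_insert + z * model.sd_insert)
    if lo < 0:
        logger.warning("minimum insert size %d < 0; clamped to 0", lo)
        lo = 0
    return lo, hi


def mate_regions(gap: Interval, model: InsertSizeModel) -> Tuple[Interval, Interval]:
    """Rescue regions ``(S_left, S_right)`` for a gap ``[s..e)``.

    Returned bounds are inclusive mate-start coordinates, clamped below at
    0; a region whose lower bound exceeds its upper bound after clamping is
    empty.
    """
    s, e = gap
    if s > e:
        raise ValueError(f"inverted gap interval [{s}..{e}]")
    mn, mx = insert_size_bounds(model)
    l = model.read_length
    s_left = (max(0, s - (mx + 2 * l)), max(0, e - (mn + l)))
    s_right = (max(0, s + (mn + l)), max(0, e + (mx + l)))
    return s_left, s_right


def _interval_contains(iv: Interval, x: int) -> bool:
    return iv[0] <= x <= iv[1]


@dataclass(frozen=True)
class ReadAlignmentRecord:
    """One read's alignment state, plus what is known about its mate."""

    read_id: str
    mapped: bool
    start: Optional[int] = None  # 0-based, half-open [start..end)
    end: Optional[int] = None
    mate_mapped: bool = False
    mate_start: Optional[int] = None
    chrom: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mapped and not (
            self.start is not None and self.end is not None and self.start < self.end
        ):
            raise ValueError(f"mapped read {self.read_id} needs start < end")


class AlignmentIndex:
    """Position index over alignment records for fast per-gap queries.

    Mapped reads are indexed by start coordinate; unmapped reads with a
    mapped mate are indexed by the mate's start.  Unmapped records whose
    mate is flagged mapped but carries no coordinate are skipped and
    counted in ``n_skipped``.
    """

    def __init__(self, records: Iterable[ReadAlignmentRecord]):
        mapped: List[Tuple[int, int, str]] = []
        rescue: List[Tuple[int, str]] = []
        self.all_unmapped_ids: Set[str] = set()
        self.n_skipped = 0
        self.n_records = 0
        for rec in records:
            self.n_records += 1
            if rec.mapped:
                mapped.append((rec.start, rec.end, rec.read_id))
            else:
                self.all_unmapped_ids.add(rec.read_id)
                if rec.mate_mapped:
                    if rec.mate_start is None:
                        self.n_skipped += 1
                    else:
                        rescue.append((rec.mate_start, rec.read_id))
        if self.n_skipped:
            logger.warning(
                "%d unmapped records lacked mate coordinates and were skipped",
                self.n_skipped,
            )
        mapped.sort(key=lambda t: t[0])
        rescue.sort(key=lambda t: t[0])
        self._m_starts = np.array([t[0] for t in mapped], dtype=np.int64)
        self._m_ends = np.array([t[1] for t in mapped], dtype=np.int64)
        self._m_ids = [t[2] for t in mapped]
        self._max_span = int((self._m_ends - self._m_starts).max()) if mapped else 0
        self._r_starts = [t[0] for t in rescue]
        self._r_ids = [t[1] for t in rescue]

    def mapped_overlapping(self, s: int, e: int) -> Set[str]:
        """Ids of mapped reads overlapping ``[s..e)`` by >= 1 bp."""
        if e <= s or len(self._m_starts) == 0:
            return set()
        lo = int(np.searchsorted(self._m_starts, s - self._max_span, side="left"))
        hi = int(np.searchsorted(self._m_starts, e, side="left"))
        return {
            self._m_ids[i]
            for i in range(lo, hi)
            if self._m_ends[i] > s  # start < e guaranteed by the slice
        }

    def mapped_crossing(self, p: int) -> Set[str]:
        """Ids of mapped reads with ``start < p < end`` (cross point p)."""
        if len(self._m_starts) == 0:
            return set()
        lo = int(np.searchsorted(self._m_starts, p - self._max_span, side="left"))
        hi = int(np.searchsorted(self._m_starts, p, side="left"))
        return {self._m_ids[i] for i in range(lo, hi) if self._m_ends[i] > p}

    def rescueable_in(self, lo: int, hi: int) -> Set[str]:
        """Ids of unmapped reads whose mapped mate starts in ``[lo..hi]``."""
        if hi < lo:
            return set()
        i = bisect.bisect_left(self._r_starts, lo)
        j = bisect.bisect_right(self._r_starts, hi)
        return set(self._r_ids[i:j])


@dataclass(frozen=True)
class FilterResult:
    """Outcome of read filtering for one gap."""

    selected_ids: FrozenSet[str]
    realized_coverage: float
    region_length: int
    read_length: int
    expected_coverage: Optional[float] = None
    fallback_fired: bool = False
    pre_fallback_coverage: Optional[float] = None
    n_skipped: int = 0


def _coverage(n_reads: int, read_length: int, region_length: int) -> float:
    return n_reads * read_length / region_length if region_length > 0 else 0.0


def _ensure_index(
    alignments: Union[AlignmentIndex, Iterable[ReadAlignmentRecord]]
) -> AlignmentIndex:
    return alignments if isinstance(alignments, AlignmentIndex) else AlignmentIndex(alignments)


def filter_reads(
    alignments: Union[AlignmentIndex, Iterable[ReadAlignmentRecord]],
    gap: Interval,
    model: InsertSizeModel,
    expected_coverage: Optional[float] = None,
) -> FilterResult:
    """Select reads likely to cover the gap ``[s..e)``.

    The gap is expressed in the same coordinates as the alignments (the
    gapped assembly/reference).  Selected reads are mapped reads
    overlapping the gap plus unmapped reads rescued through their mate's
    position; duplicates are removed by read id.  The realized fold
    coverage is measured over the gap extended by one read length on each
    side, so reads only partially overlapping the gap still count.
    """
    index = _ensure_index(alignments)
    s, e = gap
    s_left, s_right = mate_regions(gap, model)
    selected = index.mapped_overlapping(s, e)
    selected |= index.rescueable_in(*s_left)
    selected |= index.rescueable_in(*s_right)
    region_length = (e - s) + 2 * model.read_length
    return FilterResult(
        selected_ids=frozenset(selected),
        realized_coverage=_coverage(len(selected), model.read_length, region_length),
        region_length=region_length,
        read_length=model.read_length,
        expected_coverage=expected_coverage,
        n_skipped=index.n_skipped,
    )


def filter_reads_for_insertion(
    alignments: Union[AlignmentIndex, Iterable[ReadAlignmentRecord]],
    breakpoint: int,
    est_length: int,
    model: InsertSizeModel,
    expected_coverage: Optional[float] = None,
) -> FilterResult:
    """Read filter for an insertion breakpoint on the ungapped reference.

    Conceptually a gap of the estimated insertion length ``d`` is inserted
    at the breakpoint ``p`` and the standard gap filter is applied on the
    gapped coordinate system; since the alignments are against the plain
    reference (where the insertion is absent), the gapped-coordinate
    queries are translated back: mapped positions at or beyond ``p`` shift
    by ``d``, so a mapped read overlaps the gap exactly when it crosses
    ``p``, left-side mates keep their coordinates, and right-side mate
    bounds shift down by ``d``.
    """
    index = _ensure_index(alignments)
    p, d = breakpoint, est_length
    if d < 0:
        raise ValueError("est_length must be non-negative")
    (l_lo, l_hi), (r_lo, r_hi) = mate_regions((p, p + d), model)
    selected = index.mapped_crossing(p)
    # left-side mates: reference coords equal gapped coords, but only below p
    selected |= index.rescueable_in(l_lo, min(l_hi, p - 1))
    # right-side mates: gapped coords are reference coords + d
    selected |= index.rescueable_in(max(r_lo - d, p), r_hi - d)
    region_length = d + 2 * model.read_length
    return FilterResult(
        selected_ids=frozenset(selected),
        realized_coverage=_coverage(len(selected), model.read_length, region_length),
        region_length=region_length,
        read_length=model.read_length,
        expected_coverage=expected_coverage,
        n_skipped=index.n_skipped,
    )


def apply_unmapped_fallback(
    result: FilterResult,
    all_unmapped_ids: Iterable[str],
    threshold: float,
) -> FilterResult:
    """Add every unmapped read when realized coverage is below ``threshold``.

    The threshold is a fold coverage; it should be close to, but smaller
    than, the coverage of the read library.  With ``threshold <= 0`` the
    fallback never fires.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if threshold == 0 or result.realized_coverage >= threshold:
        return result
    selected = frozenset(result.selected_ids | set(all_unmapped_ids))
    return replace(
        result,
        selected_ids=selected,
        realized_coverage=_coverage(
            len(selected), result.read_length, result.region_length
        ),
        fallback_fired=True,
        pre_fallback_coverage=result.realized_coverage,
    )


def precision_recall(
    selected: Iterable[str],
    truth: Iterable[str],
    universe: Optional[Iterable[str]] = None,
) -> Tuple[Optional[float], Optional[float]]:
    """Precision and recall of a selected read set against a truth set.

    ``precision = TP / (TP + FP)`` and ``recall = TP / (TP + FN)``.  An
    empty denominator yields ``None`` (undefined), never 0.
    """
    sel = set(selected)
    tru = set(truth)
    if universe is not None:
        uni = set(universe)
        if not sel <= uni or not tru <= uni:
            raise ValueError("selected and truth must be subsets of the universe")
    tp = len(sel & tru)
    precision = tp / len(sel) if sel else None
    recall = tp / len(tru) if tru else None
    return precision, recall
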