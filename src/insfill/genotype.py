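"""End-to-end insertion genotyping.

For each breakpoint the pipeline cuts flanking sequence from the reference,
restricts the read set to gap-relevant reads (when alignments are
available), builds a site-local de Bruijn graph, and fills the gap of the
estimated insertion length between the flanks.  This is the gap-filling
reduction of insertion genotyping: conceptually, a gap of the estimated
length is inserted at each breakpoint of the reference and filling those
gaps reconstructs the donor genome.

Coordinates are 0-based half-open throughout; a site's breakpoint ``p``
means the insertion occurs between reference bases ``p - 1`` and ``p``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from insfill.debruijn import (
    EmptyGraphError,
    KmerGraph,
    build_graph,
    graph_from_counts,
    kmer_counts,
)
from insfill.gapfill import FillResult, GapSpec, fill_gap
from insfill.readfilter import (
    AlignmentIndex,
    FilterResult,
    ReadAlignmentRecord,
    apply_unmapped_fallback,
    filter_reads_for_insertion,
)

__all__ = [
    "InsertionSite",
    "GenotypeCall",
    "AmbiguousFlankError",
    "BreakpointRangeError",
    "extract_flanks",
    "genotype_site",
    "genotype_all",
    "splice_donor",
]

logger = logging.getLogger(__name__)

Reference = Union[str, Mapping[str, str]]


class AmbiguousFlankError(ValueError):
    """A flank k-mer contains an ambiguous base."""


class BreakpointRangeError(ValueError):
    """Breakpoint too close to a contig end for flank k-mers to exist."""


@dataclass(frozen=True)
class InsertionSite:
    """An insertion breakpoint with a length estimate.

    ``position`` is the 0-based offset ``p``: the insertion lies between
    reference bases ``p - 1`` and ``p``.
    """

    chrom: str
    position: int
    est_length: int
    id: str = ""


@dataclass
class GenotypeCall:
    """Result of genotyping one site."""

    site: InsertionSite
    status: str  # "filled" | "not_filled"
    insertion: Optional[str] = None
    filter_stats: Optional[FilterResult] = None
    fill: Optional[FillResult] = None

    @property
    def filled(self) -> bool:
        return self.status == "filled"


def extract_flanks(reference: str, p: int, k: int) -> Tuple[str, str]:
    """Boundary k-mers ``s = R[p-k..p]`` and ``t = R[p..p+k]``.

    Raises :class:`BreakpointRangeError` when a k-mer would run off the
    contig and :class:`AmbiguousFlankError` when either window contains a
    non-ACGT base.
    """
    if not (k <= p <= len(reference) - k):
        raise BreakpointRangeError(
            f"breakpoint {p} too close to contig end for k={k}"
        )
    s = reference[p - k : p].upper()
    t = reference[p : p + k].upper()
    for km in (s, t):
        if any(c not in "ACGT" for c in km):
            raise AmbiguousFlankError(f"ambiguous base in flank k-mer at p={p}")
    return s, t


def _get_ref(reference: Reference, chrom: str) -> str:
    if isinstance(reference, str):
        return reference
    try:
        return reference[chrom]
    except KeyError:
        raise KeyError(f"reference sequence {chrom!r} not found") from None


def _default_config():
    from insfill.io import RunConfig  # deferred: io imports this module

    return RunConfig()


def _fill_site(
    site: InsertionSite,
    refseq: str,
    graph: KmerGraph,
    cfg,
    filter_stats: Optional[FilterResult],
) -> GenotypeCall:
    k = cfg.k
    extract_flanks(refseq, site.position, k)  # validates range and bases
    window = cfg.flank_window or 2 * cfg.read_length
    left = refseq[max(0, site.position - window) : site.position].upper()
    right = refseq[site.position : site.position + window].upper()
    fuzz = min(cfg.fuzz, len(left) - k, len(right) - k)
    spec = GapSpec(
        left_flank=left,
        right_flank=right,
        est_length=site.est_length,
        slack=cfg.slack,
        fuzz=max(0, fuzz),
    )
    result = fill_gap(graph, spec, max_cost=cfg.max_cost)
    if result is None:
        logger.info("site %s at %d: not filled", site.id, site.position)
        return GenotypeCall(site, "not_filled", filter_stats=filter_stats)
    logger.info(
        "site %s at %d: filled length %d (offsets %d/%d%s)",
        site.id,
        site.position,
        len(result.insertion),
        result.left_offset,
        result.right_offset,
        ", fallback" if filter_stats is not None and filter_stats.fallback_fired else "",
    )
    return GenotypeCall(
        site, "filled", insertion=result.insertion, filter_stats=filter_stats, fill=result
    )


class _SiteGraphBuilder:
    """Builds per-site graphs from filtered reads.

    When the unmapped-read fallback fires, the (large, site-independent)
    k-mer counts of all unmapped reads are computed once and reused; only
    the site-specific mapped/rescued reads are counted per site.
    """

    def __init__(self, reads: Mapping[str, str], index: AlignmentIndex, cfg):
        self.reads = reads
        self.index = index
        self.cfg = cfg
        self._unmapped_counts = None

    def _unmapped(self):
        if self._unmapped_counts is None:
            seqs = [
                self.reads[rid]
                for rid in sorted(self.index.all_unmapped_ids)
                if rid in self.reads
            ]
            self._unmapped_counts = kmer_counts(seqs, self.cfg.k)
        return self._unmapped_counts

    def build(self, fr: FilterResult) -> Optional[KmerGraph]:
        cfg = self.cfg
        if fr.fallback_fired:
            vbase, ebase = self._unmapped()
            vc, ec = dict(vbase), dict(ebase)
            extra_ids = fr.selected_ids - self.index.all_unmapped_ids
            if extra_ids:
                va, ea = kmer_counts(
                    [self.reads[r] for r in sorted(extra_ids) if r in self.reads],
                    cfg.k,
                )
                for km, c in va.items():
                    vc[km] = vc.get(km, 0) + c
                for e, c in ea.items():
                    ec[e] = ec.get(e, 0) + c
        else:
            seqs = [self.reads[r] for r in sorted(fr.selected_ids) if r in self.reads]
            if not seqs:
                return None
            vc, ec = kmer_counts(seqs, cfg.k)
        try:
            return graph_from_counts(vc, ec, cfg.k, min_abundance=cfg.min_abundance)
        except EmptyGraphError:
            return None


def genotype_site(
    site: InsertionSite,
    reference: Reference,
    reads: Mapping[str, str],
    alignments: Optional[Union[AlignmentIndex, Sequence[ReadAlignmentRecord]]] = None,
    config=None,
    graph: Optional[KmerGraph] = None,
) -> GenotypeCall:
    """Genotype a single insertion site.

    With ``alignments`` the read set is first restricted by the insert-size
    filter (plus the unmapped fallback) and a site-local graph is built
    from the selected reads; without alignments a global graph over all
    reads is used (pass a prebuilt ``graph`` to share it across sites).
    """
    cfg = config if config is not None else _default_config()
    refseq = _get_ref(reference, site.chrom)
    if alignments is not None:
        index = (
            alignments
            if isinstance(alignments, AlignmentIndex)
            else AlignmentIndex(alignments)
        )
        fr = filter_reads_for_insertion(
            index, site.position, site.est_length, cfg.model()
        )
        fr = apply_unmapped_fallback(fr, index.all_unmapped_ids, cfg.threshold())
        site_graph = _SiteGraphBuilder(reads, index, cfg).build(fr)
        if site_graph is None:
            return GenotypeCall(site, "not_filled", filter_stats=fr)
        return _fill_site(site, refseq, site_graph, cfg, fr)
    if graph is None:
        graph = build_graph(reads.values(), cfg.k, min_abundance=cfg.min_abundance)
    return _fill_site(site, refseq, graph, cfg, None)


def genotype_all(
    sites: Sequence[InsertionSite],
    reference: Reference,
    reads: Mapping[str, str],
    alignments: Optional[Union[AlignmentIndex, Sequence[ReadAlignmentRecord]]] = None,
    config=None,
) -> List[GenotypeCall]:
    """Genotype every site; sites are processed independently.

    Sites whose flank windows overlap are still processed (the pipeline
    assumes no other variation overlaps a site's flanks), but a warning is
    logged.
    """
    cfg = config if config is not None else _default_config()
    _warn_overlapping(sites, cfg)
    calls: List[GenotypeCall] = []
    if alignments is not None:
        index = (
            alignments
            if isinstance(alignments, AlignmentIndex)
            else AlignmentIndex(alignments)
        )
        builder = _SiteGraphBuilder(reads, index, cfg)
        model = cfg.model()
        threshold = cfg.threshold()
        for site in sites:
            refseq = _get_ref(reference, site.chrom)
            fr = filter_reads_for_insertion(
                index, site.position, site.est_length, model
            )
            fr = apply_unmapped_fallback(fr, index.all_unmapped_ids, threshold)
            site_graph = builder.build(fr)
            if site_graph is None:
                calls.append(GenotypeCall(site, "not_filled", filter_stats=fr))
                continue
            calls.append(_fill_site(site, refseq, site_graph, cfg, fr))
        return calls
    graph = build_graph(reads.values(), cfg.k, min_abundance=cfg.min_abundance)
    for site in sites:
        refseq = _get_ref(reference, site.chrom)
        calls.append(_fill_site(site, refseq, graph, cfg, None))
    return calls


def _warn_overlapping(sites: Sequence[InsertionSite], cfg) -> None:
    window = cfg.flank_window or 2 * cfg.read_length
    by_chrom: Dict[str, List[InsertionSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, group in by_chrom.items():
        ordered = sorted(group, key=lambda s: s.position)
        for a, b in zip(ordered, ordered[1:]):
            if b.position - a.position < 2 * window:
                logger.warning(
                    "sites %s and %s on %s are within 2x flank window; "
                    "filters/flanks may interact",
                    a.id,
                    b.id,
                    chrom,
                )


def splice_donor(reference: str, calls: Iterable[GenotypeCall]) -> str:
    """Reconstruct the donor sequence: reference with filled insertions
    spliced in at their breakpoints."""
    filled = sorted(
        (c for c in calls if c.filled), key=lambda c: c.site.position
    )
    pieces: List[str] = []
    prev = 0
    for call in filled:
        p = call.site.position
        pieces.append(reference[prev:p])
        pieces.append(call.insertion or "")
        prev = p
    pieces.append(reference[prev:])
    return "".join(pieces)
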