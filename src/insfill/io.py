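"""File formats and run configuration.

Readers and writers for the standard formats the pipeline touches: FASTA
references, FASTQ read pairs, SAM alignments, and insertion sites as VCF
(``<INS>`` ALT with an ``SVLEN`` INFO field) or a 4-column TSV
(chrom, pos, id, length; ``pos`` is the 0-based breakpoint).

Internally all coordinates are 0-based half-open; VCF I/O converts to and
from the 1-based convention (the VCF POS is the base *before* the
insertion, i.e. breakpoint ``p`` in 0-based coordinates maps to POS ``p``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pysam
from Bio import SeqIO

from insfill.genotype import GenotypeCall, InsertionSite
from insfill.readfilter import InsertSizeModel, ReadAlignmentRecord

__all__ = [
    "RunConfig",
    "default_unmapped_threshold",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq_pairs",
    "read_sam",
    "write_sam",
    "read_sites",
    "write_sites_vcf",
    "write_calls_vcf",
    "write_report_tsv",
]


def default_unmapped_threshold(coverage: Optional[float] = None) -> float:
    """Fold-coverage threshold for the unmapped-read fallback.

    The threshold should sit close to, but below, the library coverage
    (e.g. 10 at 15x, 25 at 30x, 45 at 50x); ``floor(0.85 * coverage)``
    realizes that rule, defaulting to 25 when coverage is unknown.
    """
    if coverage is None:
        return 25.0
    return float(math.floor(0.85 * coverage))


@dataclass(frozen=True)
class RunConfig:
    """Pipeline parameters and their defaults.

    ``k=31`` is the de Bruijn graph order used throughout; ``slack=None``
    resolves per site to ``max(10, ceil(0.1 * d))``; the fallback
    threshold resolves from ``coverage`` when not given explicitly.
    ``min_abundance=2`` suppresses singleton error k-mers; use 1 for
    error-free reads.
    """

    k: int = 31
    min_abundance: int = 2
    slack: Optional[int] = None
    fuzz: int = 10
    read_length: int = 100
    mean_insert: float = 1500.0
    sd_insert: float = 150.0
    confidence: float = 0.95
    coverage: Optional[float] = None
    unmapped_threshold: Optional[float] = None
    flank_window: Optional[int] = None  # None -> 2 * read_length
    max_cost: Optional[int] = None

    def model(self) -> InsertSizeModel:
        return InsertSizeModel(
            read_length=self.read_length,
            mean_insert=self.mean_insert,
            sd_insert=self.sd_insert,
            confidence=self.confidence,
        )

    def threshold(self) -> float:
        if self.unmapped_threshold is not None:
            return self.unmapped_threshold
        return default_unmapped_threshold(self.coverage)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> Dict[str, str]:
    """Sequences by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(*paths) -> Dict[str, str]:
    """Read one or more FASTQ files into an id -> sequence mapping."""
    reads: Dict[str, str] = {}
    for path in paths:
        for rec in SeqIO.parse(str(path), "fastq"):
            reads[rec.id] = str(rec.seq).upper()
    return reads


def write_fastq_pairs(sequences: Mapping[str, str], path1, path2) -> None:
    """Write ``.../1`` reads to ``path1`` and ``.../2`` reads to ``path2``."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rid in sorted(sequences, key=_fastq_sort_key):
            seq = sequences[rid]
            fh = f2 if rid.endswith("/2") else f1
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def _fastq_sort_key(rid: str):
    base, _, mate = rid.rpartition("/")
    if base.startswith("sim") and base[3:].isdigit():
        return (int(base[3:]), mate)
    return (base, mate)


# ---------------------------------------------------------------------------
# SAM


def _split_read_id(read_id: str) -> Tuple[str, Optional[int]]:
    if read_id.endswith("/1"):
        return read_id[:-2], 1
    if read_id.endswith("/2"):
        return read_id[:-2], 2
    return read_id, None


def write_sam(
    records: Sequence[ReadAlignmentRecord],
    path,
    reference_name: str,
    reference_length: int,
    sequences: Optional[Mapping[str, str]] = None,
) -> None:
    """Write alignment records as a (headered, unsorted) SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": reference_name, "LN": reference_length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            qname, mate = _split_read_id(rec.read_id)
            seg.query_name = qname
            flag = 0
            if mate is not None:
                flag |= 0x1 | (0x40 if mate == 1 else 0x80)
            if rec.mapped:
                seg.reference_id = 0
                seg.reference_start = rec.start
                seg.mapping_quality = 60
                seg.cigarstring = f"{rec.end - rec.start}M"
            else:
                flag |= 0x4
            if mate is not None:
                if rec.mate_mapped and rec.mate_start is not None:
                    seg.next_reference_id = 0
                    seg.next_reference_start = rec.mate_start
                else:
                    flag |= 0x8
            seq = sequences.get(rec.read_id) if sequences else None
            if seq is not None:
                seg.query_sequence = seq
                seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            seg.flag = flag
            out.write(seg)


def read_sam(path) -> List[ReadAlignmentRecord]:
    """Load alignment records from SAM/BAM.

    Secondary and supplementary alignments are ignored; paired reads get
    ``/1``/``/2`` id suffixes so ids match the FASTQ naming.
    """
    records: List[ReadAlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for seg in sam:
            if seg.is_secondary or seg.is_supplementary:
                continue
            rid = seg.query_name
            if seg.is_paired:
                rid += "/1" if seg.is_read1 else "/2"
            mapped = not seg.is_unmapped
            mate_mapped = seg.is_paired and not seg.mate_is_unmapped
            records.append(
                ReadAlignmentRecord(
                    read_id=rid,
                    mapped=mapped,
                    start=seg.reference_start if mapped else None,
                    end=seg.reference_end if mapped else None,
                    mate_mapped=mate_mapped,
                    mate_start=seg.next_reference_start
                    if mate_mapped and seg.next_reference_start >= 0
                    else None,
                    chrom=seg.reference_name if mapped else None,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Insertion sites (VCF / TSV)


def read_sites(path) -> List[InsertionSite]:
    """Read insertion sites from VCF (``SVLEN`` or sequence ALT) or TSV."""
    spath = str(path)
    if spath.endswith(".vcf") or spath.endswith(".vcf.gz") or spath.endswith(".bcf"):
        return _read_sites_vcf(spath)
    return _read_sites_tsv(spath)


def _read_sites_vcf(path: str) -> List[InsertionSite]:
    sites: List[InsertionSite] = []
    with pysam.VariantFile(path) as vcf:
        for i, rec in enumerate(vcf):
            # VCF POS is the base before the insertion: 0-based breakpoint
            # = rec.start + 1.
            p = rec.start + 1
            svlen = rec.info.get("SVLEN") if "SVLEN" in rec.info else None
            if svlen is not None:
                if isinstance(svlen, (tuple, list)):
                    svlen = svlen[0]
                d = abs(int(svlen))
            else:
                alt = rec.alts[0] if rec.alts else ""
                if not alt or alt.startswith("<"):
                    raise ValueError(
                        f"{path}: record {i + 1} has symbolic ALT but no SVLEN"
                    )
                d = len(alt) - len(rec.ref)
                if d <= 0:
                    raise ValueError(f"{path}: record {i + 1} is not an insertion")
            sites.append(
                InsertionSite(
                    chrom=rec.chrom,
                    position=p,
                    est_length=d,
                    id=rec.id or f"site{i}",
                )
            )
    return sites


def _read_sites_tsv(path: str) -> List[InsertionSite]:
    sites: List[InsertionSite] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns, got {len(fields)}")
            chrom, pos, sid, length = fields
            try:
                sites.append(
                    InsertionSite(
                        chrom=chrom, position=int(pos), est_length=int(length), id=sid
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
    return sites


def write_sites_tsv(sites: Sequence[InsertionSite], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.position}\t{s.id}\t{s.est_length}\n")


def _vcf_header(reference: Mapping[str, str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##FILTER=<ID=NOTFILLED,Description="Insertion not assembled">')
    for name, seq in reference.items():
        header.contigs.add(name, length=len(seq))
    return header


def write_sites_vcf(
    sites: Sequence[InsertionSite], reference: Mapping[str, str], path
) -> None:
    """Write sites as symbolic ``<INS>`` records with ``SVLEN``."""
    header = _vcf_header(reference)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for s in sorted(sites, key=lambda s: (s.chrom, s.position)):
            ref_base = reference[s.chrom][s.position - 1]
            rec = out.new_record(
                contig=s.chrom,
                start=s.position - 1,
                stop=s.position,
                alleles=(ref_base, "<INS>"),
                id=s.id or None,
            )
            rec.info["SVTYPE"] = "INS"
            rec.info["SVLEN"] = s.est_length
            out.write(rec)


def write_calls_vcf(
    calls: Sequence[GenotypeCall], reference: Mapping[str, str], path
) -> None:
    """Write genotype calls; filled sites carry the assembled ALT sequence."""
    header = _vcf_header(reference)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.site.chrom, c.site.position)):
            s = c.site
            ref_base = reference[s.chrom][s.position - 1]
            if c.filled:
                alleles = (ref_base, ref_base + c.insertion)
            else:
                alleles = (ref_base, "<INS>")
            rec = out.new_record(
                contig=s.chrom,
                start=s.position - 1,
                stop=s.position,
                alleles=alleles,
                id=s.id or None,
            )
            rec.info["SVTYPE"] = "INS"
            rec.info["SVLEN"] = len(c.insertion) if c.filled else s.est_length
            if not c.filled:
                rec.filter.add("NOTFILLED")
            out.write(rec)


def write_report_tsv(
    calls: Sequence[GenotypeCall],
    path,
    scores: Optional[Mapping[str, float]] = None,
) -> None:
    """Machine-readable per-site report.

    Columns: site id, chrom, breakpoint, estimated length, status, filled
    length, whether the unmapped fallback fired, and (when truth is
    available) the normalized edit-distance score.
    """
    with open(path, "w") as fh:
        fh.write(
            "site\tchrom\tpos\test_length\tstatus\tfilled_length\tfallback\tscore\n"
        )
        for c in calls:
            filled_len = len(c.insertion) if c.filled else ""
            fallback = (
                str(int(c.filter_stats.fallback_fired)) if c.filter_stats else ""
            )
            sc = ""
            if scores is not None and c.site.id in scores:
                sc = f"{scores[c.site.id]:.4f}"
            fh.write(
                f"{c.site.id}\t{c.site.chrom}\t{c.site.position}\t"
                f"{c.site.est_length}\t{c.status}\t{filled_len}\t{fallback}\t{sc}\n"
            )
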