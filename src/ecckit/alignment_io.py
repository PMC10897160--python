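"""Alignment input/output, deduplication, chimeric-read extraction, coverage.

SAM/BAM records are read and written with pysam; internally every mapped
record is represented by the lightweight :class:`Alignment` dataclass with
0-based half-open coordinates. Supplementary alignments are described by SA
descriptors following the SAM tag grammar ``chrom,pos,strand,CIGAR,mapQ,NM;``
(1-based in the tag, converted at the boundary).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .intervals import GenomicInterval

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# CIGAR operations that consume the reference
_REF_OPS = set("MDN=X")
# operations that consume the query
_QUERY_OPS = set("MIS=X")


def cigar_tuples(cigar: str) -> list[tuple[str, int]]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if not ops or sum(n for _, n in ops) == 0:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return ops

def reference_span(cigar: str) -> int:
    return sum(n for op, n in cigar_tuples(cigar) if op in _REF_OPS)


def clip_lengths(cigar: str) -> tuple[int, int]:
    """(leading, trailing) soft+hard clip lengths."""
    ops = cigar_tuples(cigar)
    lead = 0
    for op, n in ops:
        if op in "SH":
            lead += n
        else:
            break
    trail = 0
    for op, n in reversed(ops):
        if op in "SH":
            trail += n
        else:
            break
    return lead, trail


@dataclass
class SAEntry:
    """One supplementary-alignment descriptor (0-based position)."""

    chrom: str
    pos: int
    strand: str
    cigar: str
    mapq: int
    nm: int = 0

    @classmethod
    def parse(cls, token: str) -> "SAEntry":
        parts = token.split(",")
        chrom, pos, strand, cigar, mapq = parts[:5]
        nm = int(parts[5]) if len(parts) > 5 and parts[5] != "" else 0
        return cls(chrom, int(pos) - 1, strand, cigar, int(mapq), nm)

    def unparse(self) -> str:
        return f"{self.chrom},{self.pos + 1},{self.strand},{self.cigar},{self.mapq},{self.nm};"


def parse_sa_tag(tag: str) -> list[SAEntry]:
    return [SAEntry.parse(t) for t in tag.split(";") if t]


@dataclass
class Alignment:
    """One mapped SAM record (primary, secondary or supplementary)."""

    read_id: str
    is_read1: bool
    chrom: str
    start: int
    cigar: str
    mapq: int
    is_reverse: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    is_proper_pair: bool = False
    is_paired: bool = True
    mate_chrom: str | None = None
    mate_start: int | None = None
    mate_is_reverse: bool = False
    mate_unmapped: bool = False
    insert_size: int = 0
    sa_entries: list[SAEntry] = field(default_factory=list)
    seq: str | None = None

    @property
    def end(self) -> int:
        """Reference end (exclusive) implied by the CIGAR."""
        return self.start + reference_span(self.cigar)

    @property
    def is_primary(self) -> bool:
        return not (self.is_secondary or self.is_supplementary)

    @property
    def unclipped_5prime(self) -> int:
        lead, trail = clip_lengths(self.cigar)
        return self.end + trail if self.is_reverse else self.start - lead

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _from_pysam(rec: pysam.AlignedSegment) -> Alignment:
    sa = []
    if rec.has_tag("SA"):
        sa = parse_sa_tag(rec.get_tag("SA"))
    return Alignment(
        read_id=rec.query_name,
        is_read1=not rec.is_read2,
        chrom=rec.reference_name,
        start=rec.reference_start,
        cigar=rec.cigarstring,
        mapq=rec.mapping_quality,
        is_reverse=rec.is_reverse,
        is_secondary=rec.is_secondary,
        is_supplementary=rec.is_supplementary,
        is_duplicate=rec.is_duplicate,
        is_proper_pair=rec.is_proper_pair,
        is_paired=rec.is_paired,
        mate_chrom=rec.next_reference_name if rec.is_paired and not rec.mate_is_unmapped else None,
        mate_start=rec.next_reference_start if rec.is_paired and not rec.mate_is_unmapped else None,
        mate_is_reverse=rec.mate_is_reverse if rec.is_paired else False,
        mate_unmapped=rec.mate_is_unmapped if rec.is_paired else False,
        insert_size=rec.template_length,
        sa_entries=sa,
        seq=rec.query_sequence,
    )


def read_alignments(
    path: str | Path,
    region: GenomicInterval | None = None,
    include_unmapped: bool = False,
) -> Iterator[Alignment]:
    """Stream mapped records from a SAM/BAM file, optionally restricted to a region.

    Yields primary, secondary and supplementary records in file (coordinate)
    order; unmapped records are skipped unless requested (they come through
    with ``chrom=None`` semantics and are only useful for counting).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mode = "rb" if path.suffix == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        it: Iterable[pysam.AlignedSegment]
        if region is not None:
            if fh.has_index():
                it = fh.fetch(region.chrom, region.start, region.end)
            else:
                it = (
                    r
                    for r in fh
                    if not r.is_unmapped
                    and r.reference_name == region.chrom
                    and r.reference_start < region.end
                    and r.reference_end > region.start
                )
        else:
            it = fh
        for rec in it:
            if rec.is_unmapped:
                if include_unmapped:
                    yield Alignment(
                        read_id=rec.query_name, is_read1=not rec.is_read2,
                        chrom="*", start=0, cigar="1M", mapq=0, is_paired=rec.is_paired,
                    )
                continue
            yield _from_pysam(rec)


def count_total_reads(path: str | Path) -> int:
    """Total primary records (mapped + unmapped), as samtools flagstat counts them."""
    n = 0
    path = Path(path)
    mode = "rb" if path.suffix == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if not rec.is_secondary and not rec.is_supplementary:
                n += 1
    return n


def write_alignments(
    alignments: Sequence[Alignment],
    path: str | Path,
    contig_lengths: dict[str, int],
    sort: bool = True,
) -> None:
    """Write records to SAM (or BAM if the path ends in .bam)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate" if sort else "unknown"},
        "SQ": [{"SN": c, "LN": n} for c, n in contig_lengths.items()],
    }
    tid = {c: i for i, c in enumerate(contig_lengths)}
    recs = sorted(alignments, key=lambda a: (tid[a.chrom], a.start)) if sort else alignments
    path = Path(path)
    mode = "wb" if path.suffix == ".bam" else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for a in recs:
            r = pysam.AlignedSegment(out.header)
            r.query_name = a.read_id
            r.reference_id = tid[a.chrom]
            r.reference_start = a.start
            r.cigarstring = a.cigar
            r.mapping_quality = a.mapq
            flag = 0
            if a.is_paired:
                flag |= 0x1
                flag |= 0x40 if a.is_read1 else 0x80
                if a.is_proper_pair:
                    flag |= 0x2
                if a.mate_unmapped:
                    flag |= 0x8
                if a.mate_is_reverse:
                    flag |= 0x20
            if a.is_reverse:
                flag |= 0x10
            if a.is_secondary:
                flag |= 0x100
            if a.is_duplicate:
                flag |= 0x400
            if a.is_supplementary:
                flag |= 0x800
            r.flag = flag
            if a.is_paired and a.mate_chrom is not None:
                r.next_reference_id = tid[a.mate_chrom]
                r.next_reference_start = a.mate_start
            else:
                r.next_reference_id = -1
                r.next_reference_start = -1
            r.template_length = a.insert_size
            if a.seq is not None:
                r.query_sequence = a.seq
                r.query_qualities = pysam.qualitystring_to_array("I" * len(a.seq))
            if a.sa_entries:
                r.set_tag("SA", "".join(e.unparse() for e in a.sa_entries))
            out.write(r)


# ---------------------------------------------------------------------------
# deduplication


def _dedup_key(a: Alignment) -> tuple:
    return (a.chrom, a.unclipped_5prime, a.is_reverse)


def deduplicate(segments: Sequence[Alignment]) -> list[Alignment]:
    """Remove duplicate read pairs, keeping one pair per fragment signature.

    The signature is the pair of clip-adjusted (unclipped) 5' positions and
    orientations of both mates; among duplicates the pair with the highest
    summed mapping quality wins, ties broken by the lexicographically
    smallest read name. Orphan reads are deduplicated on their single-end
    key. Secondary/supplementary records follow the fate of their primary.
    """
    primaries: dict[str, list[Alignment]] = {}
    for a in segments:
        if a.is_primary:
            primaries.setdefault(a.read_id, []).append(a)

    groups: dict[tuple, list[tuple[int, str]]] = {}
    for rid, recs in primaries.items():
        keys = sorted(_dedup_key(a) for a in recs)
        key = (len(recs) == 1, tuple(keys))
        score = sum(a.mapq for a in recs)
        groups.setdefault(key, []).append((score, rid))

    keep: set[str] = set()
    for members in groups.values():
        members.sort(key=lambda t: (-t[0], t[1]))
        keep.add(members[0][1])

    return [a for a in segments if a.read_id in keep]


def mapping_rate(segments: Iterable[Alignment], n_total_reads: int) -> float:
    """Mapped primary records / total reads (samtools-flagstat style)."""
    if n_total_reads <= 0:
        raise ValueError("n_total_reads must be positive")
    mapped = sum(1 for a in segments if a.is_primary and a.chrom != "*")
    if mapped > n_total_reads:
        raise ValueError("mapped count exceeds total reads")
    return mapped / n_total_reads


# ---------------------------------------------------------------------------
# chimeric (circle-supporting) read extraction


def _pair_orientation(a: Alignment, b: Alignment) -> str:
    """'FR' (convergent), 'RF' (everted) or 'tandem' for same-chrom pairs."""
    if a.is_reverse == b.is_reverse:
        return "tandem"
    fwd, rev = (a, b) if not a.is_reverse else (b, a)
    return "FR" if fwd.start <= rev.start else "RF"


def _is_r2r1(a: Alignment, b: Alignment) -> bool:
    """Tandem pairs with read 2 aligned upstream of read 1 (RCA artifact)."""
    if a.chrom != b.chrom or a.is_reverse != b.is_reverse:
        return False
    r1, r2 = (a, b) if a.is_read1 else (b, a)
    return r2.start < r1.start


def extract_chimeric(
    segments: Sequence[Alignment],
    min_mapq: int = 20,
    insert_threshold: int = 1000,
    remove_r2r1: bool = True,
) -> tuple[list[Alignment], list[tuple[Alignment, Alignment]]]:
    """Split reads and discordant pairs supporting circular templates.

    Split reads are primary records carrying at least one SA descriptor with
    mapq strictly above ``min_mapq``. Discordant pairs are inter-chromosomal,
    orientation-anomalous (everted RF or tandem FF/RR) or long-insert pairs
    with both mates above the mapq cutoff. Pairs matching the R2R1 artifact
    signature (tandem with read 2 upstream) are removed from both sets by
    default.
    """
    split = [
        a
        for a in segments
        if a.is_primary and a.sa_entries and a.mapq > min_mapq and not a.is_duplicate
    ]

    by_id: dict[str, list[Alignment]] = {}
    for a in segments:
        if a.is_primary and not a.is_duplicate:
            by_id.setdefault(a.read_id, []).append(a)

    r2r1_ids: set[str] = set()
    discordant: list[tuple[Alignment, Alignment]] = []
    for rid, recs in by_id.items():
        if len(recs) != 2:
            continue
        a, b = recs
        if a.mapq <= min_mapq or b.mapq <= min_mapq:
            continue
        if remove_r2r1 and _is_r2r1(a, b):
            r2r1_ids.add(rid)
            continue
        if a.chrom != b.chrom:
            discordant.append((a, b))
            continue
        orient = _pair_orientation(a, b)
        span = max(a.end, b.end) - min(a.start, b.start)
        if orient in ("RF", "tandem") or span > insert_threshold:
            discordant.append((a, b))

    if remove_r2r1 and r2r1_ids:
        split = [a for a in split if a.read_id not in r2r1_ids]
    return split, discordant


# ---------------------------------------------------------------------------
# coverage


@dataclass
class CoverageTrack:
    """Binned read counts per contig: each read increments every bin it overlaps."""

    bin_size: int
    contig_lengths: dict[str, int]
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for c, n in self.contig_lengths.items():
            if c not in self.counts:
                self.counts[c] = np.zeros(int(np.ceil(n / self.bin_size)), dtype=np.int64)

    def add(self, chrom: str, start: int, end: int) -> None:
        arr = self.counts[chrom]
        b0 = start // self.bin_size
        b1 = min((end - 1) // self.bin_size, len(arr) - 1)
        arr[b0 : b1 + 1] += 1

    def total(self) -> int:
        return int(sum(arr.sum() for arr in self.counts.values()))


def compute_coverage(
    segments: Iterable[Alignment],
    bin_size: int,
    contig_lengths: dict[str, int],
) -> CoverageTrack:
    """Binned coverage from primary, non-duplicate records."""
    track = CoverageTrack(bin_size=bin_size, contig_lengths=contig_lengths)
    for a in segments:
        if a.is_primary and not a.is_duplicate:
            track.add(a.chrom, a.start, a.end)
    return track
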