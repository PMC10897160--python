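"""Genomic intervals and BED-style interval arithmetic.

All coordinates are 0-based half-open throughout the package; conversion to
1-based SAM coordinates is confined to the alignment readers/writers, and BED
files are written 0-based half-open as usual.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named contig."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """min of the two overlap fractions; 0 when disjoint."""
        ov = self.overlap_len(other)
        if ov == 0:
            return 0.0
        return min(ov / len(self), ov / len(other))


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Union intervals on the same contig that overlap or lie within ``gap`` bp.

    Output is sorted and non-overlapping.
    """
    ivs = sorted(intervals)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end + gap:
            last = out[-1]
            if iv.end > last.end:
                out[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            out.append(iv)
    return out


def union_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))


def jaccard(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> float:
    """Jaccard index |A ∩ B| / |A ∪ B| between two interval sets (in bp)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    inter = sum(x.overlap_len(y) for x in a for y in b)
    union = union_length(list(a) + list(b))
    return inter / union if union else 0.0


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6 into a DataFrame with canonical column names."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def intervals_from_bed(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def intervals_to_bed(
    intervals: Sequence[GenomicInterval],
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
    strands: Sequence[str] | None = None,
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
        }
    )
    if names is not None or scores is not None or strands is not None:
        n = len(intervals)
        df["name"] = list(names) if names is not None else ["."] * n
        df["score"] = list(scores) if scores is not None else [0] * n
        df["strand"] = list(strands) if strands is not None else ["."] * n
    return df
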