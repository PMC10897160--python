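"""Circle-producing region (CPR) calling from binned coverage.

A CPR is a genomic interval whose read coverage is strongly enriched over
the post-digestion background, supported by circle-supporting (split and
discordant) reads. The caller is a simple and fully specified procedure:
threshold runs of enriched bins against a genome-wide quantile background,
merge nearby runs, then refine borders to the outermost bins retaining a
fraction of the region's coverage maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment_io import Alignment, CoverageTrack, compute_coverage, extract_chimeric
from .intervals import GenomicInterval, intervals_to_bed, merge_intervals, write_bed


@dataclass
class CPRParams:
    """Tunable knobs of the CPR caller (bp units unless noted)."""

    bin_size: int = 100
    min_cov: int = 5              # reads per bin floor
    enrichment_factor: float = 4.0
    background_quantile: float = 0.25  # quantile of nonzero bins
    merge_gap: int = 1000
    edge_fraction: float = 0.1
    min_cpr_length: int = 200
    min_mapq: int = 20
    insert_threshold: int = 1000
    excluded_contigs: tuple[str, ...] = ("chrM", "spike_circ", "spike_lin")


@dataclass
class CPR:
    """A called circle-producing region with coverage and support statistics."""

    interval: GenomicInterval
    mean_cov: float = 0.0
    max_cov: float = 0.0
    n_reads: int = 0
    n_circle_reads: int = 0
    junctions: list = field(default_factory=list)
    structure_class: str = "unclassified"

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def call_peaks(
    coverage: CoverageTrack,
    min_cov: float = 5,
    enrichment_factor: float = 4.0,
    background_quantile: float = 0.25,
    excluded_contigs: Sequence[str] = (),
) -> list[GenomicInterval]:
    """Maximal runs of bins with count >= max(min_cov, factor * background).

    The background is the given quantile of nonzero bin counts across all
    non-excluded contigs; with near-zero post-digestion background this is a
    robust floor. All-zero coverage yields an empty list.
    """
    arrays = [
        arr for c, arr in coverage.counts.items() if c not in excluded_contigs
    ]
    nonzero = np.concatenate([a[a > 0] for a in arrays]) if arrays else np.array([])
    if nonzero.size == 0:
        return []
    background = float(np.quantile(nonzero, background_quantile))
    threshold = max(float(min_cov), enrichment_factor * background)

    out: list[GenomicInterval] = []
    for chrom, arr in coverage.counts.items():
        if chrom in excluded_contigs:
            continue
        above = arr >= threshold
        if not above.any():
            continue
        # run boundaries of the boolean mask
        diff = np.diff(above.astype(np.int8))
        starts = np.flatnonzero(diff == 1) + 1
        ends = np.flatnonzero(diff == -1) + 1
        if above[0]:
            starts = np.r_[0, starts]
        if above[-1]:
            ends = np.r_[ends, len(arr)]
        clen = coverage.contig_lengths[chrom]
        for b0, b1 in zip(starts, ends):
            out.append(
                GenomicInterval(
                    chrom,
                    int(b0) * coverage.bin_size,
                    min(int(b1) * coverage.bin_size, clen),
                )
            )
    return sorted(out)


def merge_regions(
    regions: Sequence[GenomicInterval], gap: int = 1000
) -> list[GenomicInterval]:
    """Union intervals on the same contig within ``gap`` bp of each other."""
    return merge_intervals(regions, gap=gap)


def refine_borders(
    regions: Sequence[GenomicInterval],
    coverage: CoverageTrack,
    edge_fraction: float = 0.1,
) -> list[GenomicInterval]:
    """Move each border to the outermost bin holding >= edge_fraction of the max.

    Borders are first pushed outward over any adjacent qualifying bins, then
    pulled inward past sub-threshold edge bins; a region never shrinks past
    the bin holding its coverage maximum.
    """
    bs = coverage.bin_size
    out: list[GenomicInterval] = []
    for iv in regions:
        arr = coverage.counts[iv.chrom]
        b0, b1 = iv.start // bs, min((iv.end - 1) // bs, len(arr) - 1)
        region_max = arr[b0 : b1 + 1].max()
        if region_max <= 0:
            raise ValueError("refine_borders requires positive coverage in region")
        thr = edge_fraction * region_max
        apex = b0 + int(np.argmax(arr[b0 : b1 + 1]))
        while b0 > 0 and arr[b0 - 1] >= thr:
            b0 -= 1
        while b1 < len(arr) - 1 and arr[b1 + 1] >= thr:
            b1 += 1
        while b0 < apex and arr[b0] < thr:
            b0 += 1
        while b1 > apex and arr[b1] < thr:
            b1 -= 1
        clen = coverage.contig_lengths[iv.chrom]
        out.append(GenomicInterval(iv.chrom, b0 * bs, min((b1 + 1) * bs, clen)))
    return merge_intervals(out)


class _OverlapCounter:
    """Counts intervals overlapping a query via sorted start/end arrays.

    For half-open intervals, #(start < E and end > S) equals
    #(start < E) - #(end <= S) because end <= S implies start < E.
    """

    def __init__(self, triples) -> None:
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in triples:
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, pairs in by_chrom.items():
            self._starts[chrom] = np.sort(np.array([p[0] for p in pairs]))
            self._ends[chrom] = np.sort(np.array([p[1] for p in pairs]))

    def count(self, iv: GenomicInterval) -> int:
        if iv.chrom not in self._starts:
            return 0
        n_start = int(np.searchsorted(self._starts[iv.chrom], iv.end, side="left"))
        n_end = int(np.searchsorted(self._ends[iv.chrom], iv.start, side="right"))
        return n_start - n_end


def detect_cprs(
    segments: Sequence[Alignment],
    contig_lengths: dict[str, int],
    params: CPRParams | None = None,
    coverage: CoverageTrack | None = None,
) -> tuple[list[CPR], CoverageTrack]:
    """Full per-sample CPR calling on deduplicated alignments.

    Returns the called CPRs (sorted, length >= min_cpr_length, with coverage
    statistics and circle-supporting read counts) along with the binned
    coverage track used for calling. Junction objects are attached downstream
    by the junctions module.
    """
    params = params or CPRParams()
    if not segments:
        raise ValueError("empty alignment input")
    if coverage is None:
        coverage = compute_coverage(segments, params.bin_size, contig_lengths)
    peaks = call_peaks(
        coverage,
        min_cov=params.min_cov,
        enrichment_factor=params.enrichment_factor,
        background_quantile=params.background_quantile,
        excluded_contigs=params.excluded_contigs,
    )
    merged = merge_regions(peaks, gap=params.merge_gap)
    refined = refine_borders(merged, coverage, edge_fraction=params.edge_fraction)
    refined = [iv for iv in refined if len(iv) >= params.min_cpr_length]

    split, discordant = extract_chimeric(
        segments,
        min_mapq=params.min_mapq,
        insert_threshold=params.insert_threshold,
    )
    circle_ivs: list[GenomicInterval] = [a.interval() for a in split]
    for a, b in discordant:
        circle_ivs.append(a.interval())
        circle_ivs.append(b.interval())

    all_idx = _OverlapCounter(
        (a.chrom, a.start, a.end)
        for a in segments
        if a.is_primary and not a.is_duplicate
    )
    circle_idx = _OverlapCounter((iv.chrom, iv.start, iv.end) for iv in circle_ivs)

    cprs: list[CPR] = []
    bs = coverage.bin_size
    for iv in refined:
        arr = coverage.counts[iv.chrom]
        b0, b1 = iv.start // bs, min((iv.end - 1) // bs, len(arr) - 1)
        window = arr[b0 : b1 + 1]
        n_reads = all_idx.count(iv)
        n_circle = circle_idx.count(iv)
        cprs.append(
            CPR(
                interval=iv,
                mean_cov=float(window.mean()),
                max_cov=float(window.max()),
                n_reads=n_reads,
                n_circle_reads=min(n_circle, n_reads),
            )
        )
    return cprs, coverage


def write_cpr_bed(cprs: Sequence[CPR], path: str | Path) -> None:
    df = intervals_to_bed(
        [c.interval for c in cprs],
        names=[f"CPR_{i + 1}" for i in range(len(cprs))],
        scores=[c.n_circle_reads for c in cprs],
        strands=["."] * len(cprs),
    )
    write_bed(df, path)


def cprs_to_table(cprs: Sequence[CPR]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in cprs],
            "start": [c.start for c in cprs],
            "end": [c.end for c in cprs],
            "length": [len(c.interval) for c in cprs],
            "mean_cov": [c.mean_cov for c in cprs],
            "max_cov": [c.max_cov for c in cprs],
            "n_reads": [c.n_reads for c in cprs],
            "n_circle_reads": [c.n_circle_reads for c in cprs],
            "structure_class": [c.structure_class for c in cprs],
        }
    )
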