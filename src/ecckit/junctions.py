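"""Chimeric junction extraction, clustering and CPR structure classification.

A chimeric junction is the novel adjacency created when a circle closes:
split reads align in two pieces (primary + supplementary) whose clipped ends
point at the two joined genomic positions. Raw per-read junctions are
clustered by single linkage (both breakends within a window) and clusters
below the read-support floor are discarded; the retained junctions classify
each CPR as simple (junctions only joining its extremities) or complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment_io import Alignment, SAEntry, clip_lengths, reference_span
from .cpr_detect import CPR
from .intervals import GenomicInterval

LEFT = "left"    # clip on the left of the aligned piece: partner joined before pos
RIGHT = "right"  # clip on the right: partner joined after pos


@dataclass(frozen=True)
class Breakend:
    """One side of a junction: the base adjacent to the novel adjacency."""

    chrom: str
    pos: int
    side: str        # LEFT or RIGHT clip on the evidence alignment
    partner_strand: str = "+"

    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class ChimericJunction:
    """A clustered junction with read support and span classification."""

    a: Breakend
    b: Breakend
    support: int
    span_class: str = "unassigned"  # edge-joining | internal | distal-intra | inter-chromosomal
    cpr_ids: list[int] = field(default_factory=list)


def _canonical(a: Breakend, b: Breakend) -> tuple[Breakend, Breakend]:
    return (a, b) if (a.chrom, a.pos) <= (b.chrom, b.pos) else (b, a)


def extract_junction_endpoints(
    split_reads: Sequence[Alignment],
) -> list[tuple[Breakend, Breakend]]:
    """Raw breakend pairs, one per primary/supplementary alignment pair.

    For a primary alignment right-clipped at reference end ``e`` whose
    supplementary piece starts at ``s`` on the same strand, the junction is
    (right-clip @ e) -- (left-clip @ s); left-clipped primaries and
    opposite-strand supplementaries are handled symmetrically.
    """
    out: list[tuple[Breakend, Breakend]] = []
    for read in split_reads:
        if not read.sa_entries:
            raise ValueError(f"read {read.read_id} has no supplementary descriptor")
        lead, trail = clip_lengths(read.cigar)
        for sa in read.sa_entries:
            same_strand = (sa.strand == "-") == read.is_reverse
            sa_lead, sa_trail = clip_lengths(sa.cigar)
            # pick the primary clip side that the supplementary piece explains:
            # larger clip wins when both sides are clipped
            if trail >= lead:
                prim = Breakend(read.chrom, read.end, RIGHT, sa.strand)
                if same_strand:
                    supp = Breakend(sa.chrom, sa.pos, LEFT, read.strand)
                else:
                    supp = Breakend(
                        sa.chrom, sa.pos + reference_span(sa.cigar), RIGHT, read.strand
                    )
            else:
                prim = Breakend(read.chrom, read.start, LEFT, sa.strand)
                if same_strand:
                    supp = Breakend(
                        sa.chrom, sa.pos + reference_span(sa.cigar), RIGHT, read.strand
                    )
                else:
                    supp = Breakend(sa.chrom, sa.pos, LEFT, read.strand)
            out.append(_canonical(prim, supp))
    return out


def _weighted_median(values: Sequence[int], weights: Sequence[int] | None = None) -> int:
    """Smallest value whose cumulative weight reaches half the total."""
    vals = np.asarray(values)
    w = np.ones_like(vals) if weights is None else np.asarray(weights)
    order = np.argsort(vals, kind="stable")
    vals, w = vals[order], w[order]
    cum = np.cumsum(w)
    idx = int(np.searchsorted(cum, cum[-1] / 2.0, side="left"))
    return int(vals[idx])


def cluster_junctions(
    raw: Sequence[tuple[Breakend, Breakend]],
    cprs: Sequence[CPR] = (),
    window: int = 500,
    min_support: int = 2,
) -> list[ChimericJunction]:
    """Single-linkage clustering of raw junctions; support floor applied.

    Two raw junctions link when both paired breakends lie within ``window``
    bp of one another (matching ends on matching chromosomes). Cluster
    representatives are per-end support-weighted medians. Clusters with fewer
    than ``min_support`` reads are discarded. Surviving junctions are
    assigned to the CPRs containing their breakends and span-classified by
    :func:`assign_span_class`.
    """
    items = [( _canonical(a, b)) for a, b in raw]
    n = len(items)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # group by chromosome pair, then sweep on the first breakend position
    groups: dict[tuple[str, str], list[int]] = {}
    for idx, (a, b) in enumerate(items):
        groups.setdefault((a.chrom, b.chrom), []).append(idx)
    for idxs in groups.values():
        idxs.sort(key=lambda i: items[i][0].pos)
        for ii, i in enumerate(idxs):
            ai, bi = items[i]
            for j in idxs[ii + 1 :]:
                aj, bj = items[j]
                if aj.pos - ai.pos > window:
                    break
                if abs(bj.pos - bi.pos) <= window:
                    union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    out: list[ChimericJunction] = []
    for members in clusters.values():
        if len(members) < min_support:
            continue
        a_pos = _weighted_median([items[i][0].pos for i in members])
        b_pos = _weighted_median([items[i][1].pos for i in members])
        a0, b0 = items[members[0]]
        a = Breakend(a0.chrom, a_pos, a0.side, a0.partner_strand)
        b = Breakend(b0.chrom, b_pos, b0.side, b0.partner_strand)
        out.append(ChimericJunction(a=a, b=b, support=len(members)))
    out.sort(key=lambda j: (j.a.chrom, j.a.pos, j.b.chrom, j.b.pos))

    if cprs:
        assign_to_cprs(out, cprs)
    return out


def assign_to_cprs(
    junctions: Sequence[ChimericJunction],
    cprs: Sequence[CPR],
    window: int = 500,
    distal_threshold: int = 1_000_000,
) -> None:
    """Attach junctions to CPRs containing their breakends and classify span."""
    for c in cprs:
        c.junctions = []
    for j in junctions:
        j.cpr_ids = []
        for idx, c in enumerate(cprs):
            iv = c.interval
            a_in = j.a.chrom == iv.chrom and iv.start - window <= j.a.pos <= iv.end + window
            b_in = j.b.chrom == iv.chrom and iv.start - window <= j.b.pos <= iv.end + window
            if a_in and b_in:
                j.cpr_ids.append(idx)
                c.junctions.append(j)
        j.span_class = assign_span_class(j, cprs, window=window, distal_threshold=distal_threshold)


def assign_span_class(
    junction: ChimericJunction,
    cprs: Sequence[CPR],
    window: int = 500,
    distal_threshold: int = 1_000_000,
) -> str:
    """Span class: edge-joining, internal, distal-intra or inter-chromosomal."""
    a, b = junction.a, junction.b
    if a.chrom != b.chrom:
        return "inter-chromosomal"
    for idx in junction.cpr_ids:
        iv = cprs[idx].interval
        if (
            abs(a.pos - iv.start) <= window
            and abs(b.pos - iv.end) <= window
        ):
            return "edge-joining"
    if junction.cpr_ids:
        return "internal"
    if b.pos - a.pos > distal_threshold:
        return "distal-intra"
    return "internal"


def classify_cpr_structure(
    cpr: CPR,
    edge_window: int = 500,
    max_simple_junctions: int = 2,
) -> str:
    """simple = all junctions join the CPR extremities; complex otherwise.

    A CPR with no junction is unclassified. More than ``max_simple_junctions``
    distinct junctions, or any non-edge junction, makes it complex.
    """
    if not cpr.junctions:
        return "unclassified"
    if len(cpr.junctions) > max_simple_junctions:
        return "complex"
    iv = cpr.interval
    for j in cpr.junctions:
        edge = (
            j.a.chrom == iv.chrom
            and j.b.chrom == iv.chrom
            and abs(j.a.pos - iv.start) <= edge_window
            and abs(j.b.pos - iv.end) <= edge_window
        )
        if not edge:
            return "complex"
    return "simple"


def junction_span_fractions(
    junctions: Sequence[ChimericJunction],
    distal_threshold: int = 1_000_000,
) -> dict[str, float]:
    """Fractions of local (edge+internal), distal-intra and inter junctions."""
    if not junctions:
        raise ValueError("no junctions")
    n = len(junctions)
    counts = {"local": 0, "distal-intra": 0, "inter-chromosomal": 0}
    for j in junctions:
        if j.a.chrom != j.b.chrom:
            counts["inter-chromosomal"] += 1
        elif not j.cpr_ids and j.b.pos - j.a.pos > distal_threshold:
            counts["distal-intra"] += 1
        else:
            counts["local"] += 1
    return {k: v / n for k, v in counts.items()}


def junctions_to_bedpe(junctions: Sequence[ChimericJunction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom1": [j.a.chrom for j in junctions],
            "start1": [j.a.pos for j in junctions],
            "end1": [j.a.pos + 1 for j in junctions],
            "chrom2": [j.b.chrom for j in junctions],
            "start2": [j.b.pos for j in junctions],
            "end2": [j.b.pos + 1 for j in junctions],
            "name": [f"J{i + 1}_{j.span_class}" for i, j in enumerate(junctions)],
            "support": [j.support for j in junctions],
            "strand1": [j.a.partner_strand for j in junctions],
            "strand2": [j.b.partner_strand for j in junctions],
        }
    )


def write_bedpe(junctions: Sequence[ChimericJunction], path: str | Path) -> None:
    junctions_to_bedpe(junctions).to_csv(path, sep="\t", header=False, index=False)
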