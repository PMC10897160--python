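"""Alignment-level simulator of single-cell circular-DNA sequencing data.

Generates a synthetic genome (main contigs, a mitochondrial surrogate, and
circular/linear spike-in contigs), plants simple and complex eccDNA circles
in each cell, and writes per-cell coordinate-sorted SAM files that emulate
rolling-circle-amplified paired-end sequencing:

* read pairs are drawn uniformly around the circular template (positions
  uniform modulo circle length, pair counts Poisson with mean
  ``length * depth / (2 * read_length)``, scaled by a per-circle lognormal
  amplification factor);
* a read crossing the circle junction is emitted as a soft-clipped primary
  alignment plus a supplementary record with a correct SA descriptor;
* a pair straddling the junction comes out in everted (RF) orientation;
* linear background, mitochondrial and spike-in reads complete the assay.

Ground truth (planted circles, per-cell amplification) is written as JSON so
every downstream module can be validated against it.
"""

from __future__ import annotations

import hashlib
import json
from bisect import bisect_right
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment_io import Alignment, SAEntry, write_alignments
from .intervals import GenomicInterval

_BASES = np.array(list("ACGT"))


@dataclass
class SimDesign:
    """Study conditions of a simulated population (bp and x-coverage units)."""

    main_contigs: dict[str, int] = field(
        default_factory=lambda: {"chr1": 600_000, "chr2": 400_000}
    )
    mito_contig: str = "chrM"
    mito_length: int = 16_000
    spike_circ_contig: str = "spike_circ"
    spike_lin_contig: str = "spike_lin"
    spike_length: int = 2_000
    gc_content: float = 0.41

    n_cells: int = 20
    singletons_per_cell: int = 50
    circle_len_min: int = 1_000
    circle_len_max: int = 4_000
    min_spacing: int = 2_000          # planted circles keep this distance apart
    recurrent_fraction: float = 0.0   # fraction of cells carrying the recurrent circle
    recurrent_length: int = 10_000
    recurrent_jitter: float = 0.0     # border jitter as a fraction of circle length
    complex_per_cell: int = 0
    complex_segments_max: int = 4
    complex_cross_contig: bool = True

    circle_depth: float = 30.0
    background_depth: float = 0.1
    mito_depth: float = 30.0
    spike_circ_depth: float = 30.0
    spike_lin_depth: float = 0.3
    rca_sigma: float = 0.5            # lognormal amplification spread (unit mean)

    read_length: int = 150
    insert_mean: float = 300.0
    insert_sd: float = 50.0
    error_rate: float = 0.001
    min_clip: int = 20                # shorter overhangs stay soft-clip only
    seed: int = 0

    def contig_lengths(self) -> dict[str, int]:
        out = dict(self.main_contigs)
        out[self.mito_contig] = self.mito_length
        out[self.spike_circ_contig] = self.spike_length
        out[self.spike_lin_contig] = self.spike_length
        return out


@dataclass
class CircleTruth:
    """One planted circle: ordered segments plus the carrying cells."""

    circle_id: str
    segments: list[tuple[str, int, int, str]]
    cells: dict[str, dict]  # cell_id -> {"copy": float, "segments": [...]}
    structure_class: str    # simple | complex

    @property
    def length(self) -> int:
        return sum(e - s for _, s, e, _ in self.segments)

    def cell_segments(self, cell_id: str) -> list[tuple[str, int, int, str]]:
        entry = self.cells[cell_id]
        return [tuple(s) for s in entry.get("segments", self.segments)]

    def cell_intervals(self, cell_id: str) -> list[GenomicInterval]:
        return [
            GenomicInterval(c, s, e) for c, s, e, _ in self.cell_segments(cell_id)
        ]


# ---------------------------------------------------------------------------
# genome


def make_genome(design: SimDesign, seed: int | None = None) -> dict[str, str]:
    """Random genome with the designed GC content; deterministic per seed."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    gc = design.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome: dict[str, str] = {}
    for contig, length in design.contig_lengths().items():
        if length < 1000:
            raise ValueError(f"contig {contig} too small ({length} bp)")
        genome[contig] = "".join(_BASES[rng.choice(4, size=length, p=p)])
    return genome


def write_genome(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for contig, seq in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    with open(str(path) + ".fai", "w") as fai:
        offset = 0
        for contig, seq in genome.items():
            offset += len(contig) + 2
            n = len(seq)
            n_lines = (n + width - 1) // width
            fai.write(f"{contig}\t{n}\t{offset}\t{width}\t{width + 1}\n")
            offset += n + n_lines


# ---------------------------------------------------------------------------
# circle placement


class _Placer:
    """Rejection sampler for non-overlapping intervals with a spacing buffer."""

    def __init__(self, contig_lengths: dict[str, int], spacing: int, rng) -> None:
        self.lengths = contig_lengths
        self.spacing = spacing
        self.rng = rng
        self.occupied: dict[str, list[tuple[int, int]]] = {
            c: [] for c in contig_lengths
        }
        self.contigs = list(contig_lengths)
        w = np.array([contig_lengths[c] for c in self.contigs], dtype=float)
        self.weights = w / w.sum()

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.occupied[chrom].append((start, end))
        self.occupied[chrom].sort()

    def _fits(self, chrom: str, start: int, end: int) -> bool:
        for s, e in self.occupied[chrom]:
            if start < e + self.spacing and s < end + self.spacing:
                return False
        return True

    def place(self, length: int, chrom: str | None = None, max_tries: int = 2000):
        for _ in range(max_tries):
            c = chrom or self.rng.choice(self.contigs, p=self.weights)
            limit = self.lengths[c] - length
            if limit <= 0:
                continue
            start = int(self.rng.integers(0, limit))
            if self._fits(c, start, start + length):
                self.reserve(c, start, start + length)
                return c, start, start + length
        raise RuntimeError("genome too small for the requested non-overlapping placement")


def plant_circles(design: SimDesign, seed: int | None = None) -> list[CircleTruth]:
    """Plant recurrent, complex and singleton circles per the design."""
    rng = np.random.default_rng(
        np.random.SeedSequence([design.seed if seed is None else seed, 1])
    )
    cells = [f"cell_{i:03d}" for i in range(design.n_cells)]
    truths: list[CircleTruth] = []
    placers = {
        cell: _Placer(design.main_contigs, design.min_spacing, rng) for cell in cells
    }

    def copy_factor() -> float:
        if design.rca_sigma <= 0:
            return 1.0
        return float(
            rng.lognormal(mean=-design.rca_sigma**2 / 2, sigma=design.rca_sigma)
        )

    # recurrent circle: one locus shared by a designed fraction of cells
    if design.recurrent_fraction > 0:
        n_carry = int(round(design.recurrent_fraction * design.n_cells))
        big = max(design.main_contigs, key=design.main_contigs.get)
        L = design.recurrent_length
        start = int(rng.integers(0, design.main_contigs[big] - L))
        carriers = sorted(rng.choice(cells, size=n_carry, replace=False))
        # keep every cell's singletons clear of the recurrent locus
        for p in placers.values():
            p.reserve(big, start, start + L)
        entry_cells: dict[str, dict] = {}
        for cell in carriers:
            seg = [big, start, start + L, "+"]
            if design.recurrent_jitter > 0:
                j = design.recurrent_jitter * L / 2
                s2 = start + int(rng.uniform(-j, j))
                e2 = start + L + int(rng.uniform(-j, j))
                s2 = max(0, s2)
                e2 = min(design.main_contigs[big], max(e2, s2 + design.circle_len_min))
                seg = [big, s2, e2, "+"]
            entry_cells[cell] = {"copy": copy_factor(), "segments": [seg]}
        truths.append(
            CircleTruth(
                circle_id="recurrent_0",
                segments=[(big, start, start + L, "+")],
                cells=entry_cells,
                structure_class="simple",
            )
        )

    for cell in cells:
        placer = placers[cell]
        for k in range(design.complex_per_cell):
            n_seg = int(rng.integers(2, design.complex_segments_max + 1))
            segs = []
            first_contig = None
            for si in range(n_seg):
                length = int(rng.integers(design.circle_len_min, design.circle_len_max + 1))
                chrom = None
                if not design.complex_cross_contig and first_contig is not None:
                    chrom = first_contig
                c, s, e = placer.place(length, chrom=chrom)
                first_contig = first_contig or c
                segs.append((c, s, e, "+"))
            truths.append(
                CircleTruth(
                    circle_id=f"{cell}_complex_{k}",
                    segments=segs,
                    cells={cell: {"copy": copy_factor()}},
                    structure_class="complex",
                )
            )
        for k in range(design.singletons_per_cell):
            length = int(rng.integers(design.circle_len_min, design.circle_len_max + 1))
            c, s, e = placer.place(length)
            truths.append(
                CircleTruth(
                    circle_id=f"{cell}_singleton_{k}",
                    segments=[(c, s, e, "+")],
                    cells={cell: {"copy": copy_factor()}},
                    structure_class="simple",
                )
            )
    return truths


# ---------------------------------------------------------------------------
# read generation


def _apply_errors(seq: str, rng, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        current = chars[pos]
        options = [b for b in "ACGT" if b != current]
        chars[pos] = options[int(rng.integers(3))]
    return "".join(chars)


def _circle_pieces(
    a: int, read_len: int, segs: Sequence[tuple[str, int, int, str]], cum: list[int], L: int
) -> list[tuple[str, int, int, int]]:
    """Split a circle-coordinate read [a, a+read_len) into genomic pieces.

    Returns (chrom, genome_start, length, read_offset) per maximal piece.
    """
    pieces = []
    pos = a % L
    remaining = read_len
    offset = 0
    while remaining > 0:
        si = bisect_right(cum, pos) - 1
        chrom, s, e, _ = segs[si]
        within = pos - cum[si]
        take = min(remaining, (e - s) - within)
        pieces.append((chrom, s + within, take, offset))
        pos = (pos + take) % L
        remaining -= take
        offset += take
    return pieces


def _reads_for_circle(
    cell_id: str,
    prefix: str,
    segs: Sequence[tuple[str, int, int, str]],
    genome: dict[str, str],
    n_pairs: int,
    design: SimDesign,
    rng,
    circular: bool = True,
) -> list[Alignment]:
    R = design.read_length
    lens = [e - s for _, s, e, _ in segs]
    L = sum(lens)
    cum = [0]
    for ln in lens[:-1]:
        cum.append(cum[-1] + ln)
    circle_seq = "".join(genome[c][s:e] for c, s, e, _ in segs)
    records: list[Alignment] = []

    for k in range(n_pairs):
        F = int(round(rng.normal(design.insert_mean, design.insert_sd)))
        F = max(R, min(F, L))
        if circular:
            u = int(rng.integers(L))
        else:
            if L - F <= 0:
                u = 0
            else:
                u = int(rng.integers(L - F))
        read_coords = [(u, False), ((u + F - R) % L if circular else u + F - R, True)]
        flip = bool(rng.random() < 0.5)
        rid = f"{cell_id}|{prefix}|{k}"
        mate_records: list[list[Alignment]] = []
        for role, (a, is_rev) in enumerate(read_coords):
            seq = (
                circle_seq[a : a + R]
                if a + R <= L
                else circle_seq[a:] + circle_seq[: (a + R) % L]
            )
            seq = _apply_errors(seq, rng, design.error_rate)
            pieces = _circle_pieces(a, R, segs, cum, L)
            primary_idx = max(range(len(pieces)), key=lambda i: pieces[i][2])
            recs: list[Alignment] = []
            kept = [
                i
                for i in range(len(pieces))
                if pieces[i][2] >= design.min_clip or i == primary_idx
            ]
            for i in kept:
                chrom, gs, ln, off = pieces[i]
                cigar = ""
                if off:
                    cigar += f"{off}S"
                cigar += f"{ln}M"
                if R - off - ln:
                    cigar += f"{R - off - ln}S"
                recs.append(
                    Alignment(
                        read_id=rid,
                        is_read1=(role == 0) != flip,
                        chrom=chrom,
                        start=gs,
                        cigar=cigar,
                        mapq=60,
                        is_reverse=is_rev,
                        is_supplementary=(i != primary_idx),
                        seq=seq,
                    )
                )
            # SA tags cross-reference the other pieces of this read
            if len(recs) > 1:
                for r in recs:
                    r.sa_entries = [
                        SAEntry(o.chrom, o.start, r.strand, o.cigar, o.mapq, 0)
                        for o in recs
                        if o is not r
                    ]
            mate_records.append(recs)

        p0 = next(r for r in mate_records[0] if not r.is_supplementary)
        p1 = next(r for r in mate_records[1] if not r.is_supplementary)
        same = p0.chrom == p1.chrom
        span = (
            max(p0.end, p1.end) - min(p0.start, p1.start) if same else 0
        )
        proper = same and span <= 1000 and p0.start <= p1.start
        for recs, mate in ((mate_records[0], p1), (mate_records[1], p0)):
            for r in recs:
                r.is_paired = True
                r.mate_chrom = mate.chrom
                r.mate_start = mate.start
                r.mate_is_reverse = mate.is_reverse
                r.is_proper_pair = proper
                if same:
                    if r.start <= mate.start:
                        r.insert_size = span
                    else:
                        r.insert_size = -span
        records.extend(mate_records[0])
        records.extend(mate_records[1])
    return records


def _n_pairs(rng, length: int, depth: float, read_length: int) -> int:
    return int(rng.poisson(length * depth / (2 * read_length)))


def generate_cell_alignments(
    cell_id: str,
    truths: Sequence[CircleTruth],
    genome: dict[str, str],
    design: SimDesign,
    rng,
) -> list[Alignment]:
    """All records of one cell: circles, mtDNA, spike-ins, linear background."""
    records: list[Alignment] = []
    for t in truths:
        if cell_id not in t.cells:
            continue
        segs = t.cell_segments(cell_id)
        L = sum(e - s for _, s, e, _ in segs)
        mult = t.cells[cell_id].get("copy", 1.0)
        n = _n_pairs(rng, L, design.circle_depth * mult, design.read_length)
        records.extend(
            _reads_for_circle(cell_id, t.circle_id, segs, genome, n, design, rng)
        )
    # mitochondrial surrogate and circular spike-in: whole-contig circles
    for contig, depth, tag in (
        (design.mito_contig, design.mito_depth, "mito"),
        (design.spike_circ_contig, design.spike_circ_depth, "spike_circ"),
    ):
        L = len(genome[contig])
        n = _n_pairs(rng, L, depth, design.read_length)
        records.extend(
            _reads_for_circle(
                cell_id, tag, [(contig, 0, L, "+")], genome, n, design, rng
            )
        )
    # linear spike-in and residual linear background
    L = len(genome[design.spike_lin_contig])
    n = _n_pairs(rng, L, design.spike_lin_depth, design.read_length)
    records.extend(
        _reads_for_circle(
            cell_id,
            "spike_lin",
            [(design.spike_lin_contig, 0, L, "+")],
            genome,
            n,
            design,
            rng,
            circular=False,
        )
    )
    if design.background_depth > 0:
        for contig, clen in design.main_contigs.items():
            n = _n_pairs(rng, clen, design.background_depth, design.read_length)
            records.extend(
                _reads_for_circle(
                    cell_id,
                    f"bg_{contig}",
                    [(contig, 0, clen, "+")],
                    genome,
                    n,
                    design,
                    rng,
                    circular=False,
                )
            )
    return records


# ---------------------------------------------------------------------------
# population orchestration


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def truth_to_json(truths: Sequence[CircleTruth]) -> list[dict]:
    return [
        {
            "circle_id": t.circle_id,
            "structure_class": t.structure_class,
            "segments": [list(s) for s in t.segments],
            "cells": t.cells,
        }
        for t in truths
    ]


def truth_from_json(data: list[dict]) -> list[CircleTruth]:
    return [
        CircleTruth(
            circle_id=d["circle_id"],
            segments=[tuple(s) for s in d["segments"]],
            cells=d["cells"],
            structure_class=d["structure_class"],
        )
        for d in data
    ]


def simulate_population(
    design: SimDesign, out_dir: str | Path, force: bool = False
) -> dict:
    """Write genome, per-cell SAMs, truth/design JSON and a checksum manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)

    genome = make_genome(design)
    write_genome(genome, out / "genome.fa")
    truths = plant_circles(design)
    contig_lengths = design.contig_lengths()

    cells = [f"cell_{i:03d}" for i in range(design.n_cells)]
    read_counts: dict[str, int] = {}
    for i, cell in enumerate(cells):
        rng = np.random.default_rng(np.random.SeedSequence([design.seed, 2, i]))
        records = generate_cell_alignments(cell, truths, genome, design, rng)
        write_alignments(records, out / f"{cell}.sam", contig_lengths)
        read_counts[cell] = sum(1 for r in records if r.is_primary)

    with open(out / "truth.json", "w") as fh:
        json.dump(truth_to_json(truths), fh, indent=1, sort_keys=True)
    with open(out / "design.json", "w") as fh:
        json.dump(asdict(design), fh, indent=1, sort_keys=True)

    manifest = {
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.name != "manifest.json"
        },
        "read_counts": read_counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# canned designs


def default_design(seed: int = 0, **overrides) -> SimDesign:
    """Detection-benchmark conditions: 20 cells, 1 Mb, 50 singletons/cell."""
    return SimDesign(seed=seed, **overrides)


def classification_design(
    seed: int = 0,
    recurrent_fraction: float = 0.9,
    recurrent_jitter: float = 0.0,
    singletons_per_cell: int = 10,
    **overrides,
) -> SimDesign:
    """One recurrent circle in most cells plus sparse singletons."""
    return SimDesign(
        seed=seed,
        recurrent_fraction=recurrent_fraction,
        recurrent_jitter=recurrent_jitter,
        singletons_per_cell=singletons_per_cell,
        **overrides,
    )


def translocation_design(seed: int = 0, **overrides) -> SimDesign:
    """Complex multi-segment, cross-contig circles (stress-like conditions)."""
    overrides.setdefault("complex_per_cell", 5)
    overrides.setdefault("singletons_per_cell", 10)
    return SimDesign(seed=seed, **overrides)


def simulate_topic_matrix(
    n_groups: int = 3,
    cells_per_group: int = 20,
    bins_per_group: int = 40,
    reads_per_cell: int = 200,
    noise: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Planted-partition cells-by-bins count matrix for topic-model benchmarks.

    Each group draws (1 - noise) of its reads uniformly from its own disjoint
    bin block and the rest uniformly from all bins. Returns the count matrix
    (cells x bins) and the true group label per cell.
    """
    rng = np.random.default_rng(seed)
    n_bins = n_groups * bins_per_group
    n_cells = n_groups * cells_per_group
    counts = np.zeros((n_cells, n_bins), dtype=np.int64)
    labels = np.repeat(np.arange(n_groups), cells_per_group)
    for i, g in enumerate(labels):
        p = np.full(n_bins, noise / n_bins)
        block = slice(g * bins_per_group, (g + 1) * bins_per_group)
        p[block] += (1 - noise) / bins_per_group
        counts[i] = rng.multinomial(reads_per_cell, p)
    df = pd.DataFrame(
        counts,
        index=[f"cell_{i:03d}" for i in range(n_cells)],
        columns=[f"bin_{j:04d}" for j in range(n_bins)],
    )
    return df, labels
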