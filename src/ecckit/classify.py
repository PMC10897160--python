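"""Pseudo-bulk CPR classification by frequency and uniformity.

For every CPR ``j`` called on the pooled (pseudo-bulk) alignments of a cell
population, two quantities are computed across the ``N_tot`` single cells:

* frequency of occurrence ``f_raw = N_pos / N_tot``, where a cell counts as
  positive when one of its own CPRs covers at least ``min_overlap`` (default
  10%) of the pseudo-bulk CPR's length;
* mean uniformity ``j_raw``: the average over all cells of the Jaccard index
  between the pseudo-bulk CPR and the union of that cell's overlapping CPRs
  (cells without overlap contribute 0).

Both are normalized to the corresponding mitochondrial references ``f_mt``
and ``J_mt`` (values above 1 are capped at 1), multiplied into a uniformity
score ``U = f_norm * j_norm``, and thresholded into the four quadrants
HFHU / HFLU / LFHU / LFLU (high/low frequency x high/low uniformity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .alignment_io import Alignment
from .cpr_detect import CPR, CPRParams, detect_cprs
from .intervals import GenomicInterval, jaccard


@dataclass
class CellProfile:
    """Per-cell inputs to classification: the cell's CPRs and mito status."""

    cell_id: str
    cprs: list[CPR] = field(default_factory=list)
    mito_reads: int = 0
    qc: dict = field(default_factory=dict)
    pass_qc: bool = True

    def intervals(self) -> list[GenomicInterval]:
        return [c.interval for c in self.cprs]


@dataclass
class ClassifyParams:
    min_overlap: float = 0.10     # cell-positivity overlap fraction of the pseudo-bulk CPR
    f_threshold: float = 0.65
    u_threshold: float = 0.30
    use_f_norm: bool = True       # threshold f_norm (default) rather than f_raw
    min_mito_reads: int = 10


@dataclass
class ClassificationRecord:
    """All per-pseudo-bulk-CPR classification quantities."""

    cpr: CPR
    n_pos: int
    n_tot: int
    f_raw: float
    j_raw: float
    f_mt: float
    j_mt: float
    f_norm: float
    j_norm: float
    u: float
    label: str


def build_pseudobulk(
    cell_alignments: Sequence[Sequence[Alignment]],
    contig_lengths: dict[str, int],
    params: CPRParams | None = None,
) -> list[CPR]:
    """Re-run CPR calling on the pooled alignments of all passing cells."""
    pooled: list[Alignment] = []
    for segs in cell_alignments:
        pooled.extend(segs)
    if not pooled:
        raise ValueError("empty pseudo-bulk pool")
    cprs, _ = detect_cprs(pooled, contig_lengths, params=params)
    return cprs


def cpr_frequency(
    pseudo_cpr: CPR | GenomicInterval,
    cell_profiles: Sequence[CellProfile],
    min_overlap: float = 0.10,
) -> tuple[float, int, int]:
    """(f_raw, N_pos, N_tot): fraction of cells with a >=10%-overlapping circle."""
    iv = pseudo_cpr.interval if isinstance(pseudo_cpr, CPR) else pseudo_cpr
    if not cell_profiles:
        raise ValueError("no cells profiled")
    n_tot = len(cell_profiles)
    n_pos = 0
    for cell in cell_profiles:
        # a cell is positive when at least one of its circles covers
        # >= min_overlap of the pseudo-bulk CPR length
        if any(
            civ.overlap_len(iv) >= min_overlap * len(iv) for civ in cell.intervals()
        ):
            n_pos += 1
    return n_pos / n_tot, n_pos, n_tot


def cpr_uniformity(
    pseudo_cpr: CPR | GenomicInterval,
    cell_profiles: Sequence[CellProfile],
) -> float:
    """Mean over cells of the Jaccard index with each cell's overlapping circles."""
    iv = pseudo_cpr.interval if isinstance(pseudo_cpr, CPR) else pseudo_cpr
    if not cell_profiles:
        raise ValueError("no cells profiled")
    total = 0.0
    for cell in cell_profiles:
        overlapping = [civ for civ in cell.intervals() if civ.overlaps(iv)]
        if overlapping:
            total += jaccard([iv], overlapping)
    return total / len(cell_profiles)


def normalize_to_mito(
    f_raw: float, j_raw: float, f_mt: float, j_mt: float
) -> tuple[float, float]:
    """Divide by the mitochondrial references and cap at 1."""
    if f_mt <= 0 or j_mt <= 0:
        raise ValueError(
            "mitochondrial reference missing: f_mt and J_mt must be positive"
        )
    return min(1.0, f_raw / f_mt), min(1.0, j_raw / j_mt)


def uniformity_score(f_norm: float, j_norm: float) -> float:
    return f_norm * j_norm


def classify_cpr(
    f: float, u: float, f_threshold: float = 0.65, u_threshold: float = 0.30
) -> str:
    """Quadrant label from strict thresholds on frequency and uniformity score."""
    hf = f > f_threshold
    hu = u > u_threshold
    return ("HF" if hf else "LF") + ("HU" if hu else "LU")


def mito_references(
    cell_profiles: Sequence[CellProfile], min_mito_reads: int = 10
) -> tuple[float, float]:
    """f_mt and J_mt from treating the mito contig as a pseudo-CPR per cell.

    A cell carries the mitochondrial pseudo-circle when it has at least
    ``min_mito_reads`` mito-mapped reads; the per-cell Jaccard with the
    population-level mito pseudo-CPR is then 1 (same full-contig interval).
    """
    present = sum(1 for c in cell_profiles if c.mito_reads >= min_mito_reads)
    frac = present / len(cell_profiles)
    return frac, frac


def classify_population(
    cell_profiles: Sequence[CellProfile],
    pseudo_cprs: Sequence[CPR],
    params: ClassifyParams | None = None,
) -> list[ClassificationRecord]:
    """One classification record per pseudo-bulk CPR (deterministic)."""
    params = params or ClassifyParams()
    cells = [c for c in cell_profiles if c.pass_qc]
    if not cells:
        raise ValueError("no cells passing QC")
    f_mt, j_mt = mito_references(cells, params.min_mito_reads)
    records: list[ClassificationRecord] = []
    for cpr in pseudo_cprs:
        f_raw, n_pos, n_tot = cpr_frequency(cpr, cells, params.min_overlap)
        j_raw = cpr_uniformity(cpr, cells)
        f_norm, j_norm = normalize_to_mito(f_raw, j_raw, f_mt, j_mt)
        u = uniformity_score(f_norm, j_norm)
        f_for_label = f_norm if params.use_f_norm else f_raw
        label = classify_cpr(f_for_label, u, params.f_threshold, params.u_threshold)
        records.append(
            ClassificationRecord(
                cpr=cpr,
                n_pos=n_pos,
                n_tot=n_tot,
                f_raw=f_raw,
                j_raw=j_raw,
                f_mt=f_mt,
                j_mt=j_mt,
                f_norm=f_norm,
                j_norm=j_norm,
                u=u,
                label=label,
            )
        )
    return records


_LABEL_COLORS = {
    "HFHU": "214,39,40",
    "HFLU": "255,127,14",
    "LFHU": "44,160,44",
    "LFLU": "31,119,180",
}


def records_to_table(records: Sequence[ClassificationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.cpr.chrom for r in records],
            "start": [r.cpr.start for r in records],
            "end": [r.cpr.end for r in records],
            "n_pos": [r.n_pos for r in records],
            "n_tot": [r.n_tot for r in records],
            "f_raw": [r.f_raw for r in records],
            "j_raw": [r.j_raw for r in records],
            "f_mt": [r.f_mt for r in records],
            "j_mt": [r.j_mt for r in records],
            "f_norm": [r.f_norm for r in records],
            "j_norm": [r.j_norm for r in records],
            "u": [r.u for r in records],
            "label": [r.label for r in records],
        }
    )


def write_classification(
    records: Sequence[ClassificationRecord], tsv_path: str | Path, bed_path: str | Path | None = None
) -> None:
    records_to_table(records).to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for i, r in enumerate(records):
                fh.write(
                    "\t".join(
                        map(
                            str,
                            [
                                r.cpr.chrom,
                                r.cpr.start,
                                r.cpr.end,
                                f"CPR_{i + 1}_{r.label}",
                                int(round(1000 * r.u)),
                                ".",
                                r.cpr.start,
                                r.cpr.end,
                                _LABEL_COLORS[r.label],
                            ],
                        )
                    )
                    + "\n"
                )
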