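"""Downstream eccDNA-landscape statistics.

Coverage autocorrelation with a coordinate-shuffle baseline, GC-content
comparison of CPRs versus matched background, meta-gene (scale-regions)
profiles of circle reads, feature-overlap enrichment, CPR co-occurrence
across cells, eccDNA/expression correlation, copy-number-stratified eccDNA
density, and daughter-cell distances.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment_io import CoverageTrack
from .cpr_detect import CPR
from .intervals import GenomicInterval


# ---------------------------------------------------------------------------
# autocorrelation


def _autocorr_single(signal: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Pearson r between f(x) and f(x+d) for each lag d (in bins)."""
    out = np.full(len(lags), np.nan)
    for i, d in enumerate(lags):
        if d == 0:
            out[i] = 1.0
            continue
        a, b = signal[:-d], signal[d:]
        if a.std() == 0 or b.std() == 0:
            continue
        out[i] = float(np.corrcoef(a, b)[0, 1])
    return out


def coverage_autocorrelation(
    coverage: CoverageTrack,
    max_lag: int,
    n_shuffles: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Autocorrelation r(d) of binned coverage, with a shuffle baseline.

    r(d) is computed per contig and combined across contigs weighted by bin
    count; the baseline permutes the genomic order of the bins (a coordinate
    shuffle preserving the count marginal) and recomputes r(d). Distances in
    the returned table are base pairs. Raises on zero-variance signal.
    """
    lags = np.arange(0, max_lag // coverage.bin_size + 1)
    arrays = [arr.astype(float) for arr in coverage.counts.values() if len(arr) > lags[-1] + 1]
    if not arrays or all(a.std() == 0 for a in arrays):
        raise ValueError("coverage signal has zero variance")
    weights = np.array([len(a) for a in arrays], dtype=float)

    def combined(signals: list[np.ndarray]) -> np.ndarray:
        rs = np.vstack([_autocorr_single(s, lags) for s in signals])
        mask = ~np.isnan(rs)
        w = np.where(mask, weights[:, None], 0.0)
        with np.errstate(invalid="ignore"):
            return np.nansum(rs * w, axis=0) / w.sum(axis=0)

    result = pd.DataFrame(
        {"distance": lags * coverage.bin_size, "r_observed": combined(arrays)}
    )
    if n_shuffles > 0:
        rng = np.random.default_rng(seed)
        shuffled = np.zeros((n_shuffles, len(lags)))
        for k in range(n_shuffles):
            shuffled[k] = combined([rng.permutation(a) for a in arrays])
        result["r_shuffled"] = shuffled.mean(axis=0)
    return result


# ---------------------------------------------------------------------------
# GC content


def gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


def gc_content_compare(
    cprs: Sequence[CPR | GenomicInterval],
    genome: Mapping[str, str],
    n_background_per_cpr: int = 1,
    seed: int = 0,
) -> dict:
    """Per-CPR GC versus length/contig-matched random non-CPR intervals.

    Background intervals are drawn uniformly on the same contig with the same
    length, rejecting overlaps with any CPR; groups are compared with a
    two-sided Wilcoxon rank-sum test.
    """
    rng = np.random.default_rng(seed)
    ivs = [c.interval if isinstance(c, CPR) else c for c in cprs]
    for iv in ivs:
        if iv.end > len(genome[iv.chrom]):
            raise ValueError(f"{iv} exceeds contig bounds")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    gc_in = [gc_fraction(genome[iv.chrom][iv.start : iv.end]) for iv in ivs]
    gc_out: list[float] = []
    for iv in ivs:
        clen = len(genome[iv.chrom])
        for _ in range(n_background_per_cpr):
            for _try in range(1000):
                s = int(rng.integers(0, clen - len(iv)))
                cand = GenomicInterval(iv.chrom, s, s + len(iv))
                if not any(cand.overlaps(o) for o in by_chrom[iv.chrom]):
                    gc_out.append(gc_fraction(genome[iv.chrom][s : s + len(iv)]))
                    break
    stat, p = stats.ranksums(gc_in, gc_out)
    return {
        "gc_in": float(np.mean(gc_in)),
        "gc_out": float(np.mean(gc_out)),
        "gc_in_values": gc_in,
        "gc_out_values": gc_out,
        "statistic": float(stat),
        "p_value": float(p),
    }


# ---------------------------------------------------------------------------
# meta-gene profile


def metagene_profile(
    read_midpoints: Mapping[str, np.ndarray],
    genes: pd.DataFrame,
    body_bins: int = 50,
    flank_bp: int = 2000,
    flank_bins: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Scale-regions profile of circle-read midpoints over gene bodies.

    ``genes`` needs chrom/start/end/strand columns. Gene bodies are scaled to
    ``body_bins`` columns with fixed-width flanks on both sides; minus-strand
    genes are reversed so transcription runs left to right. Genes shorter
    than ``body_bins`` bases are skipped. Returns (matrix, column mean).
    """
    n_cols = 2 * flank_bins + body_bins
    rows = []
    for g in genes.itertuples():
        glen = g.end - g.start
        if glen < body_bins:
            continue
        mids = read_midpoints.get(g.chrom)
        row = np.zeros(n_cols)
        if mids is not None and len(mids):
            w0, w1 = g.start - flank_bp, g.end + flank_bp
            sel = mids[(mids >= w0) & (mids < w1)]
            for m in sel:
                if m < g.start:
                    col = int((m - w0) / flank_bp * flank_bins)
                elif m >= g.end:
                    col = flank_bins + body_bins + int((m - g.end) / flank_bp * flank_bins)
                else:
                    col = flank_bins + int((m - g.start) / glen * body_bins)
                row[min(col, n_cols - 1)] += 1
        if getattr(g, "strand", "+") == "-":
            row = row[::-1]
        rows.append(row)
    matrix = np.vstack(rows) if rows else np.zeros((0, n_cols))
    return matrix, matrix.mean(axis=0) if len(matrix) else np.zeros(n_cols)


# ---------------------------------------------------------------------------
# feature overlap


def feature_overlap_stats(
    cprs_by_cell: Mapping[str, Sequence[CPR | GenomicInterval]],
    features: pd.DataFrame,
    circle_reads: Mapping[str, Sequence[int]] | None = None,
    cpr_frequency: Mapping[tuple[str, int, int], float] | None = None,
) -> dict:
    """Overlap of per-cell CPRs with a feature track (>=1 bp rule).

    Returns per-cell overlap counts, per-CPR flags, the feature fraction
    (circle reads inside feature-overlapping CPRs over all circle reads, when
    read counts are supplied), and a two-sided rank-sum comparison of CPR
    frequency between overlapping and non-overlapping CPRs (when a frequency
    map is supplied).
    """
    if features.empty:
        raise ValueError("empty feature table")
    feats = [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        for r in features.itertuples()
    ]
    per_cell_counts: dict[str, int] = {}
    flags: dict[str, list[bool]] = {}
    reads_in, reads_total = 0, 0
    freq_overlap, freq_other = [], []
    for cell, cprs in cprs_by_cell.items():
        ivs = [c.interval if isinstance(c, CPR) else c for c in cprs]
        cell_flags = [any(iv.overlaps(f) for f in feats) for iv in ivs]
        flags[cell] = cell_flags
        per_cell_counts[cell] = int(sum(cell_flags))
        if circle_reads is not None:
            counts = list(circle_reads[cell])
            reads_total += sum(counts)
            reads_in += sum(c for c, fl in zip(counts, cell_flags) if fl)
        if cpr_frequency is not None:
            for iv, fl in zip(ivs, cell_flags):
                f = cpr_frequency.get((iv.chrom, iv.start, iv.end))
                if f is None:
                    continue
                (freq_overlap if fl else freq_other).append(f)
    out = {
        "per_cell_overlap_counts": per_cell_counts,
        "per_cpr_flags": flags,
        "feature_fraction": (reads_in / reads_total) if reads_total else float("nan"),
    }
    if freq_overlap and freq_other:
        stat, p = stats.ranksums(freq_overlap, freq_other)
        out["frequency_statistic"] = float(stat)
        out["frequency_p_value"] = float(p)
        out["mean_frequency_overlapping"] = float(np.mean(freq_overlap))
        out["mean_frequency_other"] = float(np.mean(freq_other))
    return out


# ---------------------------------------------------------------------------
# co-occurrence and expression correlation


def cooccurrence(
    matrix: pd.DataFrame,
    anchor_columns: Sequence[str],
    pcc_threshold: float = 0.5,
) -> pd.DataFrame:
    """Pearson correlation of every CPR column with an anchor region's vector.

    ``matrix`` is cells x CPRs (binary presence by default). The anchor
    vector is the mean of the anchor columns (binary: any). Zero-variance
    columns are excluded as undefined.
    """
    missing = [c for c in anchor_columns if c not in matrix.columns]
    if missing or not anchor_columns:
        raise KeyError(f"anchor columns not in catalog: {missing}")
    anchor = matrix[list(anchor_columns)].mean(axis=1)
    if anchor.std() == 0:
        raise ValueError("anchor vector has zero variance")
    rows = []
    for col in matrix.columns:
        v = matrix[col]
        if v.std() == 0:
            continue
        pcc = float(np.corrcoef(v, anchor)[0, 1])
        rows.append({"cpr": col, "pcc": pcc, "selected": pcc > pcc_threshold})
    return pd.DataFrame(rows)


def expression_correlation(
    ecc_reads: pd.DataFrame,
    expression: pd.DataFrame,
    pcc_threshold: float = 0.6,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-gene PCC between eccDNA read abundance and expression across cells.

    Both tables are cells x genes; cells are intersected, genes restricted to
    the shared set. Expression is log1p-transformed by default. Constant
    vectors are excluded.
    """
    cells = ecc_reads.index.intersection(expression.index)
    if len(cells) < 3:
        raise ValueError("need at least 3 shared cells")
    genes = ecc_reads.columns.intersection(expression.columns)
    rows = []
    for gene in genes:
        x = ecc_reads.loc[cells, gene].to_numpy(dtype=float)
        y = expression.loc[cells, gene].to_numpy(dtype=float)
        if log_transform:
            y = np.log1p(y)
        if x.std() == 0 or y.std() == 0:
            continue
        pcc = float(np.corrcoef(x, y)[0, 1])
        rows.append({"gene": gene, "pcc": pcc, "flagged": pcc > pcc_threshold})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# copy-number stratified density


def cn_density(
    cprs_by_cell: Mapping[str, Sequence[CPR | GenomicInterval]],
    cn_segments: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """eccDNAs per 100 kb of territory in each copy-number class.

    ``cn_segments`` needs chrom/start/end/cn columns. A CPR is assigned to
    the class of the segment containing its midpoint. Returns the per-cell
    density table (cells x CN classes) and pairwise two-sided Welch t-tests
    between classes. Zero-territory classes are excluded.
    """
    territory: dict[int, float] = {}
    for r in cn_segments.itertuples():
        territory[int(r.cn)] = territory.get(int(r.cn), 0.0) + (r.end - r.start)
    classes = sorted(k for k, v in territory.items() if v > 0)

    rows = {}
    for cell, cprs in cprs_by_cell.items():
        counts = dict.fromkeys(classes, 0)
        for c in cprs:
            iv = c.interval if isinstance(c, CPR) else c
            mid = (iv.start + iv.end) // 2
            for r in cn_segments.itertuples():
                if r.chrom == iv.chrom and r.start <= mid < r.end:
                    if int(r.cn) in counts:
                        counts[int(r.cn)] += 1
                    break
        rows[cell] = {
            k: counts[k] / (territory[k] / 100_000) for k in classes
        }
    dens = pd.DataFrame(rows).T.sort_index()

    tests = []
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            t, p = stats.ttest_ind(dens[a], dens[b], equal_var=False)
            tests.append({"cn_a": a, "cn_b": b, "t": float(t), "p_value": float(p)})
    return dens, pd.DataFrame(tests)


# ---------------------------------------------------------------------------
# daughter-cell distances


def daughter_distance(
    vectors_by_cell: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Euclidean distance between cells' normalized eccDNA abundance vectors.

    Returns the full symmetric distance matrix; when ``pairs`` is given the
    matrix is restricted to the listed cells (catalog columns must match, as
    they come from one population's pseudo-bulk CPR set).
    """
    X = vectors_by_cell.to_numpy(dtype=float)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    dm = pd.DataFrame(d, index=vectors_by_cell.index, columns=vectors_by_cell.index)
    if pairs is not None:
        cells = sorted({c for p in pairs for c in p})
        missing = [c for c in cells if c not in dm.index]
        if missing:
            raise KeyError(f"cells missing from vector catalog: {missing}")
        dm = dm.loc[cells, cells]
    return dm
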