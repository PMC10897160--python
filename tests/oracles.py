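"""Independent brute-force oracles used to validate the implementation.

Everything here deliberately avoids the library's own interval/cluster code:
interval arithmetic is done on explicit per-base Python sets, clustering by
O(n^2) pairwise linkage, run-calling by per-bin scanning.
"""

from __future__ import annotations

import numpy as np


# --- per-base interval arithmetic -----------------------------------------


def bases(iv: tuple[str, int, int]) -> set[tuple[str, int]]:
    chrom, start, end = iv
    return {(chrom, p) for p in range(start, end)}


def bases_of(ivs) -> set[tuple[str, int]]:
    out: set[tuple[str, int]] = set()
    for iv in ivs:
        out |= bases(iv)
    return out


def oracle_merge(ivs: list[tuple[str, int, int]], gap: int = 0) -> list[tuple[str, int, int]]:
    """Merge via per-base set arithmetic with a gap dilation."""
    # dilate each interval by gap on the right, union, then read off runs
    dilated = bases_of([(c, s, e + gap) for c, s, e in ivs])
    raw = bases_of(ivs)
    out = []
    for chrom in sorted({c for c, _ in raw}):
        pts = sorted(p for c, p in dilated if c == chrom)
        runs = []
        for p in pts:
            if runs and p == runs[-1][1]:
                runs[-1][1] = p + 1
            else:
                runs.append([p, p + 1])
        for s, e in runs:
            real = sorted(p for c, p in raw if c == chrom and s <= p < e)
            if real:
                out.append((chrom, real[0], real[-1] + 1))
    return out


def oracle_classification(
    pseudo: tuple[str, int, int],
    cells: list[list[tuple[str, int, int]]],
    f_mt: float,
    j_mt: float,
    min_overlap: float = 0.10,
    f_threshold: float = 0.65,
    u_threshold: float = 0.30,
) -> dict:
    """Frequency/uniformity quantities via per-base sets (exact fractions)."""
    pb = bases(pseudo)
    n_tot = len(cells)
    n_pos = 0
    j_sum = 0.0
    for cell in cells:
        if any(len(bases(civ) & pb) >= min_overlap * len(pb) for civ in cell):
            n_pos += 1
        overlapping = [civ for civ in cell if bases(civ) & pb]
        if overlapping:
            ub = bases_of(overlapping)
            j_sum += len(ub & pb) / len(ub | pb)
    f_raw = n_pos / n_tot
    j_raw = j_sum / n_tot
    f_norm = min(1.0, f_raw / f_mt)
    j_norm = min(1.0, j_raw / j_mt)
    u = f_norm * j_norm
    label = ("HF" if f_norm > f_threshold else "LF") + ("HU" if u > u_threshold else "LU")
    return {
        "n_pos": n_pos,
        "f_raw": f_raw,
        "j_raw": j_raw,
        "f_norm": f_norm,
        "j_norm": j_norm,
        "u": u,
        "label": label,
    }


# --- junction clustering ---------------------------------------------------


def oracle_cluster(
    raw: list[tuple[str, int, str, int]],
    window: int = 500,
    min_support: int = 2,
) -> list[dict]:
    """O(n^2) single-linkage clustering of (chromA, posA, chromB, posB) pairs.

    ``raw`` entries are (chrom_a, pos_a, chrom_b, pos_b), already canonical.
    Returns clusters as dicts with weighted-median representatives.
    """
    n = len(raw)
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(i + 1, n):
                ca, pa, cb, pb = raw[i]
                da, qa, db, qb = raw[j]
                if (
                    ca == da
                    and cb == db
                    and abs(pa - qa) <= window
                    and abs(pb - qb) <= window
                    and labels[i] != labels[j]
                ):
                    lo, hi = sorted((labels[i], labels[j]))
                    labels = [lo if l == hi else l for l in labels]
                    changed = True
    clusters = {}
    for i, l in enumerate(labels):
        clusters.setdefault(l, []).append(i)
    out = []
    for members in clusters.values():
        if len(members) < min_support:
            continue
        pa = lower_median([raw[i][1] for i in members])
        pb = lower_median([raw[i][3] for i in members])
        out.append(
            {
                "chrom_a": raw[members[0]][0],
                "chrom_b": raw[members[0]][2],
                "pos_a": pa,
                "pos_b": pb,
                "support": len(members),
            }
        )
    return out


def lower_median(values: list[int]) -> int:
    """Smallest value whose cumulative unit weight reaches half the total."""
    vals = sorted(values)
    total = len(vals)
    cum = 0
    for v in vals:
        cum += 1
        if cum >= total / 2:
            return v
    return vals[-1]


# --- coverage --------------------------------------------------------------


def oracle_binned_coverage(
    reads: list[tuple[str, int, int]],
    bin_size: int,
    contig_lengths: dict[str, int],
) -> dict[str, np.ndarray]:
    """Per-bin read counts by literally enumerating each read's bins."""
    out = {
        c: np.zeros(int(np.ceil(n / bin_size)), dtype=int)
        for c, n in contig_lengths.items()
    }
    for chrom, start, end in reads:
        touched = sorted({p // bin_size for p in range(start, end)})
        for b in touched:
            if b < len(out[chrom]):
                out[chrom][b] += 1
    return out


def oracle_run_scan(counts: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of bins >= threshold by per-bin scanning."""
    runs = []
    in_run = False
    for i, v in enumerate(counts):
        if v >= threshold and not in_run:
            runs.append([i, i + 1])
            in_run = True
        elif v >= threshold:
            runs[-1][1] = i + 1
        else:
            in_run = False
    return [tuple(r) for r in runs]


# --- multiple testing ------------------------------------------------------


def oracle_bh(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg by the direct defining formula."""
    n = len(pvals)
    indexed = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    for rank_from_1, i in enumerate(indexed, start=1):
        candidates = [
            pvals[j] * n / (indexed.index(j) + 1)
            for j in indexed[rank_from_1 - 1 :]
        ]
        adj[i] = min(1.0, min(candidates))
    return adj
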