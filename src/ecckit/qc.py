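"""Per-cell QC metrics and sample filters.

The filters mirror standard practice for circle-enrichment assays: discard a
cell when its mapping rate is below 90%, its circular spike-in enrichment is
below 80%, fewer than 100 CPRs were found, or the mappability proxy (fraction
of primary reads with mapQ > 20) is below 70%. The combination rule is
configurable (default: fail on any violation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .alignment_io import Alignment
from .cpr_detect import CPR


def spikein_enrichment(reads_circular_spike: int, reads_all_spike: int) -> float:
    """Circular spike-in reads over all spike-in reads."""
    if reads_all_spike == 0:
        raise ValueError("no spike-in reads detected")
    if reads_circular_spike > reads_all_spike:
        raise ValueError("circular spike-in reads exceed total spike-in reads")
    return reads_circular_spike / reads_all_spike


def circle_read_enrichment(
    segments: Iterable[Alignment], cprs: Sequence[CPR]
) -> float:
    """Fraction of primary non-duplicate reads whose midpoint lies in a CPR."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in cprs:
        by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    total = inside = 0
    for a in segments:
        if not a.is_primary or a.is_duplicate:
            continue
        total += 1
        mid = a.midpoint()
        if any(s <= mid < e for s, e in by_chrom.get(a.chrom, ())):
            inside += 1
    if total == 0:
        raise ValueError("no reads")
    return inside / total


@dataclass
class QCThresholds:
    min_mapping_rate: float = 0.90
    min_spike_circ: float = 0.80
    min_cprs: int = 100
    min_mappability: float = 0.70
    rule: str = "any"  # "any": fail on any violation; "and": fail only if mapping AND spike violated


def cell_filter(
    qc: Mapping[str, float], thresholds: QCThresholds | None = None
) -> tuple[bool, list[str]]:
    """Pass/fail with the violated criteria enumerated.

    ``qc`` must provide mapping_rate, spikein_circular_fraction, n_cprs and
    mappability_proxy. The default rule fails on any violation; the "and"
    rule applies the read-level filters jointly (fail only when both the
    mapping-rate and spike-in thresholds are violated), with the CPR-count
    and mappability filters always individually disqualifying.
    """
    t = thresholds or QCThresholds()
    reasons: list[str] = []
    if qc["mapping_rate"] < t.min_mapping_rate:
        reasons.append(f"mapping_rate {qc['mapping_rate']:.3f} < {t.min_mapping_rate}")
    if qc["spikein_circular_fraction"] < t.min_spike_circ:
        reasons.append(
            f"spikein_circular_fraction {qc['spikein_circular_fraction']:.3f} < {t.min_spike_circ}"
        )
    if t.rule == "and" and len(reasons) == 1:
        reasons = []
    if qc["n_cprs"] < t.min_cprs:
        reasons.append(f"n_cprs {qc['n_cprs']} < {t.min_cprs}")
    if qc["mappability_proxy"] < t.min_mappability:
        reasons.append(
            f"mappability_proxy {qc['mappability_proxy']:.3f} < {t.min_mappability}"
        )
    return (len(reasons) == 0, reasons)


def mappability_proxy(segments: Iterable[Alignment], min_mapq: int = 20) -> float:
    """Fraction of primary records with mapQ above the cutoff."""
    total = good = 0
    for a in segments:
        if a.is_primary:
            total += 1
            if a.mapq > min_mapq:
                good += 1
    return good / total if total else 0.0
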