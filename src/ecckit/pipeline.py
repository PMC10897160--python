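"""End-to-end orchestration: per-cell runs, population runs, configuration.

`run_cell` takes one cell's coordinate-sorted alignments through
deduplication, CPR calling, junction clustering, structure classification
and QC; `run_population` pools passing cells into a pseudo-bulk profile,
classifies every pseudo-bulk CPR by frequency/uniformity, fits the topic
model and writes a population summary. Both are pure functions of
(inputs, config, seed); every output embeds the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import classify as _classify
from . import topics as _topics
from .alignment_io import (
    Alignment,
    count_total_reads,
    deduplicate,
    extract_chimeric,
    mapping_rate,
    read_alignments,
)
from .classify import CellProfile, ClassifyParams, build_pseudobulk, classify_population
from .cpr_detect import CPRParams, detect_cprs, write_cpr_bed, cprs_to_table
from .junctions import (
    assign_to_cprs,
    classify_cpr_structure,
    cluster_junctions,
    extract_junction_endpoints,
    write_bedpe,
)
from .qc import (
    QCThresholds,
    cell_filter,
    circle_read_enrichment,
    mappability_proxy,
    spikein_enrichment,
)

logger = logging.getLogger("ecckit")


@dataclass
class Config:
    """Versioned pipeline configuration: all thresholds in one place."""

    version: int = 1
    cpr: CPRParams = field(default_factory=CPRParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    qc: QCThresholds = field(default_factory=QCThresholds)
    junction_window: int = 500
    junction_min_support: int = 2
    edge_window: int = 500
    max_simple_junctions: int = 2
    distal_threshold: int = 1_000_000
    topic_bin_size: int = 2000
    mito_contig: str = "chrM"
    spike_circ_contig: str = "spike_circ"
    spike_lin_contig: str = "spike_lin"
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if key in ("cpr", "classify", "qc") and isinstance(value, dict):
                sub = getattr(cfg, key)
                for k, v in value.items():
                    setattr(sub, k, tuple(v) if isinstance(v, list) else v)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def run_cell(
    alignment_path: str | Path,
    contig_lengths: dict[str, int],
    config: Config | None = None,
    out_dir: str | Path | None = None,
) -> tuple[CellProfile, list[Alignment]]:
    """Process one cell: dedup, CPR calling, junctions, structure, QC.

    Returns the CellProfile (with QC and pass/fail) and the deduplicated
    alignments; writes BED/BEDPE/TSV outputs when ``out_dir`` is given.
    """
    config = config or Config()
    path = Path(alignment_path)
    cell_id = path.stem
    stage = "alignment_io"
    try:
        segments = list(read_alignments(path))
        if not segments:
            raise ValueError("empty alignment file")
        n_total = count_total_reads(path)
        map_rate = mapping_rate(segments, n_total)
        segments = deduplicate(segments)

        stage = "cpr_detect"
        cprs, coverage = detect_cprs(segments, contig_lengths, params=config.cpr)

        stage = "junctions"
        split, _ = extract_chimeric(
            segments,
            min_mapq=config.cpr.min_mapq,
            insert_threshold=config.cpr.insert_threshold,
        )
        raw = extract_junction_endpoints(split) if split else []
        junctions = cluster_junctions(
            raw,
            cprs,
            window=config.junction_window,
            min_support=config.junction_min_support,
        )
        for c in cprs:
            c.structure_class = classify_cpr_structure(
                c,
                edge_window=config.edge_window,
                max_simple_junctions=config.max_simple_junctions,
            )

        stage = "qc"
        spike_circ = sum(
            1
            for a in segments
            if a.is_primary and a.chrom == config.spike_circ_contig
        )
        spike_all = spike_circ + sum(
            1
            for a in segments
            if a.is_primary and a.chrom == config.spike_lin_contig
        )
        mito_reads = sum(
            1 for a in segments if a.is_primary and a.chrom == config.mito_contig
        )
        qc = {
            "cell_id": cell_id,
            "total_reads": n_total,
            "mapping_rate": map_rate,
            "spikein_circular_fraction": (
                spikein_enrichment(spike_circ, spike_all) if spike_all else 0.0
            ),
            "circle_read_enrichment": (
                circle_read_enrichment(segments, cprs) if cprs else 0.0
            ),
            "n_cprs": len(cprs),
            "mappability_proxy": mappability_proxy(segments),
            "mito_reads": mito_reads,
        }
        passed, reasons = cell_filter(qc, config.qc)
        qc["pass_reasons"] = reasons

        profile = CellProfile(
            cell_id=cell_id,
            cprs=cprs,
            mito_reads=mito_reads,
            qc=qc,
            pass_qc=passed,
        )

        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_cpr_bed(cprs, out / f"{cell_id}.cprs.bed")
            write_bedpe(junctions, out / f"{cell_id}.junctions.bedpe")
            table = cprs_to_table(cprs)
            table.insert(0, "cell_id", cell_id)
            table.to_csv(out / f"{cell_id}.cprs.tsv", sep="\t", index=False)
            with open(out / f"{cell_id}.qc.json", "w") as fh:
                json.dump(
                    {**qc, "pass_qc": passed, "config_hash": config.hash()},
                    fh,
                    indent=1,
                    sort_keys=True,
                )
        logger.info("cell %s: %d CPRs, %d junctions, pass_qc=%s", cell_id, len(cprs), len(junctions), passed)
        return profile, segments
    except Exception as exc:
        raise RuntimeError(f"[{stage}] cell {cell_id}: {exc}") from exc


def run_population(
    cell_paths: Sequence[str | Path],
    contig_lengths: dict[str, int],
    config: Config | None = None,
    out_dir: str | Path | None = None,
    topic_grid: Sequence[int] = (),
) -> dict:
    """Process a directory of cells into classification + topics + summary.

    QC-failing cells are excluded from classification and topic modeling but
    reported in the summary. Raises when no cell passes QC.
    """
    config = config or Config()
    profiles: list[CellProfile] = []
    alignments: dict[str, list[Alignment]] = {}
    for p in sorted(map(Path, cell_paths)):
        profile, segs = run_cell(p, contig_lengths, config, out_dir=out_dir)
        profiles.append(profile)
        alignments[profile.cell_id] = segs

    passing = [p for p in profiles if p.pass_qc]
    if not passing:
        reasons = {p.cell_id: p.qc.get("pass_reasons", []) for p in profiles}
        raise ValueError(f"no cells pass QC: {json.dumps(reasons, sort_keys=True)}")

    pseudo = build_pseudobulk(
        [alignments[p.cell_id] for p in passing], contig_lengths, params=config.cpr
    )
    records = classify_population(passing, pseudo, params=config.classify)

    result: dict = {
        "config_hash": config.hash(),
        "n_cells": len(profiles),
        "n_passing": len(passing),
        "qc": {p.cell_id: {k: v for k, v in p.qc.items() if k != "cell_id"} for p in profiles},
        "n_pseudobulk_cprs": len(pseudo),
        "label_counts": {
            label: sum(1 for r in records if r.label == label)
            for label in ("HFHU", "HFLU", "LFHU", "LFLU")
        },
    }

    bin_matrix = _topics.build_bin_matrix(
        {p.cell_id: alignments[p.cell_id] for p in passing},
        {p.cell_id: p.cprs for p in passing},
        contig_lengths,
        bin_size=config.topic_bin_size,
        excluded_contigs=(
            config.mito_contig,
            config.spike_circ_contig,
            config.spike_lin_contig,
        ),
    )
    model = None
    if topic_grid:
        models = [
            _topics.fit_lda(bin_matrix, k, seed=config.seed) for k in topic_grid
        ]
        if len(models) >= 3:
            best_k, table = _topics.select_model(models)
            model = next(m for m in models if m.n_topics == best_k)
            result["selected_n_topics"] = best_k
        else:
            model = models[-1]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _classify.write_classification(
            records, out / "classification.tsv", out / "classification.bed"
        )
        bin_matrix.counts.to_csv(out / "bin_matrix.tsv", sep="\t")
        if model is not None:
            model.cell_topic.to_csv(out / "cell_topic.tsv", sep="\t")
            model.topic_bin.to_csv(out / "topic_bin.tsv", sep="\t")
        with open(out / "summary.json", "w") as fh:
            json.dump(result, fh, indent=1, sort_keys=True, default=str)

    result["records"] = records
    result["profiles"] = profiles
    result["pseudobulk_cprs"] = pseudo
    result["bin_matrix"] = bin_matrix
    result["topic_model"] = model
    return result
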