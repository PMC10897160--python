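"""Shared fixtures: small simulated populations reused across test modules."""

from __future__ import annotations

import json
from pathlib import Path

import pytest

from ecckit.pipeline import Config
from ecckit.simulate import SimDesign, simulate_population, truth_from_json


SMALL_CONTIGS = {"chr1": 300_000, "chr2": 200_000}


def small_config() -> Config:
    # desk-scale genomes carry far fewer CPRs than a real cell; scale the
    # CPR-count QC floor accordingly (all other thresholds at defaults)
    cfg = Config()
    cfg.qc.min_cprs = 3
    return cfg


@pytest.fixture(scope="session")
def small_population(tmp_path_factory) -> dict:
    """3 cells, 12 singleton circles each, error-free reads."""
    out = tmp_path_factory.mktemp("smallpop")
    design = SimDesign(
        n_cells=3,
        singletons_per_cell=12,
        main_contigs=dict(SMALL_CONTIGS),
        error_rate=0.0,
        seed=11,
    )
    manifest = simulate_population(design, out, force=True)
    truth = truth_from_json(json.loads((out / "truth.json").read_text()))
    return {
        "dir": out,
        "design": design,
        "truth": truth,
        "manifest": manifest,
        "contig_lengths": design.contig_lengths(),
        "cells": sorted(out.glob("cell_*.sam")),
    }


@pytest.fixture(scope="session")
def small_cell(small_population) -> dict:
    """First cell of the small population, processed through run_cell."""
    from ecckit.pipeline import run_cell

    profile, segments = run_cell(
        small_population["cells"][0],
        small_population["contig_lengths"],
        small_config(),
    )
    return {
        "profile": profile,
        "segments": segments,
        "truth": small_population["truth"],
        "design": small_population["design"],
    }
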