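"""Bin-matrix construction, LDA fitting, model selection, differential topics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ecckit.alignment_io import Alignment
from ecckit.cpr_detect import CPR
from ecckit.intervals import GenomicInterval
from ecckit.simulate import simulate_topic_matrix
from ecckit.topics import (
    TopicModel,
    benjamini_hochberg,
    build_bin_matrix,
    differential_topics,
    dominant_topic_groups,
    fit_lda,
    select_model,
    topic_regions,
)

from oracles import oracle_bh

CONTIGS = {"chr1": 100_000}


def read(chrom, start, rid="r", length=100):
    return Alignment(
        read_id=rid, is_read1=True, chrom=chrom, start=start, cigar=f"{length}M", mapq=60
    )


def cpr(chrom, start, end):
    return CPR(interval=GenomicInterval(chrom, start, end))


class TestBuildBinMatrix:
    def test_single_cell_single_bin_normalizes_to_one(self):
        reads = [read("chr1", 1000 + i, rid=f"r{i}") for i in range(10)]
        bm = build_bin_matrix(
            {"c": reads}, {"c": [cpr("chr1", 500, 2500)]}, CONTIGS, bin_size=2000
        )
        assert bm.normalized.shape == (1, 1)
        assert bm.normalized.iloc[0, 0] == 1.0
        assert bm.counts.iloc[0, 0] == 10

    def test_reads_outside_own_cprs_excluded(self):
        reads = [read("chr1", 1000), read("chr1", 50_000, rid="outside")]
        bm = build_bin_matrix(
            {"c": reads}, {"c": [cpr("chr1", 500, 2500)]}, CONTIGS, bin_size=2000
        )
        assert bm.counts.to_numpy().sum() == 1

    def test_disjoint_cells_give_block_structure(self):
        cells = {
            "a": [read("chr1", 1000 + i, rid=f"a{i}") for i in range(5)],
            "b": [read("chr1", 60_000 + i, rid=f"b{i}") for i in range(5)],
        }
        cprs = {
            "a": [cpr("chr1", 500, 2500)],
            "b": [cpr("chr1", 59_500, 61_500)],
        }
        bm = build_bin_matrix(cells, cprs, CONTIGS, bin_size=2000)
        m = bm.counts.to_numpy()
        assert m.shape == (2, 2)
        assert m[0, 1] == 0 and m[1, 0] == 0
        assert m[0, 0] > 0 and m[1, 1] > 0

    def test_cell_without_in_cpr_reads_excluded(self):
        cells = {"empty": [read("chr1", 90_000)], "ok": [read("chr1", 1000)]}
        cprs = {"empty": [cpr("chr1", 500, 2500)], "ok": [cpr("chr1", 500, 2500)]}
        bm = build_bin_matrix(cells, cprs, CONTIGS, bin_size=2000)
        assert bm.excluded_cells == ["empty"]
        assert list(bm.counts.index) == ["ok"]


class TestFitLDA:
    def test_single_topic_degenerate(self):
        df, _ = simulate_topic_matrix(cells_per_group=5, seed=0)
        model = fit_lda(df, 1, seed=0)
        assert np.allclose(model.cell_topic.to_numpy(), 1.0)

    def test_distributions_are_simplex_points(self):
        df, _ = simulate_topic_matrix(cells_per_group=5, seed=1)
        model = fit_lda(df, 4, seed=0)
        assert np.allclose(model.cell_topic.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(model.topic_bin.sum(axis=1), 1.0, atol=1e-9)
        assert (model.cell_topic.to_numpy() >= 0).all()
        assert (model.topic_bin.to_numpy() >= 0).all()

    def test_same_seed_identical_model(self):
        df, _ = simulate_topic_matrix(cells_per_group=5, seed=2)
        a = fit_lda(df, 3, seed=7)
        b = fit_lda(df, 3, seed=7)
        pd.testing.assert_frame_equal(a.cell_topic, b.cell_topic)
        pd.testing.assert_frame_equal(a.topic_bin, b.topic_bin)

    def test_planted_groups_dominated_by_distinct_topics(self):
        df, labels = simulate_topic_matrix(seed=5)
        model = fit_lda(df, 3, seed=0)
        dominant = model.cell_topic.idxmax(axis=1)
        weights = model.cell_topic.max(axis=1)
        assert (weights > 0.8).mean() > 0.95
        # each planted group maps to its own topic
        assert dominant.groupby(labels).nunique().max() == 1
        assert dominant.nunique() == 3

    def test_perplexity_decreases_with_more_iterations(self):
        df, _ = simulate_topic_matrix(cells_per_group=5, seed=3)
        px = [fit_lda(df, 3, n_iter=it, seed=0).perplexity for it in (5, 20, 60)]
        assert px[0] >= px[1] - 1e-6 and px[1] >= px[2] - 1e-6

    def test_too_many_topics_rejected(self):
        df, _ = simulate_topic_matrix(cells_per_group=2, bins_per_group=3, seed=0)
        with pytest.raises(ValueError):
            fit_lda(df, df.shape[1] + 1)


def fake_model(k, ll, px):
    cols = [f"topic_{i}" for i in range(k)]
    return TopicModel(
        n_topics=k,
        cell_topic=pd.DataFrame([[1.0 / k] * k], columns=cols),
        topic_bin=pd.DataFrame(np.ones((k, 2)) / 2, index=cols, columns=["b1", "b2"]),
        log_likelihood=ll,
        perplexity=px,
    )


class TestSelectModel:
    def test_elbow_at_constructed_knee(self):
        lls = {2: -1000, 3: -500, 4: -490, 5: -480, 6: -470}
        models = [fake_model(k, ll, 100.0) for k, ll in lls.items()]
        best, table = select_model(models)
        assert best == 3
        assert set(table["n_topics"]) == set(lls)

    def test_flat_curve_tie_broken_by_perplexity(self):
        models = [fake_model(k, -1000.0, px) for k, px in [(2, 50), (3, 40), (4, 60)]]
        best, _ = select_model(models)
        assert best == 3

    def test_planted_three_topic_data_selected(self):
        df, labels = simulate_topic_matrix(seed=5)
        models = [fit_lda(df, k, seed=0) for k in range(2, 7)]
        best, _ = select_model(models)
        assert best == 3
        chosen = next(m for m in models if m.n_topics == best)
        groups = dominant_topic_groups(chosen).astype("category").cat.codes
        assert adjusted_rand_score(labels, groups) >= 0.9

    def test_too_few_grid_points_rejected(self):
        with pytest.raises(ValueError):
            select_model([fake_model(2, -1.0, 1.0), fake_model(3, -1.0, 1.0)])


class TestTopicRegions:
    def test_contiguous_top_bins_merge_into_one_region(self):
        bins = [GenomicInterval("chr1", i * 2000, (i + 1) * 2000) for i in range(50)]
        loadings = np.full(50, 1e-4)
        loadings[10:20] = 0.1  # one contiguous 10-bin run
        loadings /= loadings.sum()
        model = TopicModel(
            n_topics=1,
            cell_topic=pd.DataFrame([[1.0]], columns=["topic_1"]),
            topic_bin=pd.DataFrame([loadings], index=["topic_1"],
                                   columns=[f"b{i}" for i in range(50)]),
            log_likelihood=0.0,
            perplexity=1.0,
        )
        regions = topic_regions(model, bins, score_quantile=0.8)
        assert regions["topic_1"] == [GenomicInterval("chr1", 20_000, 40_000)]

    def test_quantile_rule_keeps_top_fraction(self):
        bins = [GenomicInterval("chr1", i * 2000, (i + 1) * 2000) for i in range(100)]
        loadings = np.linspace(1, 100, 100)
        loadings /= loadings.sum()
        model = TopicModel(
            n_topics=1,
            cell_topic=pd.DataFrame([[1.0]], columns=["topic_1"]),
            topic_bin=pd.DataFrame([loadings], index=["topic_1"],
                                   columns=[f"b{i}" for i in range(100)]),
            log_likelihood=0.0,
            perplexity=1.0,
        )
        regions = topic_regions(model, bins, score_quantile=0.9, merge_gap=0)
        total_bins = sum(len(r) // 2000 for r in regions["topic_1"])
        assert total_bins == 10  # top decile retained


class TestDifferentialTopics:
    def test_identical_groups_select_nothing(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(
            rng.dirichlet(np.ones(4), size=12),
            index=[f"c{i}" for i in range(12)],
            columns=[f"topic_{k}" for k in range(4)],
        )
        labels = pd.Series(["A"] * 6 + ["B"] * 6, index=m.index)
        res = differential_topics(m, labels)
        assert not res["selected"].any()

    def test_strong_shift_selected(self):
        rng = np.random.default_rng(1)
        base = rng.dirichlet(np.ones(3), size=40)
        m = pd.DataFrame(base, index=[f"c{i}" for i in range(40)],
                         columns=["topic_1", "topic_2", "topic_3"])
        m.iloc[:20, 0] = m.iloc[:20, 0] * 8 + 0.5  # group A loaded on topic_1
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=m.index)
        res = differential_topics(m, labels).set_index("topic")
        assert bool(res.loc["topic_1", "selected"]) is True

    def test_small_group_rejected(self):
        m = pd.DataFrame(np.ones((4, 2)) / 2, index=list("abcd"),
                         columns=["topic_1", "topic_2"])
        labels = pd.Series(["A", "A", "B", "B"], index=m.index)
        with pytest.raises(ValueError):
            differential_topics(m, labels)


def test_bh_adjustment_matches_direct_formula_oracle():
    rng = np.random.default_rng(4)
    for _ in range(20):
        ps = rng.random(int(rng.integers(1, 11))).tolist()
        np.testing.assert_allclose(benjamini_hochberg(ps), oracle_bh(ps), atol=1e-12)
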