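"""Landscape statistics: autocorrelation, GC, profiles, densities, distances."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecckit.alignment_io import CoverageTrack
from ecckit.intervals import GenomicInterval
from ecckit.landscape import (
    cn_density,
    cooccurrence,
    coverage_autocorrelation,
    daughter_distance,
    expression_correlation,
    feature_overlap_stats,
    gc_content_compare,
    gc_fraction,
    metagene_profile,
)


def track_from(counts, bin_size=100):
    arr = np.asarray(counts, dtype=np.int64)
    return CoverageTrack(
        bin_size=bin_size,
        contig_lengths={"chr1": len(arr) * bin_size},
        counts={"chr1": arr},
    )


class TestAutocorrelation:
    def test_r0_is_one(self):
        t = track_from(np.random.default_rng(0).poisson(5, 1000))
        res = coverage_autocorrelation(t, max_lag=1000)
        assert res["r_observed"].iloc[0] == 1.0

    def test_periodic_signal_correlates_at_period(self):
        period = 10
        signal = np.tile(np.r_[np.ones(5) * 10, np.zeros(5)], 200)
        res = coverage_autocorrelation(track_from(signal), max_lag=period * 100)
        r_at_p = res.loc[res["distance"] == period * 100, "r_observed"].iloc[0]
        assert r_at_p == pytest.approx(1.0, abs=1e-9)

    def test_iid_poisson_decorrelates(self):
        signal = np.random.default_rng(1).poisson(5, 100_000)
        res = coverage_autocorrelation(track_from(signal), max_lag=2000)
        off = res.loc[res["distance"] > 0, "r_observed"]
        assert (off.abs() < 0.05).all()

    def test_shuffle_baseline_matches_iid_null(self):
        # strongly autocorrelated input: observed r high, shuffled r near 0
        blocks = np.repeat(np.random.default_rng(2).poisson(20, 500), 40)
        res = coverage_autocorrelation(track_from(blocks), max_lag=500, n_shuffles=5, seed=0)
        assert res["r_observed"].iloc[1] > 0.9
        assert res.loc[res["distance"] > 0, "r_shuffled"].abs().max() < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            coverage_autocorrelation(track_from(np.full(1000, 7)), max_lag=500)


class TestGC:
    def test_all_gc_sequence(self):
        genome = {"chr1": "GC" * 5000}
        res = gc_content_compare([GenomicInterval("chr1", 100, 300)], genome, seed=0)
        assert res["gc_in"] == 1.0

    def test_planted_at_rich_circles_detected(self):
        rng = np.random.default_rng(3)
        bases = rng.choice(list("ACGT"), size=100_000)
        cprs = []
        for k in range(20):
            s = 1000 + k * 4000
            bases[s : s + 1000] = rng.choice(list("AT"), size=1000)
            cprs.append(GenomicInterval("chr1", s, s + 1000))
        genome = {"chr1": "".join(bases)}
        res = gc_content_compare(cprs, genome, seed=1)
        assert res["gc_in"] < res["gc_out"]
        assert res["p_value"] < 1e-6

    def test_null_composition_gives_nonsignificant_p(self):
        rng = np.random.default_rng(4)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=100_000))}
        ps = []
        for seed in range(10):
            s_positions = rng.integers(0, 95_000, size=10)
            cprs = [GenomicInterval("chr1", int(s), int(s) + 500) for s in s_positions]
            ps.append(gc_content_compare(cprs, genome, seed=seed)["p_value"])
        assert min(ps) > 1e-4  # no systematic signal

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            gc_content_compare(
                [GenomicInterval("chr1", 0, 2000)], {"chr1": "A" * 1000}
            )


GENES = pd.DataFrame(
    {
        "chrom": ["chr1", "chr1"],
        "start": [10_000, 50_000],
        "end": [20_000, 58_000],
        "strand": ["+", "-"],
    }
)


class TestMetagene:
    def test_reads_only_in_flanks_leave_body_empty(self):
        mids = {"chr1": np.array([9_000, 21_000, 49_000, 59_000])}
        matrix, mean = metagene_profile(mids, GENES, body_bins=20, flank_bp=2000, flank_bins=5)
        assert matrix[:, 5:25].sum() == 0
        assert matrix.sum() == 4

    def test_mass_conservation(self):
        rng = np.random.default_rng(5)
        mids = {"chr1": rng.integers(0, 70_000, size=2000)}
        matrix, _ = metagene_profile(mids, GENES, body_bins=20, flank_bp=2000, flank_bins=5)
        in_windows = 0
        for g in GENES.itertuples():
            w0, w1 = g.start - 2000, g.end + 2000
            in_windows += int(((mids["chr1"] >= w0) & (mids["chr1"] < w1)).sum())
        assert matrix.sum() == in_windows

    def test_uniform_reads_give_flat_body(self):
        rng = np.random.default_rng(6)
        mids = {"chr1": rng.integers(10_000, 20_000, size=20_000)}
        genes = GENES.iloc[[0]]
        _, mean = metagene_profile(mids, genes, body_bins=20, flank_bp=2000, flank_bins=5)
        body = mean[5:25]
        assert body.std() / body.mean() < 0.1

    def test_minus_strand_reversed(self):
        # read near the TSS of a minus-strand gene lands at the profile start
        mids = {"chr1": np.array([57_900])}
        genes = GENES.iloc[[1]]
        matrix, _ = metagene_profile(mids, genes, body_bins=20, flank_bp=2000, flank_bins=5)
        assert matrix[0, :8].sum() == 1 and matrix[0, 8:].sum() == 0

    def test_short_gene_skipped(self):
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [10], "strand": ["+"]}
        )
        matrix, _ = metagene_profile({"chr1": np.array([5])}, genes, body_bins=20)
        assert matrix.shape[0] == 0


class TestFeatureOverlap:
    def test_genomewide_features_cover_everything(self):
        feats = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10**6]})
        cprs = {"cellA": [GenomicInterval("chr1", 100, 500)]}
        res = feature_overlap_stats(cprs, feats, circle_reads={"cellA": [10]})
        assert res["per_cell_overlap_counts"]["cellA"] == 1
        assert res["feature_fraction"] == 1.0

    def test_disjoint_features_zero_fraction(self):
        feats = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100]})
        cprs = {"cellA": [GenomicInterval("chr1", 100, 500)]}
        res = feature_overlap_stats(cprs, feats, circle_reads={"cellA": [10]})
        assert res["feature_fraction"] == 0.0

    def test_empty_feature_table_rejected(self):
        with pytest.raises(ValueError):
            feature_overlap_stats({}, pd.DataFrame(columns=["chrom", "start", "end"]))

    def test_frequency_comparison_detects_feature_biased_circles(self):
        feats = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000]})
        cprs, freq = {}, {}
        rng = np.random.default_rng(7)
        for i in range(10):
            s_on = int(rng.integers(0, 9000))
            on = GenomicInterval("chr1", s_on, s_on + 500)
            off = GenomicInterval("chr1", 20_000 + i * 1000, 20_500 + i * 1000)
            cprs[f"c{i}"] = [on, off]
            freq[(on.chrom, on.start, on.end)] = 0.8 + 0.02 * rng.random()
            freq[(off.chrom, off.start, off.end)] = 0.1 + 0.02 * rng.random()
        res = feature_overlap_stats(cprs, feats, cpr_frequency=freq)
        assert res["mean_frequency_overlapping"] > res["mean_frequency_other"]
        assert res["frequency_p_value"] < 0.01


class TestCooccurrence:
    def test_identical_column_pcc_one(self):
        m = pd.DataFrame(
            {"anchor": [1, 0, 1, 0, 1], "same": [1, 0, 1, 0, 1], "anti": [0, 1, 0, 1, 0]}
        )
        res = cooccurrence(m, ["anchor"]).set_index("cpr")
        assert res.loc["same", "pcc"] == pytest.approx(1.0)
        assert res.loc["anti", "pcc"] == pytest.approx(-1.0)
        assert bool(res.loc["same", "selected"]) is True

    def test_zero_variance_columns_excluded(self):
        m = pd.DataFrame({"anchor": [1, 0, 1], "const": [1, 1, 1]})
        res = cooccurrence(m, ["anchor"])
        assert "const" not in set(res["cpr"])

    def test_independent_columns_rarely_exceed_threshold(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(
            rng.integers(0, 2, size=(50, 200)),
            columns=[f"cpr{i}" for i in range(200)],
        )
        res = cooccurrence(m, ["cpr0"])
        others = res[res["cpr"] != "cpr0"]
        assert (others["pcc"].abs() < 0.5).mean() >= 0.95

    def test_missing_anchor_rejected(self):
        with pytest.raises(KeyError):
            cooccurrence(pd.DataFrame({"a": [1, 0]}), ["missing"])


class TestExpressionCorrelation:
    def test_proportional_gene_flagged(self):
        cells = [f"c{i}" for i in range(10)]
        reads = pd.DataFrame(
            {"coupled": np.arange(10.0), "flat": np.ones(10)}, index=cells
        )
        expr = pd.DataFrame(
            {"coupled": 3 * np.arange(10.0), "flat": np.ones(10)}, index=cells
        )
        res = expression_correlation(reads, expr, log_transform=False)
        assert set(res["gene"]) == {"coupled"}  # constant gene excluded
        assert res.iloc[0]["pcc"] == pytest.approx(1.0)
        assert bool(res.iloc[0]["flagged"]) is True

    def test_too_few_shared_cells_rejected(self):
        a = pd.DataFrame({"g": [1, 2]}, index=["c1", "c2"])
        with pytest.raises(ValueError):
            expression_correlation(a, a)


class TestCNDensity:
    def test_direct_ratio(self):
        segs = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1_000_000], "cn": [5]}
        )
        cprs = {
            "cellA": [GenomicInterval("chr1", i * 10_000, i * 10_000 + 500) for i in range(10)]
        }
        dens, _ = cn_density(cprs, segs)
        assert dens.loc["cellA", 5] == pytest.approx(1.0)  # 10 per 1 Mb = 1 per 100 kb

    def test_no_cprs_zero(self):
        segs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000], "cn": [2]})
        dens, _ = cn_density({"cellA": []}, segs)
        assert dens.loc["cellA", 2] == 0.0

    def test_invariant_to_splitting_segments(self):
        cprs = {
            "cellA": [GenomicInterval("chr1", 5_000, 5_500), GenomicInterval("chr1", 60_000, 61_000)]
        }
        whole = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000], "cn": [3]})
        split = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 40_000], "end": [40_000, 100_000], "cn": [3, 3]}
        )
        d1, _ = cn_density(cprs, whole)
        d2, _ = cn_density(cprs, split)
        assert d1.loc["cellA", 3] == pytest.approx(d2.loc["cellA", 3])

    def test_monotone_with_cn_proportional_rates(self):
        rng = np.random.default_rng(9)
        segs = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [0, 300_000, 600_000],
                "end": [300_000, 600_000, 900_000],
                "cn": [2, 4, 8],
            }
        )
        cprs = {}
        for c in range(12):
            ivs = []
            for seg in segs.itertuples():
                rate = int(seg.cn)  # circles per 100 kb proportional to CN
                n = rng.poisson(rate * 3)
                for s in rng.integers(seg.start, seg.end - 500, size=n):
                    ivs.append(GenomicInterval("chr1", int(s), int(s) + 400))
            cprs[f"c{c}"] = ivs
        dens, tests = cn_density(cprs, segs)
        means = dens.mean()
        assert means[2] < means[4] < means[8]
        assert not tests.empty


class TestDaughterDistance:
    def test_identical_vectors_zero(self):
        v = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        assert daughter_distance(v).loc["a", "b"] == 0.0

    def test_three_four_five(self):
        v = pd.DataFrame([[0.0, 3.0, 4.0], [0.0, 0.0, 0.0]], index=["a", "b"])
        assert daughter_distance(v).loc["a", "b"] == pytest.approx(5.0)

    def test_missing_cells_rejected(self):
        v = pd.DataFrame([[1.0]], index=["a"])
        with pytest.raises(KeyError):
            daughter_distance(v, pairs=[("a", "zz")])


def test_ranksum_p_matches_permutation_oracle():
    """Normal-approximation rank-sum p agrees with an exact permutation null."""
    rng = np.random.default_rng(10)
    for _ in range(3):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.8, 1, 8)
        stat, p = stats.ranksums(x, y)

        def rank_stat(a, b):
            return stats.ranksums(a, b).statistic

        perm = stats.permutation_test(
            (x, y), rank_stat, permutation_type="independent",
            n_resamples=2000, random_state=0,
        )
        assert p == pytest.approx(perm.pvalue, abs=0.05)
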