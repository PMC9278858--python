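import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import make_track
from oracles import binned_means_trapezoid, kruskal_h, pearson_r
from polterm.genome_annotation import GeneModel, TerminatorAnnotation, TTract
from polterm.rt_calling import RTRegion
from polterm.termination_stats import (
    FoldChangeTrack,
    StatsError,
    TerminationSummary,
    cluster_by_terminator_length,
    correlate_conditions,
    estimate_readthrough_fraction,
    exclude_outliers_iqr,
    gene_body_interval,
    group_tests,
    heatmap_matrix,
    log2_fold_change_track,
    metagene_matrix,
    paired_wilcoxon,
    rank_by_dependency,
    rt_index,
    summaries_to_frame,
    terminators_per_quartile,
)

CHROM = "chrT"
N = 3000


def plus_anno(gene_start=400, tract_start=500, tract_len=6, gene_id="g"):
    gene = GeneModel(gene_id, CHROM, gene_start, tract_start, "+")
    tract = TTract(CHROM, tract_start, tract_start + tract_len, "+")
    return TerminatorAnnotation(gene_id, gene, tract, 0)


def region(anno, length):
    start = anno.primary.end
    return RTRegion(anno.gene_id, CHROM, start, start + length, "+",
                    length, 1 if length else 0, length == 0)


def pair(plus_values, minus_values=None):
    if minus_values is None:
        minus_values = np.zeros(len(plus_values))
    return (make_track(plus_values, chrom=CHROM, strand="+"),
            make_track(minus_values, chrom=CHROM, strand="-"))


class TestRTIndex:
    def test_definitional_percentage(self):
        arr = np.zeros(N)
        arr[400:506] = 100 / 106  # body total 100
        arr[506:556] = 1.0        # RT total 50
        p, m = pair(arr)
        summary = rt_index(p, m, plus_anno(), region(plus_anno(), 50))
        assert summary.gene_body_signal == pytest.approx(100)
        assert summary.rt_signal == pytest.approx(50)
        assert summary.rt_index == pytest.approx(50.0)

    def test_empty_region_zero_percent(self):
        arr = np.zeros(N)
        arr[400:506] = 1.0
        p, m = pair(arr)
        summary = rt_index(p, m, plus_anno(), region(plus_anno(), 0))
        assert summary.rt_index == 0.0

    def test_zero_body_flagged(self):
        p, m = pair(np.zeros(N))
        summary = rt_index(p, m, plus_anno(), region(plus_anno(), 0))
        assert summary.rt_index is None

    def test_scale_invariance(self, rng):
        arr = np.zeros(N)
        arr[400:700] = rng.random(300) + 0.1
        p1, m1 = pair(arr)
        p2, m2 = pair(arr * 37.5)
        anno = plus_anno()
        s1 = rt_index(p1, m1, anno, region(anno, 80))
        s2 = rt_index(p2, m2, anno, region(anno, 80))
        assert s1.rt_index == pytest.approx(s2.rt_index)

    def test_gene_body_interval_minus(self):
        gene = GeneModel("g", CHROM, 500, 600, "-")
        anno = TerminatorAnnotation("g", gene, TTract(CHROM, 494, 500, "-"), 0)
        assert gene_body_interval(anno) == (494, 600)


class TestReadthroughEstimator:
    def test_uniform_dwell_closed_form(self):
        # body occupancy n, downstream occupancy f*n → estimate f exactly
        n, f = 200.0, 0.3
        arr = np.zeros(N)
        arr[400:506] = n
        arr[506:1506] = f * n
        p, m = pair(arr)
        est = estimate_readthrough_fraction(p, m, plus_anno())
        assert est == pytest.approx(f)

    def test_median_robust_to_single_pause_spike(self):
        n, f = 200.0, 0.3
        arr = np.zeros(N)
        arr[400:506] = n
        arr[506:1506] = f * n
        arr[508] = 40 * n  # pause spike inside the probe window
        p, m = pair(arr)
        est = estimate_readthrough_fraction(p, m, plus_anno())
        assert est == pytest.approx(f)

    def test_zero_body_none(self):
        p, m = pair(np.zeros(N))
        assert estimate_readthrough_fraction(p, m, plus_anno()) is None


class TestFoldChange:
    def test_equal_tracks_zero(self, rng):
        arr = rng.random(N) * 5
        a, _ = pair(arr)
        fc = log2_fold_change_track(a, a)
        assert not fc.data[CHROM].any()

    def test_double_approx_one(self):
        wt, _ = pair(np.full(N, 1000.0))
        mut, _ = pair(np.full(N, 2000.0))
        fc = log2_fold_change_track(mut, wt, pseudocount=1.0)
        assert fc.data[CHROM][0] == pytest.approx(1.0, abs=2e-3)

    def test_formula_exact(self):
        wt, _ = pair(np.array([0.0, 3.0]))
        mut, _ = pair(np.array([0.0, 7.0]))
        fc = log2_fold_change_track(mut, wt, pseudocount=1.0)
        assert fc.data[CHROM][0] == 0.0
        assert fc.data[CHROM][1] == pytest.approx(np.log2(8 / 4))

    def test_negative_pseudocount_errors(self):
        a, _ = pair(np.zeros(N))
        with pytest.raises(StatsError):
            log2_fold_change_track(a, a, pseudocount=-1)


class TestMetagene:
    def test_constant_coverage_all_bins_one(self):
        p, m = pair(np.ones(N))
        annos = [plus_anno(gene_id="a"),
                 plus_anno(gene_start=1600, tract_start=1800, gene_id="b")]
        mat = metagene_matrix(p.data, m.data, annos, body_bins=100)
        assert mat.shape == (2, 100)
        np.testing.assert_allclose(mat.to_numpy(), 1.0)

    def test_scale_invariance_double_length_gene(self):
        arr = np.full(N, 2.5)
        p, m = pair(arr)
        short = plus_anno(gene_start=400, tract_start=500, gene_id="s")
        long = plus_anno(gene_start=1000, tract_start=1200, gene_id="l")
        mat = metagene_matrix(p.data, m.data, [short, long], body_bins=50)
        np.testing.assert_allclose(mat.loc["s"], mat.loc["l"])

    def test_linear_ramp_matches_trapezoid_oracle(self):
        anno = plus_anno(gene_start=400, tract_start=500, tract_len=6)
        body_start, body_end = 400, 506
        arr = np.zeros(N)
        L = body_end - body_start
        arr[body_start:body_end] = np.arange(L) / (L - 1)
        p, m = pair(arr)
        mat = metagene_matrix(p.data, m.data, [anno], body_bins=7)
        expected = binned_means_trapezoid(arr[body_start:body_end], 7)
        np.testing.assert_allclose(mat.iloc[0].to_numpy(), expected)

    def test_minus_strand_mirrored(self):
        gene = GeneModel("g", CHROM, 500, 600, "-")
        anno = TerminatorAnnotation("g", gene, TTract(CHROM, 494, 500, "-"), 0)
        arr = np.zeros(N)
        arr[494:600] = np.linspace(1, 2, 106)  # increases toward the gene 5'
        p, m = pair(np.zeros(N), arr)
        mat = metagene_matrix(p.data, m.data, [anno], body_bins=10)
        row = mat.iloc[0].to_numpy()
        assert row[0] > row[-1]  # column 0 is 5'

    def test_gene_shorter_than_bins_fractional(self):
        anno = plus_anno(gene_start=500, tract_start=510, tract_len=4)
        arr = np.zeros(N)
        arr[500:514] = 3.0
        p, m = pair(arr)
        mat = metagene_matrix(p.data, m.data, [anno], body_bins=100)
        np.testing.assert_allclose(mat.iloc[0].to_numpy(), 3.0)

    def test_flank_bins(self):
        arr = np.zeros(N)
        arr[390:400] = 7.0
        p, m = pair(arr)
        mat = metagene_matrix(p.data, m.data, [plus_anno()], body_bins=10,
                              flank_bp=20)
        assert mat.shape == (1, 50)
        row = mat.iloc[0]
        assert row["up_-1"] == 7.0 and row["up_-20"] == 0.0

    def test_genes_without_primary_skipped(self):
        gene = GeneModel("np", CHROM, 100, 200, "+")
        bare = TerminatorAnnotation("np", gene)
        p, m = pair(np.ones(N))
        mat = metagene_matrix(p.data, m.data, [plus_anno(), bare])
        assert list(mat.index) == ["g"]


class TestHeatmap:
    def fc(self, values):
        return FoldChangeTrack("+", {CHROM: np.asarray(values, float)})

    def zero_minus(self):
        return FoldChangeTrack("-", {CHROM: np.zeros(N)})

    def test_equal_conditions_all_zero(self):
        annos = [plus_anno(gene_id="a"),
                 plus_anno(gene_start=1600, tract_start=1800, gene_id="b")]
        mat = heatmap_matrix(self.fc(np.zeros(N)), self.zero_minus(), annos)
        assert not mat.to_numpy().any()

    def test_ordering_is_permutation_sorted_by_row_mean(self):
        arr = np.zeros(N)
        arr[400:506] = 1.0   # gene a mean 1
        arr[1600:1806] = 5.0  # gene b mean 5
        annos = [plus_anno(gene_id="a"),
                 plus_anno(gene_start=1600, tract_start=1800, gene_id="b")]
        mat = heatmap_matrix(self.fc(arr), self.zero_minus(), annos)
        assert sorted(mat.index) == ["a", "b"]
        assert list(mat.index) == ["b", "a"]
        means = mat.mean(axis=1).to_numpy()
        assert all(x >= y for x, y in zip(means, means[1:]))


def quartile_annos_and_fc(scores):
    """One gene per score; fold change constant over each downstream window."""
    annos, arr = [], np.zeros(len(scores) * 2000 + 2000)
    for i, score in enumerate(scores):
        base = i * 2000
        anno = plus_anno(gene_start=base + 100, tract_start=base + 200,
                         gene_id=f"g{i:02d}")
        arr[base + 206:base + 906] = score
        annos.append(anno)
    fc_plus = FoldChangeTrack("+", {CHROM: arr})
    fc_minus = FoldChangeTrack("-", {CHROM: np.zeros_like(arr)})
    return annos, fc_plus, fc_minus


class TestDependencyRanking:
    def test_eight_distinct_scores(self):
        scores = [3.0, 7.0, 1.0, 5.0, 2.0, 8.0, 4.0, 6.0]
        annos, fp, fm = quartile_annos_and_fc(scores)
        qs = {q.gene_id: q for q in rank_by_dependency(fp, fm, annos)}
        assert {g for g, q in qs.items() if q.quartile == "Q1"} == {"g05", "g01"}
        assert {g for g, q in qs.items() if q.quartile == "Q4"} == {"g02", "g04"}

    def test_scores_recovered(self):
        scores = [3.0, 7.0, 1.0, 5.0]
        annos, fp, fm = quartile_annos_and_fc(scores)
        # window 700 covers the constant block exactly
        for q in rank_by_dependency(fp, fm, annos):
            i = int(q.gene_id[1:])
            assert q.dependency_score == pytest.approx(scores[i])

    def test_all_equal_tie_break_deterministic(self):
        annos, fp, fm = quartile_annos_and_fc([2.0] * 8)
        qs = rank_by_dependency(fp, fm, annos)
        by_gene = {q.gene_id: q.quartile for q in qs}
        # lexicographic gene_id order fills Q1..Q4
        assert by_gene["g00"] == "Q1" and by_gene["g07"] == "Q4"

    def test_matches_sort_oracle(self, rng):
        scores = list(rng.random(13) * 10)
        annos, fp, fm = quartile_annos_and_fc(scores)
        qs = rank_by_dependency(fp, fm, annos)
        ranked = sorted(range(13), key=lambda i: -scores[i])
        sizes = [4, 3, 3, 3]  # remainders to the top quartiles by rank order
        expect = {}
        pos = 0
        for qi, size in enumerate(sizes, 1):
            for i in ranked[pos:pos + size]:
                expect[f"g{i:02d}"] = f"Q{qi}"
            pos += size
        assert {q.gene_id: q.quartile for q in qs} == expect

    def test_too_few_genes(self):
        annos, fp, fm = quartile_annos_and_fc([1.0, 2.0])
        with pytest.raises(StatsError):
            rank_by_dependency(fp, fm, annos)


class TestTerminatorsPerQuartile:
    def make(self, strong_counts):
        annos = []
        for i, n_strong in enumerate(strong_counts):
            anno = plus_anno(gene_start=100, tract_start=200,
                             gene_id=f"g{i:02d}")
            anno.secondary = [
                TTract(CHROM, 300 + 10 * j, 306 + 10 * j, "+")
                for j in range(n_strong)
            ]
            annos.append(anno)
        from polterm.termination_stats import QuartileAssignment
        qs = [QuartileAssignment(f"g{i:02d}", 0.0, f"Q{i % 4 + 1}")
              for i in range(len(strong_counts))]
        return qs, annos

    def test_all_genes_two_strong(self):
        qs, annos = self.make([2] * 8)
        table = terminators_per_quartile(qs, annos)
        strong = table[table["kind"] == "strong"]
        assert (strong["mean"] == 2).all()
        assert (strong["se"] == 0).all()

    def test_single_gene_quartile_se_flagged(self):
        qs, annos = self.make([1, 2, 3, 0])
        table = terminators_per_quartile(qs, annos)
        assert table["se"].isna().all()
        assert (table["n"] == 1).all()

    def test_hand_means(self):
        qs, annos = self.make([0, 1, 2, 3, 4, 1, 2, 3])
        table = terminators_per_quartile(qs, annos)
        q1 = table[(table["quartile"] == "Q1") & (table["kind"] == "strong")]
        assert q1["mean"].iloc[0] == pytest.approx((0 + 4) / 2)

    def test_empty_quartile_errors(self):
        qs, annos = self.make([1, 2])
        with pytest.raises(StatsError, match="empty quartile"):
            terminators_per_quartile(qs, annos)


class TestGroupTests:
    def test_h_matches_rank_formula(self):
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        res = group_tests(groups)
        assert res["kruskal_H"] == pytest.approx(kruskal_h(groups))

    def test_h_matches_rank_formula_with_ties(self, rng):
        groups = {
            "a": list(rng.integers(0, 4, 10)),
            "b": list(rng.integers(0, 4, 12)),
            "c": list(rng.integers(1, 5, 9)),
        }
        res = group_tests(groups)
        assert res["kruskal_H"] == pytest.approx(kruskal_h(groups))

    def test_identical_groups_pairwise_p_one(self):
        res = group_tests({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert res["pairwise"][("a", "b")] == pytest.approx(1.0, abs=0.05)

    def test_label_permutation_invariance(self):
        g1 = {"a": [1, 5, 3], "b": [2, 8, 4], "c": [9, 6, 7]}
        g2 = {"a": [9, 6, 7], "b": [1, 5, 3], "c": [2, 8, 4]}
        assert group_tests(g1)["kruskal_H"] == pytest.approx(
            group_tests(g2)["kruskal_H"])

    def test_all_identical_flagged(self):
        res = group_tests({"a": [2, 2], "b": [2, 2]})
        assert res["defined"] is False

    def test_requires_nonempty_groups(self):
        with pytest.raises(StatsError):
            group_tests({"a": [1.0], "b": []})


class TestPairedWilcoxon:
    def test_matches_scipy(self, rng):
        a = rng.random(30)
        b = a + rng.normal(0.2, 0.1, 30)
        res = paired_wilcoxon(a, b)
        ref = sps.wilcoxon(a, b)
        assert res["pvalue"] == pytest.approx(ref.pvalue)

    def test_identical_flagged(self):
        res = paired_wilcoxon([1, 2], [1, 2])
        assert np.isnan(res["pvalue"])


def summary(gene_id, rt_idx, tract_len, condition="WT", rt_len=0):
    return TerminationSummary(gene_id, condition, 100.0, rt_idx, rt_idx,
                              rt_len, tract_len, 0, 0)


class TestClusterByLength:
    def test_single_class_overall_mean(self):
        summaries = [summary(f"g{i}", 10.0 + i, 5) for i in range(4)]
        table = cluster_by_terminator_length(summaries)
        assert len(table) == 1
        assert table["mean_rt_index"].iloc[0] == pytest.approx(11.5)

    def test_hand_means_and_pooling(self):
        summaries = [summary("a", 10, 4), summary("b", 20, 4),
                     summary("c", 5, 9), summary("d", 15, 12)]
        table = cluster_by_terminator_length(summaries, pool_from=8)
        by = dict(zip(table["tract_len"], table["mean_rt_index"]))
        assert by["4"] == pytest.approx(15.0)
        assert by[">=8"] == pytest.approx(10.0)

    def test_equal_indices_se_zero(self):
        summaries = [summary(f"g{i}", 7.0, 6) for i in range(5)]
        table = cluster_by_terminator_length(summaries)
        assert table["se"].iloc[0] == 0.0

    def test_undefined_rt_index_excluded(self):
        s = summary("a", 10, 4)
        bad = TerminationSummary("b", "WT", 0.0, 0.0, None, 0, 4, 0, 0)
        table = cluster_by_terminator_length([s, bad])
        assert table["n"].iloc[0] == 1


class TestCorrelateConditions:
    def test_identical_r_one(self):
        a = [summary(f"g{i}", float(i + 1), 5) for i in range(5)]
        b = [summary(f"g{i}", float(i + 1), 5, "mut") for i in range(5)]
        assert correlate_conditions(a, b)["r"] == pytest.approx(1.0)

    def test_antiordered_r_minus_one(self):
        a = [summary(f"g{i}", float(i), 5) for i in range(5)]
        b = [summary(f"g{i}", float(-2 * i), 5, "mut") for i in range(5)]
        assert correlate_conditions(a, b)["r"] == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, rng):
        xs, ys = rng.random(20), rng.random(20)
        a = [summary(f"g{i}", float(xs[i]), 5) for i in range(20)]
        b = [summary(f"g{i}", float(ys[i]), 5, "mut") for i in range(20)]
        res = correlate_conditions(a, b)
        assert res["r"] == pytest.approx(pearson_r(xs, ys))

    def test_constant_flagged(self):
        a = [summary(f"g{i}", 1.0, 5) for i in range(5)]
        b = [summary(f"g{i}", float(i), 5, "mut") for i in range(5)]
        assert correlate_conditions(a, b)["defined"] is False

    def test_rt_length_metric(self):
        a = [summary(f"g{i}", 1.0, 5, rt_len=i * 10) for i in range(5)]
        b = [summary(f"g{i}", 1.0, 5, "mut", rt_len=i * 20) for i in range(5)]
        assert correlate_conditions(a, b, "rt_length")["r"] == pytest.approx(1.0)

    def test_unknown_metric(self):
        with pytest.raises(StatsError):
            correlate_conditions([], [], "nope")


class TestMisc:
    def test_outlier_exclusion_keeps_bulk(self):
        vals = list(range(20)) + [1000.0]
        kept = exclude_outliers_iqr(vals)
        assert 1000.0 not in kept
        assert len(kept) == 20

    def test_summaries_frame_schema(self):
        frame = summaries_to_frame([summary("a", 10.0, 5)])
        assert list(frame.columns)[:4] == [
            "gene_id", "condition", "gene_body_signal", "rt_signal"]
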