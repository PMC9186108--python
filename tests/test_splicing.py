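"""Unit tests for junction filtering, intron clustering and cryptic events."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rnalof.splicing import (
    JUNCTION_COLUMNS,
    CrypticEvent,
    cluster_introns,
    detect_event_across_samples,
    differential_cluster_usage,
    filter_junctions,
    quantify_cryptic_event,
)


def make_junctions(rows):
    """rows: (chrom, start, end, strand, sample_id, count, min_anchor)"""
    return pd.DataFrame(rows, columns=JUNCTION_COLUMNS)


class TestFilterJunctions:
    def test_anchor_boundary_six_retained_five_removed(self):
        j = make_junctions(
            [
                ("chr1", 100, 200, "+", "s1", 10, 5),
                ("chr1", 100, 200, "+", "s1", 10, 6),
                ("chr1", 100, 300, "+", "s1", 10, 7),
            ]
        )
        out = filter_junctions(j, min_anchor=6)
        assert len(out) == 2
        assert (out["min_anchor"] >= 6).all()

    def test_empty_input_empty_output(self):
        out = filter_junctions(make_junctions([]))
        assert out.empty

    def test_min_count(self):
        j = make_junctions([("chr1", 1, 2, "+", "s", 0, 10), ("chr1", 1, 2, "+", "s", 3, 10)])
        assert len(filter_junctions(j, min_count=1)) == 1


class TestClusterIntrons:
    def test_shared_start_clusters_together(self):
        j = make_junctions(
            [
                ("chr1", 100, 200, "+", "s1", 6, 8),
                ("chr1", 100, 300, "+", "s1", 6, 8),
            ]
        )
        clusters = cluster_introns(j, minclureads=10)
        assert len(clusters) == 1
        assert clusters[0].junctions == ((100, 200), (100, 300))
        assert clusters[0].total_reads == 12

    def test_below_minclureads_dropped(self):
        j = make_junctions([("chr1", 100, 200, "+", "s1", 9, 8)])
        assert cluster_introns(j, minclureads=10) == []
        assert len(cluster_introns(j, minclureads=9)) == 1

    def test_opposite_strands_never_merge(self):
        j = make_junctions(
            [
                ("chr1", 100, 200, "+", "s1", 20, 8),
                ("chr1", 100, 200, "-", "s1", 20, 8),
            ]
        )
        clusters = cluster_introns(j, minclureads=10)
        assert len(clusters) == 2
        assert {c.strand for c in clusters} == {"+", "-"}

    def test_transitive_connectivity_through_shared_end(self):
        # A shares start with B; B shares end with C -> one cluster of three
        j = make_junctions(
            [
                ("chr1", 100, 200, "+", "s1", 5, 8),
                ("chr1", 100, 400, "+", "s1", 5, 8),
                ("chr1", 300, 400, "+", "s1", 5, 8),
            ]
        )
        clusters = cluster_introns(j, minclureads=10)
        assert len(clusters) == 1
        assert len(clusters[0].junctions) == 3

    def test_partition_and_read_conservation(self, rng):
        starts = rng.integers(0, 50, size=40) * 100
        j = make_junctions(
            [
                ("chr1", int(s), int(s + 100 + 100 * (i % 3)), "+", f"s{i % 2}", int(rng.integers(1, 20)), 8)
                for i, s in enumerate(starts)
            ]
        )
        clusters = cluster_introns(j, minclureads=0)
        seen = [jn for c in clusters for jn in c.junctions]
        pooled = j.groupby(["start", "end"])["count"].sum()
        assert sorted(seen) == sorted(set(pooled.index))  # partition: each junction once
        assert sum(c.total_reads for c in clusters) == j["count"].sum()

    def test_deterministic_ids(self):
        j = make_junctions(
            [
                ("chr2", 500, 600, "+", "s1", 20, 8),
                ("chr1", 100, 200, "+", "s1", 20, 8),
            ]
        )
        clusters = cluster_introns(j)
        assert [c.cluster_id for c in clusters] == ["clu_1", "clu_2"]
        assert clusters[0].chrom == "chr1"  # sorted by chrom then start


class TestDifferentialClusterUsage:
    def _clusters(self, wt_counts, mut_counts):
        j = make_junctions(
            [("chr1", 100, 200 + 100 * i, "+", "wt_1", c, 8) for i, c in enumerate(wt_counts)]
            + [("chr1", 100, 200 + 100 * i, "+", "mut_1", c, 8) for i, c in enumerate(mut_counts)]
        )
        return cluster_introns(j, minclureads=0)

    def test_identical_proportions_give_p_one(self):
        clusters = self._clusters([90, 10], [90, 10])
        res = differential_cluster_usage(clusters, {"wt_1": "wt", "mut_1": "mut"})
        assert res["g_statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_g_statistic_matches_hand_computed_llr(self):
        # 2x2 table WT (90, 10) vs MUT (10, 90): brute-force LLR
        table = np.array([[90.0, 10.0], [10.0, 90.0]])
        expected = table.sum(axis=1)[:, None] * table.sum(axis=0)[None, :] / table.sum()
        g_oracle = 2.0 * (table * np.log(table / expected)).sum()
        clusters = self._clusters([90, 10], [10, 90])
        res = differential_cluster_usage(clusters, {"wt_1": "wt", "mut_1": "mut"})
        assert res["g_statistic"].iloc[0] == pytest.approx(g_oracle, rel=1e-12)
        assert res["p_value"].iloc[0] == pytest.approx(stats.chi2.sf(g_oracle, 1), rel=1e-12)
        assert res["significant"].iloc[0]

    def test_proportions_sum_to_one_per_condition(self):
        clusters = self._clusters([30, 10, 60], [10, 80, 10])
        from rnalof.splicing import DifferentialClusterUsage

        est = DifferentialClusterUsage().fit(clusters, {"wt_1": "wt", "mut_1": "mut"})
        props = est.proportions_
        assert props["prop_wt"].sum() == pytest.approx(1.0)
        assert props["prop_mut"].sum() == pytest.approx(1.0)

    def test_singleton_cluster_untested(self):
        j = make_junctions([("chr1", 1, 100, "+", "wt_1", 50, 8), ("chr1", 1, 100, "+", "mut_1", 50, 8)])
        clusters = cluster_introns(j)
        res = differential_cluster_usage(clusters, {"wt_1": "wt", "mut_1": "mut"})
        assert not res["tested"].iloc[0]
        assert math.isnan(res["p_value"].iloc[0])

    def test_single_condition_rejected(self):
        clusters = self._clusters([1, 2], [3, 4])
        with pytest.raises(ValueError, match="two conditions"):
            differential_cluster_usage(clusters, {"wt_1": "wt", "mut_1": "wt"})


EVENT = CrypticEvent(
    event_id="E", chrom="chr1", strand="+", canonical=(100, 500), cryptic=((100, 250), (300, 500))
)


class TestCrypticQuantification:
    def _table(self, canonical, cr1, cr2, sample="s1"):
        rows = []
        if canonical:
            rows.append(("chr1", 100, 500, "+", sample, canonical, 8))
        if cr1:
            rows.append(("chr1", 100, 250, "+", sample, cr1, 8))
        if cr2:
            rows.append(("chr1", 300, 500, "+", sample, cr2, 8))
        return make_junctions(rows)

    def test_no_cryptic_reads_zero_percent(self):
        canonical, cryptic, percent = quantify_cryptic_event(self._table(50, 0, 0), EVENT, "s1")
        assert canonical == 50 and percent == 0.0

    def test_equal_support_fifty_percent(self):
        single = CrypticEvent("E1", "chr1", "+", (100, 500), ((100, 250),))
        _, _, percent = quantify_cryptic_event(self._table(30, 30, 0), single, "s1")
        assert percent == pytest.approx(50.0)

    def test_mean_vs_sum_combination(self):
        canonical, cryptic, p_mean = quantify_cryptic_event(self._table(30, 30, 30), EVENT, "s1")
        assert p_mean == pytest.approx(50.0)  # mean of the two CE junctions = 30
        _, _, p_sum = quantify_cryptic_event(self._table(30, 30, 30), EVENT, "s1", combine="sum")
        assert p_sum == pytest.approx(100 * 60 / 90)

    def test_no_evidence_is_undefined(self):
        _, _, percent = quantify_cryptic_event(self._table(0, 0, 0), EVENT, "s1")
        assert math.isnan(percent)

    def test_absent_coordinates_count_zero_not_error(self):
        other = CrypticEvent("X", "chr9", "+", (1, 2), ((1, 3),))
        canonical, cryptic, percent = quantify_cryptic_event(self._table(10, 10, 10), other, "s1")
        assert canonical == 0 and math.isnan(percent)


class TestDetectAcrossSamples:
    def test_detection_counts_and_exclusion(self):
        rows = []
        # wt: canonical only; mut_1 cryptic; mut_2 nothing at all
        rows += [("chr1", 100, 500, "+", "wt_1", 40, 8)]
        rows += [("chr1", 100, 500, "+", "mut_1", 20, 8), ("chr1", 100, 250, "+", "mut_1", 20, 8),
                 ("chr1", 300, 500, "+", "mut_1", 20, 8)]
        table, detection = detect_event_across_samples(
            make_junctions(rows), EVENT, {"wt_1": "wt", "mut_1": "mut", "mut_2": "mut"}
        )
        assert detection == {"wt": 0, "mut": 1}
        assert table.loc["mut_1", "percent_cryptic"] == pytest.approx(50.0)
        assert table.loc["mut_2", "excluded"]  # zero canonical reads
        assert math.isnan(table.loc["mut_2", "percent_cryptic"])
        assert not table.loc["wt_1", "detected"]
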