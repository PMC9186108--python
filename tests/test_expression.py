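"""Unit tests for normalization, DEG calling, concordance and PCA projection."""

import numpy as np
import pandas as pd
import pytest

from rnalof.expression import (
    ReferencePCA,
    bh_adjust,
    differential_expression,
    fit_reference_pca,
    fold_change_concordance,
    normalize_counts,
    project_samples,
)


def counts_frame(data, samples=None):
    df = pd.DataFrame(data)
    df.index = pd.Index([f"g{i}" for i in range(len(df))], name="gene_id")
    if samples:
        df.columns = samples
    return df


class TestNormalization:
    def test_identical_samples_unit_factors(self):
        counts = counts_frame({"a": [10, 20, 30], "b": [10, 20, 30]})
        _, sf = normalize_counts(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_factor_ratio_two(self):
        counts = counts_frame({"a": [10, 20, 30], "b": [20, 40, 60]})
        normalized, sf = normalize_counts(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        pd.testing.assert_series_equal(normalized["a"], normalized["b"], check_names=False)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_counts(pd.DataFrame())

    def test_no_allpositive_gene_rejected_with_guidance(self):
        counts = counts_frame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="positive counts in every sample"):
            normalize_counts(counts)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_stepup(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_order_preserved(self):
        p = [0.9, 0.001, 0.5]
        adj = bh_adjust(p)
        assert adj[1] == adj.min()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([np.nan])


class TestDifferentialExpression:
    def test_identical_groups_no_degs(self, rng):
        base = rng.poisson(100, size=(50, 3))
        counts = counts_frame(np.hstack([base, base]), samples=["a1", "a2", "a3", "b1", "b2", "b3"])
        groups = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
        res = differential_expression(counts, groups)
        assert np.allclose(res["log2fc"], 0.0)
        assert not res["deg"].any()

    def test_both_cutoffs_required(self, rng):
        # 10 genes get a tiny but extremely consistent shift (factor 1.12,
        # |log2FC| ~ 0.16 < 0.25) against a stable background: padj is small
        # but the fold-change cutoff must still block the DEG flag
        a = np.tile([1000, 1001, 999], (40, 1)) + rng.integers(0, 2, size=(40, 3))
        b = a.copy()
        b[:10] = (b[:10] * 1.12).astype(int)
        counts = counts_frame(np.hstack([a, b]), samples=["a1", "a2", "a3", "b1", "b2", "b3"])
        groups = {s: s[0] for s in counts.columns}
        res = differential_expression(counts, groups)
        small_fc_significant = (res["p_adj"] < 0.05) & (np.abs(res["log2fc"]) <= 0.25)
        assert small_fc_significant.any()          # significance alone occurs
        assert not res.loc[small_fc_significant, "deg"].any()  # but never flags a DEG
        assert (res["deg"] == ((res["p_adj"] < 0.05) & (np.abs(res["log2fc"]) > 0.25))).all()

    def test_fewer_than_two_replicates_rejected(self):
        counts = counts_frame({"a1": [10] * 5, "b1": [10] * 5, "b2": [10] * 5})
        with pytest.raises(ValueError, match="two replicates"):
            differential_expression(counts, {"a1": "A", "b1": "B", "b2": "B"})

    def test_sign_convention_alt_over_ref(self):
        a = np.tile([100], (20, 3))
        b = np.tile([400], (20, 3))
        counts = counts_frame(np.hstack([a, b]), samples=["a1", "a2", "a3", "b1", "b2", "b3"])
        res = differential_expression(counts, {s: s[0] for s in counts.columns})
        # normalization absorbs a global shift, so test relative direction only
        assert res.columns.str.contains("mean_a").any()


class TestConcordance:
    def _contrast(self, lfcs):
        return pd.DataFrame({"log2fc": lfcs}, index=pd.Index([f"g{i}" for i in range(len(lfcs))], name="gene_id"))

    def test_self_correlation_is_one(self, rng):
        c = self._contrast(rng.normal(size=30))
        rep = fold_change_concordance(c, c, c.index)
        assert rep.r == pytest.approx(1.0)

    def test_anti_correlation_is_minus_one(self, rng):
        c = self._contrast(rng.normal(size=30))
        rep = fold_change_concordance(c, -c, c.index)
        assert rep.r == pytest.approx(-1.0)

    def test_symmetry_and_order_invariance(self, rng):
        a = self._contrast(rng.normal(size=30))
        b = self._contrast(rng.normal(size=30))
        genes = list(a.index)
        r1 = fold_change_concordance(a, b, genes).r
        r2 = fold_change_concordance(b, a, genes).r
        r3 = fold_change_concordance(a, b, genes[::-1]).r
        assert r1 == pytest.approx(r2) == pytest.approx(r3)

    def test_exclusion_removes_genes(self, rng):
        a = self._contrast(rng.normal(size=10))
        b = self._contrast(rng.normal(size=10))
        rep = fold_change_concordance(a, b, a.index, exclude={"g0"})
        assert rep.n_genes == 9 and "g0" in rep.excluded

    def test_missing_fold_changes_dropped_with_count(self, rng):
        a = self._contrast(rng.normal(size=10))
        b = self._contrast(rng.normal(size=10))
        b.loc["g3", "log2fc"] = np.nan
        rep = fold_change_concordance(a, b, a.index)
        assert rep.n_genes == 9 and rep.n_dropped == 1

    def test_too_few_genes_rejected(self):
        a = self._contrast([1.0, 2.0])
        with pytest.raises(ValueError, match="at least 3"):
            fold_change_concordance(a, a, a.index)


class TestReferencePCA:
    def _reference(self, rng, n_genes=40, n_samples=6):
        counts = rng.poisson(200, size=(n_genes, n_samples))
        return counts_frame(counts, samples=[f"r{i}" for i in range(n_samples)])

    def test_round_trip_reproduces_reference_scores(self, rng):
        ref = self._reference(rng)
        pca = fit_reference_pca(ref, list(ref.index[:20]), k=2)
        reproj = project_samples(pca, ref)
        assert np.abs(reproj.to_numpy() - pca.scores_.to_numpy()).max() < 1e-8

    def test_reference_means_project_to_origin(self, rng):
        ref = self._reference(rng)
        pca = fit_reference_pca(ref, list(ref.index[:20]), k=2)
        logged_means = pd.DataFrame({"q": pca.gene_means_})
        scores = pca.project_logged(logged_means)
        assert np.allclose(scores.to_numpy(), 0.0, atol=1e-10)

    def test_k_exceeding_rank_rejected(self, rng):
        ref = self._reference(rng, n_samples=3)
        with pytest.raises(ValueError, match="exceeds"):
            fit_reference_pca(ref, list(ref.index[:20]), k=3)

    def test_gene_subset_smaller_than_k_rejected(self, rng):
        ref = self._reference(rng)
        with pytest.raises(ValueError, match="exceeds"):
            fit_reference_pca(ref, list(ref.index[:1]), k=2)

    def test_missing_query_genes_listed(self, rng):
        ref = self._reference(rng)
        pca = fit_reference_pca(ref, list(ref.index[:20]), k=2)
        query = ref.drop(index=["g3"])
        with pytest.raises(ValueError, match="g3"):
            pca.transform(query)

    def test_planted_separation_appears_on_pc1(self, rng):
        n_genes = 60
        base = rng.poisson(300, size=(n_genes, 8)).astype(float)
        base[:20, 4:] *= 4.0  # strong group effect on 20 axis genes
        ref = counts_frame(base.astype(int), samples=[f"r{i}" for i in range(8)])
        pca = ReferencePCA(genes=list(ref.index), n_components=2).fit(ref)
        pc1 = pca.scores_["PC1"]
        assert abs(pc1[:4].mean() - pc1[4:].mean()) > 3 * max(pc1[:4].std(), pc1[4:].std())
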