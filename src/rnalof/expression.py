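"""Differential expression and loss-of-function phenocopy scoring.

Gene-level counts are normalized with median-of-ratios size factors and
tested for differential expression with a Welch t-test on
log2(normalized + 1); genes are called differentially expressed when
both a BH-adjusted p-value cutoff (default 0.05) and a |log2 fold
change| cutoff (default 0.25) are met. This is a deliberately simple
stand-in for a negative-binomial GLM: the reusable content is the
normalization, the double cutoff and the downstream comparison logic,
not the count model.

Phenocopy similarity between two contrasts (e.g. mutant-vs-wild-type
against knock-down-vs-control) is scored two ways:

* Pearson correlation of log2 fold changes over a shared gene universe,
  optionally excluding genes whose behaviour is known to diverge — the
  autoregulated TARDBP transcript rises when the protein is mutated but
  falls when the gene is knocked down, so it is excluded before
  computing r;
* principal-component analysis fit on reference samples restricted to a
  DEG-intersection gene set, with query samples projected through the
  stored transform (normalization -> log2 -> gene centering -> loadings),
  never re-centered on the query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "MedianOfRatiosNormalizer",
    "normalize_counts",
    "bh_adjust",
    "WelchDE",
    "differential_expression",
    "SimilarityReport",
    "fold_change_concordance",
    "ReferencePCA",
    "fit_reference_pca",
    "project_samples",
]


class MedianOfRatiosNormalizer(TransformerMixin, BaseEstimator):
    """Median-of-ratios library-size normalization.

    ``fit`` stores the per-gene geometric means (over genes with strictly
    positive counts in every fitting sample); ``transform`` computes each
    sample's size factor as the median count-to-reference ratio over
    those genes and divides the sample by it. Because the reference is
    frozen at fit time, transforming new samples is consistent with the
    fitting set — required for out-of-sample PCA projection.
    """

    def fit(self, counts: pd.DataFrame, y=None) -> "MedianOfRatiosNormalizer":
        counts = self._validate(counts)
        positive = (counts > 0).all(axis=1)
        if not positive.any():
            raise ValueError(
                "no gene has positive counts in every sample; median-of-ratios "
                "normalization needs at least one such gene (check for empty "
                "samples or filter the matrix first)"
            )
        self.ref_genes_ = counts.index[positive]
        self.log_ref_means_ = np.log(counts.loc[positive]).mean(axis=1)
        self.size_factors_ = self._factors(counts)
        return self

    def _validate(self, counts: pd.DataFrame) -> pd.DataFrame:
        if counts.empty:
            raise ValueError("count matrix is empty")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        return counts

    def _factors(self, counts: pd.DataFrame) -> pd.Series:
        missing = self.ref_genes_.difference(counts.index)
        if len(missing):
            raise ValueError(f"counts lack {len(missing)} reference genes, e.g. {list(missing[:5])}")
        sub = counts.loc[self.ref_genes_]
        with np.errstate(divide="ignore"):
            log_ratios = np.log(sub).sub(self.log_ref_means_, axis=0)
        # a query sample may have zero counts at some reference genes;
        # those ratios are dropped rather than poisoning the median
        factors = np.exp(np.nanmedian(log_ratios.replace(-np.inf, np.nan), axis=0))
        return pd.Series(factors, index=counts.columns, name="size_factor")

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        counts = self._validate(counts)
        return counts.div(self._factors(counts), axis=1)


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Normalize a count matrix; returns (normalized matrix, size factors)."""
    norm = MedianOfRatiosNormalizer().fit(counts)
    return norm.transform(counts), norm.size_factors_


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    Output order matches input order; ties are preserved.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1] and be non-missing")
    return multipletests(p, method="fdr_bh")[1]


class WelchDE(BaseEstimator):
    """Two-condition differential-expression caller.

    Counts are median-of-ratios normalized; per gene the two conditions
    are compared with a two-sided Welch t-test on log2(normalized + 1),
    p-values BH-adjusted across genes, and the fold change computed as
    log2((mean2 + c) / (mean1 + c)) on normalized means with pseudocount
    ``c`` (default 1). A gene is flagged DEG only when padj < alpha AND
    |log2FC| > lfc_cut — both cutoffs, never one.
    """

    def __init__(self, alpha: float = 0.05, lfc_cut: float = 0.25, pseudocount: float = 1.0):
        self.alpha = alpha
        self.lfc_cut = lfc_cut
        self.pseudocount = pseudocount

    def fit(self, counts: pd.DataFrame, groups: dict[str, str]) -> "WelchDE":
        conditions = list(dict.fromkeys(groups.values()))
        if len(conditions) != 2:
            raise ValueError(f"exactly two conditions required, got {conditions}")
        ref, alt = conditions
        samples_a = [s for s in counts.columns if groups.get(s) == ref]
        samples_b = [s for s in counts.columns if groups.get(s) == alt]
        if len(samples_a) < 2 or len(samples_b) < 2:
            raise ValueError("each condition needs at least two replicates")
        normalized, size_factors = normalize_counts(counts[samples_a + samples_b])
        logged = np.log2(normalized + 1.0)
        a = logged[samples_a].to_numpy()
        b = logged[samples_b].to_numpy()
        mean_a = normalized[samples_a].mean(axis=1)
        mean_b = normalized[samples_b].mean(axis=1)
        c = self.pseudocount
        lfc = np.log2((mean_b + c) / (mean_a + c))
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        degenerate = np.isnan(p)  # zero variance in both groups
        if degenerate.any():
            equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
            p[degenerate] = np.where(equal[degenerate], 1.0, 0.0)
        padj = bh_adjust(p)
        deg = (padj < self.alpha) & (np.abs(lfc) > self.lfc_cut)
        self.conditions_ = (ref, alt)
        self.size_factors_ = size_factors
        self.results_ = pd.DataFrame(
            {
                "base_mean": (mean_a + mean_b) / 2.0,
                f"mean_{ref}": mean_a,
                f"mean_{alt}": mean_b,
                "log2fc": lfc,  # alt over ref
                "p_value": p,
                "p_adj": padj,
                "deg": deg,
            },
            index=counts.index,
        )
        self.results_.index.name = "gene_id"
        return self


def differential_expression(
    counts: pd.DataFrame,
    groups: dict[str, str],
    alpha: float = 0.05,
    lfc_cut: float = 0.25,
    **kwargs,
) -> pd.DataFrame:
    """Functional wrapper over :class:`WelchDE`."""
    return WelchDE(alpha=alpha, lfc_cut=lfc_cut, **kwargs).fit(counts, groups).results_


@dataclass
class SimilarityReport:
    """Fold-change concordance between two contrasts."""

    r: float
    p_value: float
    n_genes: int
    excluded: tuple[str, ...]
    n_dropped: int
    slope: float
    intercept: float


def fold_change_concordance(
    contrast_a: pd.DataFrame,
    contrast_b: pd.DataFrame,
    gene_universe,
    exclude=(),
) -> SimilarityReport:
    """Pearson correlation of log2 fold changes over a gene universe.

    Both contrasts must carry a ``log2fc`` column indexed by gene.
    Genes in ``exclude`` are removed before correlating (the classic case
    is the autoregulated TARDBP gene, which moves opposite ways under
    mutation and knock-down); genes missing a finite fold change in
    either contrast are dropped with a logged count.
    """
    exclude = set(exclude)
    universe = [g for g in gene_universe if g not in exclude]
    fa = contrast_a["log2fc"].reindex(universe)
    fb = contrast_b["log2fc"].reindex(universe)
    ok = fa.notna() & fb.notna() & np.isfinite(fa) & np.isfinite(fb)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("fold_change_concordance: dropped %d genes without a fold change in both contrasts", n_dropped)
    x, y = fa[ok].to_numpy(), fb[ok].to_numpy()
    if x.size < 3:
        raise ValueError(f"need at least 3 paired genes to correlate, got {x.size}")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return SimilarityReport(
        r=float(r),
        p_value=float(p),
        n_genes=int(x.size),
        excluded=tuple(sorted(exclude)),
        n_dropped=n_dropped,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


class ReferencePCA(BaseEstimator):
    """PCA fit on reference samples with out-of-sample projection.

    The transform pipeline is: median-of-ratios normalization (reference
    frozen at fit), log2(normalized + 1) as the variance-stabilizing
    stand-in, restriction to a fixed gene subset (typically a
    DEG-list intersection), gene-wise centering on the reference means,
    then projection onto the SVD loadings of the centered reference.
    Query samples reuse every stored piece — they are never re-centered
    or re-fit — so projecting a reference sample reproduces its own
    score exactly.
    """

    def __init__(self, genes=None, n_components: int = 2):
        self.genes = genes
        self.n_components = n_components

    def fit(self, counts: pd.DataFrame, y=None) -> "ReferencePCA":
        genes = list(self.genes) if self.genes is not None else list(counts.index)
        missing = [g for g in genes if g not in counts.index]
        if missing:
            raise ValueError(f"gene subset not in reference matrix: {missing[:10]}")
        n_samples = counts.shape[1]
        max_rank = min(len(genes), n_samples - 1)
        if self.n_components > max_rank:
            raise ValueError(
                f"n_components={self.n_components} exceeds the maximum rank "
                f"{max_rank} ({n_samples} reference samples, {len(genes)} genes)"
            )
        self.normalizer_ = MedianOfRatiosNormalizer().fit(counts)
        logged = np.log2(self.normalizer_.transform(counts) + 1.0)
        X = logged.loc[genes].T  # samples x genes
        self.genes_ = list(genes)
        self._pca = PCA(n_components=self.n_components, svd_solver="full").fit(X)
        self.gene_means_ = pd.Series(self._pca.mean_, index=self.genes_)
        self.loadings_ = pd.DataFrame(
            self._pca.components_.T,
            index=self.genes_,
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        self.scores_ = pd.DataFrame(
            self._pca.transform(X), index=counts.columns, columns=self.loadings_.columns
        )
        return self

    def project_logged(self, logged: pd.DataFrame) -> pd.DataFrame:
        """Project already log-transformed samples (genes x samples)."""
        missing = [g for g in self.genes_ if g not in logged.index]
        if missing:
            raise ValueError(f"query lacks genes required by the PCA: {missing[:10]}")
        X = logged.loc[self.genes_].T
        return pd.DataFrame(
            self._pca.transform(X), index=logged.columns, columns=self.loadings_.columns
        )

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        """Normalize, log-transform and project query samples (genes x samples)."""
        logged = np.log2(self.normalizer_.transform(counts) + 1.0)
        return self.project_logged(logged)


def fit_reference_pca(counts: pd.DataFrame, deg_intersection, k: int = 2) -> ReferencePCA:
    """Fit a :class:`ReferencePCA` on reference samples over a gene subset."""
    return ReferencePCA(genes=deg_intersection, n_components=k).fit(counts)


def project_samples(pca: ReferencePCA, query_counts: pd.DataFrame) -> pd.DataFrame:
    """Project query samples through a fitted reference PCA."""
    return pca.transform(query_counts)
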