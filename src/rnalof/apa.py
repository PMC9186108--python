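"""Alternative-polyadenylation usage: the gene-level Psi metric.

A gene with several polyadenylation sites (PAS) distributes its
transcripts over 3'UTR isoforms of different lengths. Ordering the sites
proximal to distal along the transcribed strand and indexing them
m = 1..n, gene-level usage is summarized as the expression-weighted mean
of the normalized rank:

    Psi = sum_m TPM_m * (m - 1) / (n - 1)  /  sum_m TPM_m

so Psi = 0 means exclusive use of the most proximal site, Psi = 1
exclusive use of the most distal site, and intermediate values a mixture.
Psi is undefined for single-site genes (n = 1) and for genes with zero
retained expression; both are reported as NaN, never silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "PASAnnotation",
    "order_pas",
    "filter_pas_by_expression",
    "compute_psi",
    "compute_psi_table",
    "DifferentialPsi",
    "differential_psi",
]


@dataclass(frozen=True)
class PASAnnotation:
    """A gene's set of polyadenylation sites.

    Positions are 1-based genomic coordinates of cleavage sites. After
    :func:`order_pas`, ``pas_positions[m - 1]`` is the site with
    proximal-to-distal index m.
    """

    gene_id: str
    chrom: str
    strand: str
    pas_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.pas_positions:
            raise ValueError(f"{self.gene_id}: PAS position list must be non-empty")
        if len(set(self.pas_positions)) != len(self.pas_positions):
            raise ValueError(f"{self.gene_id}: PAS positions must be distinct")

    @property
    def n(self) -> int:
        """Number of distinct PAS in the gene."""
        return len(self.pas_positions)


def order_pas(annotation: PASAnnotation) -> PASAnnotation:
    """Index a gene's PAS proximal to distal along the transcribed strand.

    On "+" the most proximal site (m = 1) has the smallest genomic
    coordinate; on "-" transcription runs right to left, so the ordering
    is by descending coordinate. An unknown strand leaves the ordering
    undecidable and raises.
    """
    if annotation.strand == "+":
        ordered = tuple(sorted(annotation.pas_positions))
    elif annotation.strand == "-":
        ordered = tuple(sorted(annotation.pas_positions, reverse=True))
    else:
        raise ValueError(
            f"{annotation.gene_id}: strand must be '+' or '-', got "
            f"{annotation.strand!r}; proximal-to-distal ordering is undecidable"
        )
    return replace(annotation, pas_positions=ordered)


def _check_quant(quant: pd.DataFrame) -> None:
    if not isinstance(quant.index, pd.MultiIndex) or quant.index.nlevels != 2:
        raise ValueError(
            "PAS quantification table must be indexed by (gene_id, pas_index)"
        )
    if (quant.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")


def filter_pas_by_expression(quant: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Retain PAS whose mean TPM across all samples exceeds ``threshold``.

    The comparison is strict (> threshold): a site averaging exactly the
    threshold is removed. Retention is decided on the mean over every
    sample in the analysis so that the per-gene site count n stays the
    same in all samples and Psi remains comparable across them. Surviving
    sites are re-indexed 1..n' preserving the proximal-to-distal order;
    genes left with fewer than two sites are carried forward and later
    yield undefined Psi.
    """
    _check_quant(quant)
    keep = quant.mean(axis=1) > threshold
    out = quant.loc[keep].copy()
    # re-index m within each gene, preserving original order
    new_m = out.groupby(level=0, sort=False).cumcount() + 1
    out.index = pd.MultiIndex.from_arrays(
        [out.index.get_level_values(0), new_m],
        names=list(quant.index.names),
    )
    return out


def compute_psi(tpm_by_m, n: int | None = None) -> float:
    """Gene-level PAS usage for one sample.

    Parameters
    ----------
    tpm_by_m : sequence of non-negative TPM values ordered proximal to
        distal (index m = 1..n).
    n : expected number of sites; defaults to ``len(tpm_by_m)`` and is
        checked against it when given.

    Returns NaN (undefined) when n = 1 — the (n - 1) rank denominator
    vanishes — or when total TPM is zero.
    """
    tpm = np.asarray(tpm_by_m, dtype=float)
    if n is None:
        n = tpm.size
    if tpm.size != n:
        raise ValueError(f"TPM vector length {tpm.size} does not match n={n}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if (tpm < 0).any():
        raise ValueError("TPM values must be non-negative")
    total = tpm.sum()
    if n == 1 or total == 0:
        return float("nan")
    weights = np.arange(n, dtype=float) / (n - 1)  # (m-1)/(n-1)
    return float((tpm * weights).sum() / total)


def compute_psi_table(quant: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-sample Psi from a (filtered, re-indexed) quant table.

    Undefined cells (single retained site, or zero total TPM in that
    sample) are NaN; the table keeps one row per gene regardless.
    """
    _check_quant(quant)
    genes = quant.index.get_level_values(0)
    m = quant.index.get_level_values(1).to_numpy(dtype=float)
    n_per_gene = pd.Series(genes).groupby(genes, sort=False).transform("size").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = (m - 1) / (n_per_gene - 1)
    values = quant.to_numpy(dtype=float)
    wsum = pd.DataFrame(values * weights[:, None], index=quant.index, columns=quant.columns)
    num = wsum.groupby(level=0, sort=False).sum()
    den = quant.groupby(level=0, sort=False).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = num / den
    single = pd.Series(n_per_gene, index=quant.index).groupby(level=0, sort=False).first() < 2
    psi.loc[single[single].index] = np.nan
    psi[den == 0] = np.nan
    psi.index.name = "gene_id"
    return psi


class DifferentialPsi(BaseEstimator):
    """Two-condition differential PAS usage test.

    Per gene, a two-sided Welch t-test on the per-replicate Psi values;
    a gene is testable only when both conditions have at least
    ``min_defined`` defined Psi values. Following the study design this
    stage applies a raw p-value cutoff (default alpha = 0.01) with no
    multiplicity correction; BH adjustment can be switched on.

    Attributes (after ``fit``)
    --------------------------
    conditions_ : (reference, alternative) condition labels, in first
        appearance order of the sample->condition map.
    results_ : DataFrame with per-gene means, delta_psi
        (alternative - reference), p_value, significant and tested flags.
    """

    def __init__(self, alpha: float = 0.01, min_defined: int = 2, bh_correct: bool = False):
        self.alpha = alpha
        self.min_defined = min_defined
        self.bh_correct = bh_correct

    def fit(self, psi: pd.DataFrame, groups: dict[str, str]) -> "DifferentialPsi":
        conditions = list(dict.fromkeys(groups.values()))
        if len(conditions) != 2:
            raise ValueError(f"exactly two conditions required, got {conditions}")
        missing = [s for s in psi.columns if s not in groups]
        if missing:
            raise ValueError(f"samples missing from condition map: {missing}")
        ref, alt = conditions
        a = psi[[s for s in psi.columns if groups[s] == ref]].to_numpy(dtype=float)
        b = psi[[s for s in psi.columns if groups[s] == alt]].to_numpy(dtype=float)
        n_a = np.sum(~np.isnan(a), axis=1)
        n_b = np.sum(~np.isnan(b), axis=1)
        tested = (n_a >= self.min_defined) & (n_b >= self.min_defined)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            mean_a = np.nanmean(a, axis=1)
            mean_b = np.nanmean(b, axis=1)
        delta = mean_b - mean_a
        pvals = np.full(len(psi), np.nan)
        if tested.any():
            res = stats.ttest_ind(
                b[tested], a[tested], axis=1, equal_var=False, nan_policy="omit"
            )
            p = np.asarray(res.pvalue, dtype=float)
            # both groups constant: scipy yields NaN; equal means -> no
            # evidence of change (p=1), different means -> certain change
            degenerate = np.isnan(p)
            if degenerate.any():
                d = delta[tested]
                p[degenerate] = np.where(np.isclose(d[degenerate], 0.0), 1.0, 0.0)
            pvals[tested] = p
        result = pd.DataFrame(
            {
                "gene_id": psi.index,
                f"mean_{ref}": mean_a,
                f"mean_{alt}": mean_b,
                "delta_psi": delta,
                "p_value": pvals,
                "tested": tested,
            }
        ).set_index("gene_id")
        if self.bh_correct:
            from .expression import bh_adjust

            padj = np.full(len(psi), np.nan)
            padj[tested] = bh_adjust(pvals[tested])
            result["p_adj"] = padj
            result["significant"] = tested & (np.nan_to_num(padj, nan=1.0) < self.alpha)
        else:
            result["significant"] = tested & (np.nan_to_num(pvals, nan=1.0) < self.alpha)
        self.conditions_ = (ref, alt)
        self.results_ = result
        return self


def differential_psi(
    psi: pd.DataFrame, groups: dict[str, str], alpha: float = 0.01, **kwargs
) -> pd.DataFrame:
    """Functional wrapper over :class:`DifferentialPsi`."""
    return DifferentialPsi(alpha=alpha, **kwargs).fit(psi, groups).results_
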