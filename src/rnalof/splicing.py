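"""Annotation-free intron clustering and cryptic-exon quantification.

Splice-junction evidence arrives as one record per intron per sample
(0-based half-open coordinates, BED convention) carrying a read count
and the smallest read overhang ("anchor") observed on either side of
the junction. The stages here mirror an annotation-free differential
splicing workflow:

1. filter junctions by anchor length (default: at least 6 bp on each
   side) and read support;
2. cluster introns that share a splice site (same chromosome and
   strand, identical start or identical end coordinate, transitively)
   and discard clusters with fewer than ``minclureads`` total reads;
3. test each cluster's junction-usage proportions between two
   conditions with a condition-pooled G-test, BH-adjusted across
   clusters;
4. for curated cryptic-exon events (a canonical exon-exon junction in
   competition with junctions flanking a cryptic exon), quantify the
   percent of spanning reads supporting cryptic inclusion per sample.

The cluster test deliberately pools replicates within a condition: it is
a log-likelihood-ratio test on the junction x condition count table and
therefore ignores replicate-level overdispersion, a documented
simplification of Dirichlet-multinomial cluster regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "JUNCTION_COLUMNS",
    "IntronCluster",
    "CrypticEvent",
    "filter_junctions",
    "IntronClusterer",
    "cluster_introns",
    "DifferentialClusterUsage",
    "differential_cluster_usage",
    "quantify_cryptic_event",
    "detect_event_across_samples",
]

#: long-format junction table schema (one row per intron per sample)
JUNCTION_COLUMNS = ["chrom", "start", "end", "strand", "sample_id", "count", "min_anchor"]


@dataclass(frozen=True)
class CrypticEvent:
    """A canonical junction and the cryptic-exon junctions competing with it.

    ``canonical`` is the (start, end) intron of the normal exon-exon
    junction; ``cryptic`` holds one or more (start, end) introns flanking
    the cryptic exon (e.g. donor->CE and CE->acceptor). Coordinates are
    0-based half-open, as in junction tables.
    """

    event_id: str
    chrom: str
    strand: str
    canonical: tuple[int, int]
    cryptic: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.cryptic:
            raise ValueError(f"{self.event_id}: at least one cryptic junction required")
        if self.canonical in self.cryptic:
            raise ValueError(f"{self.event_id}: cryptic junctions must differ from the canonical one")
        for s, e in (self.canonical, *self.cryptic):
            if s >= e:
                raise ValueError(f"{self.event_id}: junction start must be < end ({s}, {e})")


@dataclass
class IntronCluster:
    """A connected set of introns sharing splice sites.

    ``counts`` has one row per member junction, indexed by (start, end),
    and one column per sample; rows are sorted by coordinate.
    """

    cluster_id: str
    chrom: str
    strand: str
    counts: pd.DataFrame = field(repr=False)

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        return tuple(self.counts.index)

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())


def _check_junctions(junctions: pd.DataFrame) -> None:
    missing = [c for c in JUNCTION_COLUMNS if c not in junctions.columns]
    if missing:
        raise ValueError(f"junction table missing columns: {missing}")
    if len(junctions):
        if (junctions["start"] >= junctions["end"]).any():
            raise ValueError("junction start must be < end")
        if (junctions["count"] < 0).any():
            raise ValueError("junction counts must be non-negative")


def filter_junctions(
    junctions: pd.DataFrame, min_anchor: int = 6, min_count: int = 1
) -> pd.DataFrame:
    """Drop junction records with short anchors or too few reads.

    A record is retained iff its minimum anchor is at least ``min_anchor``
    bases (the 6 bp default means a 5 bp overhang is rejected but 6 bp
    kept) and its read count is at least ``min_count``. Order-preserving.
    """
    _check_junctions(junctions)
    keep = (junctions["min_anchor"] >= min_anchor) & (junctions["count"] >= min_count)
    return junctions.loc[keep].reset_index(drop=True)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


class IntronClusterer(BaseEstimator):
    """Connected-component clustering of introns sharing splice sites.

    Junction counts are first summed across samples per
    (chrom, strand, start, end). Two junctions are linked when they lie
    on the same chromosome and strand and share their start coordinate
    or their end coordinate; clusters are the transitive closure of that
    relation. Components whose total read count across all members and
    samples is below ``minclureads`` are discarded. Strand-unknown
    junctions are never merged with stranded ones: identical coordinates
    on different strand labels stay apart.

    Cluster ids ("clu_1", "clu_2", ...) are assigned after sorting
    components by (chrom, smallest start, strand), so output is
    deterministic and diffable.
    """

    def __init__(self, minclureads: int = 10):
        self.minclureads = minclureads

    def fit(self, junctions: pd.DataFrame) -> "IntronClusterer":
        _check_junctions(junctions)
        wide = (
            junctions.pivot_table(
                index=["chrom", "strand", "start", "end"],
                columns="sample_id",
                values="count",
                aggfunc="sum",
                fill_value=0,
            )
            .sort_index()
        )
        keys = list(wide.index)
        uf = _UnionFind(len(keys))
        by_site: dict[tuple, int] = {}
        for i, (chrom, strand, start, end) in enumerate(keys):
            for site in ((chrom, strand, "s", start), (chrom, strand, "e", end)):
                if site in by_site:
                    uf.union(by_site[site], i)
                else:
                    by_site[site] = i
        components: dict[int, list[int]] = {}
        for i in range(len(keys)):
            components.setdefault(uf.find(i), []).append(i)
        clusters = []
        for members in components.values():
            sub = wide.iloc[sorted(members)]
            if int(sub.to_numpy().sum()) < self.minclureads:
                continue
            chrom, strand = keys[members[0]][0], keys[members[0]][1]
            counts = sub.droplevel(["chrom", "strand"])
            counts.columns.name = None
            clusters.append((chrom, counts.index.min(), strand, counts))
        clusters.sort(key=lambda c: (c[0], c[1], c[2]))
        self.clusters_ = [
            IntronCluster(cluster_id=f"clu_{i + 1}", chrom=chrom, strand=strand, counts=counts)
            for i, (chrom, _, strand, counts) in enumerate(clusters)
        ]
        return self


def cluster_introns(junctions: pd.DataFrame, minclureads: int = 10) -> list[IntronCluster]:
    """Functional wrapper over :class:`IntronClusterer`."""
    return IntronClusterer(minclureads=minclureads).fit(junctions).clusters_


def _g_statistic(table: np.ndarray) -> tuple[float, int]:
    """Log-likelihood-ratio statistic of independence on a J x C table.

    Cells expected to be zero (zero row or column margin) contribute
    nothing; degrees of freedom are (J - 1) for the two-condition case.
    """
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = table * np.log(table / expected)
    g = 2.0 * np.nansum(terms[table > 0])
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return float(g), int(df)


class DifferentialClusterUsage(BaseEstimator):
    """Two-condition differential intron-cluster usage.

    Per cluster, member-junction counts are pooled within each condition
    and the junction x condition table tested with a G-test
    (df = J - 1); p-values are BH-adjusted across all tested clusters.
    A cluster is testable when it has at least two member junctions and a
    nonzero pooled total in each condition. Per-condition junction-usage
    proportions (each condition summing to 1 over members) are reported
    alongside, for spliced-pair style displays.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, clusters: list[IntronCluster], groups: dict[str, str]) -> "DifferentialClusterUsage":
        conditions = list(dict.fromkeys(groups.values()))
        if len(conditions) != 2:
            raise ValueError(f"exactly two conditions required, got {conditions}")
        ref, alt = conditions
        rows = []
        prop_rows = []
        for clu in clusters:
            samples = [s for s in clu.counts.columns if s in groups]
            pooled = pd.DataFrame(
                {
                    ref: clu.counts[[s for s in samples if groups[s] == ref]].sum(axis=1),
                    alt: clu.counts[[s for s in samples if groups[s] == alt]].sum(axis=1),
                }
            )
            testable = len(clu.counts) >= 2 and (pooled.sum(axis=0) > 0).all()
            if testable:
                g, df = _g_statistic(pooled.to_numpy())
                p = float(stats.chi2.sf(g, df))
            else:
                g, p = np.nan, np.nan
            rows.append(
                {
                    "cluster_id": clu.cluster_id,
                    "chrom": clu.chrom,
                    "strand": clu.strand,
                    "n_junctions": len(clu.counts),
                    "total_reads": clu.total_reads,
                    "g_statistic": g,
                    "p_value": p,
                    "tested": testable,
                }
            )
            totals = pooled.sum(axis=0)
            for (start, end), row in pooled.iterrows():
                prop_rows.append(
                    {
                        "cluster_id": clu.cluster_id,
                        "chrom": clu.chrom,
                        "strand": clu.strand,
                        "start": start,
                        "end": end,
                        f"count_{ref}": int(row[ref]),
                        f"count_{alt}": int(row[alt]),
                        f"prop_{ref}": row[ref] / totals[ref] if totals[ref] > 0 else np.nan,
                        f"prop_{alt}": row[alt] / totals[alt] if totals[alt] > 0 else np.nan,
                    }
                )
        result = pd.DataFrame(rows).set_index("cluster_id") if rows else pd.DataFrame(
            columns=["chrom", "strand", "n_junctions", "total_reads", "g_statistic", "p_value", "tested"]
        )
        if len(result):
            from .expression import bh_adjust

            padj = np.full(len(result), np.nan)
            tested = result["tested"].to_numpy()
            if tested.any():
                padj[tested] = bh_adjust(result.loc[tested, "p_value"].to_numpy())
            result["p_adj"] = padj
            result["significant"] = tested & (np.nan_to_num(padj, nan=1.0) < self.alpha)
        self.conditions_ = (ref, alt)
        self.results_ = result
        self.proportions_ = pd.DataFrame(prop_rows)
        return self


def differential_cluster_usage(
    clusters: list[IntronCluster], groups: dict[str, str], alpha: float = 0.05
) -> pd.DataFrame:
    """Functional wrapper over :class:`DifferentialClusterUsage`."""
    return DifferentialClusterUsage(alpha=alpha).fit(clusters, groups).results_


def _junction_count(junctions: pd.DataFrame, event: CrypticEvent, coords, sample_id) -> int:
    sel = (
        (junctions["chrom"] == event.chrom)
        & (junctions["strand"] == event.strand)
        & (junctions["start"] == coords[0])
        & (junctions["end"] == coords[1])
        & (junctions["sample_id"] == sample_id)
    )
    return int(junctions.loc[sel, "count"].sum())


def quantify_cryptic_event(
    junctions: pd.DataFrame,
    event: CrypticEvent,
    sample_id: str,
    combine: str = "mean",
) -> tuple[int, dict[tuple[int, int], int], float]:
    """Percent cryptic inclusion for one event in one sample.

    Junction coordinates must match records exactly (no fuzzy matching);
    an event junction absent from the table counts zero reads — absence
    is evidence of non-use, not an error. With cryptic support
    S (the mean of the per-cryptic-junction counts by default — each
    inclusion read pair supports both flanking junctions once, so the
    mean avoids double counting; ``combine="sum"`` is available) and
    canonical count K, percent cryptic is 100 * S / (S + K); when
    S + K = 0 there is no spanning evidence at all and the percent is
    undefined (NaN).
    """
    if combine not in ("mean", "sum"):
        raise ValueError("combine must be 'mean' or 'sum'")
    _check_junctions(junctions)
    canonical = _junction_count(junctions, event, event.canonical, sample_id)
    cryptic = {c: _junction_count(junctions, event, c, sample_id) for c in event.cryptic}
    values = np.array(list(cryptic.values()), dtype=float)
    s = float(values.mean() if combine == "mean" else values.sum())
    denom = s + canonical
    percent = float("nan") if denom == 0 else 100.0 * s / denom
    return canonical, cryptic, percent


def detect_event_across_samples(
    junctions: pd.DataFrame,
    event: CrypticEvent,
    groups: dict[str, str],
    combine: str = "mean",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-sample cryptic percentages plus per-condition detection counts.

    Detection means any cryptic-junction read (S > 0) in that sample.
    Samples with zero canonical-junction reads are flagged ``excluded``
    and left out of percentage summaries (their rate is unreliable or
    undefined), but still count toward detection when cryptic reads
    exist. Returns the per-sample table and a condition -> number of
    samples with detected cryptic splicing map.
    """
    rows = []
    for sample_id, condition in groups.items():
        canonical, cryptic, percent = quantify_cryptic_event(junctions, event, sample_id, combine)
        values = np.array(list(cryptic.values()), dtype=float)
        s = float(values.mean() if combine == "mean" else values.sum())
        rows.append(
            {
                "sample_id": sample_id,
                "condition": condition,
                "canonical_count": canonical,
                "cryptic_support": s,
                "percent_cryptic": percent,
                "detected": s > 0,
                "excluded": canonical == 0,
            }
        )
    table = pd.DataFrame(rows).set_index("sample_id")
    detection = (
        table.groupby("condition", sort=False)["detected"].sum().astype(int).to_dict()
    )
    return table, detection
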