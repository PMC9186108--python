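"""Synthetic two-condition RNA-seq datasets with planted, recoverable effects.

Three generators emulate the data the analysis stages consume, for a
wild-type vs mutant design with a configurable number of replicates:

* :func:`simulate_apa_dataset` — per-PAS TPM tables. Each gene draws
  its site count from ``pas_count_range`` and its baseline usage from a
  symmetric Dirichlet; for shifted genes a fixed usage mass equal to
  ``delta_psi`` is moved between the most proximal and most distal site
  in the mutant condition, which makes the expected Psi shift exactly
  ``delta_psi`` (the Psi weight of site 1 is 0 and of site n is 1).
  Per-sample TPM = log-normal gene expression x usage x multiplicative
  gamma replicate noise.
* :func:`simulate_junction_dataset` — junction-spanning read counts for
  cryptic-exon events plus background junctions for clustering. In the
  mutant condition each event draws cryptic reads ~ Poisson(depth * rho)
  (every inclusion read pair supports each flanking cryptic junction
  once, so both cryptic junctions carry the same count) and canonical
  reads ~ Poisson(depth * (1 - rho)).
* :func:`simulate_count_matrix` — negative-binomial gene counts
  (gamma-Poisson mixture, common dispersion) with a planted fraction of
  DE genes whose |log2FC| always clears 0.25, plus a designated
  TARDBP-like autoregulation gene whose planted direction depends on the
  contrast kind: up under the mutation, down under knock-down.

Every generator derives its random stream from the master seed with a
fixed offset, so the three datasets are independently regeneratable, and
a fixed config yields byte-identical tables on rerun.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .apa import PASAnnotation
from .config import SimulationConfig
from .splicing import JUNCTION_COLUMNS, CrypticEvent

__all__ = [
    "SyntheticTruth",
    "TARDBP_GENE_ID",
    "sample_names",
    "simulate_apa_dataset",
    "simulate_junction_dataset",
    "simulate_count_matrix",
    "simulate_phenocopy_pair",
    "default_events",
]

#: id of the planted autoregulation gene in count matrices
TARDBP_GENE_ID = "TARDBP"

# fixed seed-stream offsets, one per generator
_APA_STREAM = 1
_JUNCTION_STREAM = 2
_COUNT_STREAM = 3


@dataclass
class SyntheticTruth:
    """Ground truth of planted effects, for recovery tests."""

    shifted_genes: dict[str, float] = field(default_factory=dict)  # gene -> signed expected delta Psi
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> planted log2FC
    tardbp_gene_id: str | None = None
    tardbp_log2fc: float | None = None
    event_rho: dict[str, float] = field(default_factory=dict)  # event -> planted cryptic rate

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "apa_shift", "id": g, "value": d} for g, d in self.shifted_genes.items()
        ]
        rows += [{"kind": "de", "id": g, "value": f} for g, f in self.de_genes.items()]
        if self.tardbp_gene_id is not None:
            rows.append({"kind": "tardbp", "id": self.tardbp_gene_id, "value": self.tardbp_log2fc})
        rows += [{"kind": "cryptic_rho", "id": e, "value": r} for e, r in self.event_rho.items()]
        return pd.DataFrame(rows, columns=["kind", "id", "value"])


def sample_names(config: SimulationConfig, conditions: tuple[str, str] = ("wt", "mut")) -> dict[str, str]:
    """Sample -> condition map of the simulated design (first condition first)."""
    groups = {}
    for cond in conditions:
        for i in range(config.n_replicates_per_group):
            groups[f"{cond}_{i + 1}"] = cond
    return groups


def _gamma_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    shape = 1.0 / cv**2
    return rng.gamma(shape, scale=1.0 / shape, size=size)


def simulate_apa_dataset(
    config: SimulationConfig,
) -> tuple[dict[str, PASAnnotation], pd.DataFrame, SyntheticTruth]:
    """Generate PAS annotations, a per-PAS TPM table and the planted truth.

    Returns ``(annotations, quant, truth)`` where ``quant`` is indexed by
    (gene_id, pas_index) with one column per sample, pas_index already
    proximal-to-distal (m = 1..n). Shifted genes move a usage mass of
    ``delta_psi`` from the most proximal to the most distal site (or the
    reverse, sign chosen at random) in the mutant condition; baselines of
    shifted genes are blended with endpoint mass so the move is always
    feasible, keeping the expected shift exact.
    """
    config.validate()
    if config.frac_apa_shift > 0 and config.delta_psi > 0.5:
        raise ValueError(
            "delta_psi > 0.5 cannot be planted: the endpoint-blended baseline "
            "reserves a mass of delta_psi at both the proximal and distal site"
        )
    rng = np.random.default_rng([config.seed, _APA_STREAM])
    groups = sample_names(config)
    samples = list(groups)
    n_mut = config.n_replicates_per_group
    lo, hi = config.pas_count_range
    truth = SyntheticTruth()

    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    site_counts = rng.integers(lo, hi + 1, size=config.n_genes)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    expression = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=config.n_genes)

    multi = np.flatnonzero(site_counts >= 2)
    n_shift = int(round(config.frac_apa_shift * config.n_genes))
    n_shift = min(n_shift, multi.size)
    shifted = set(rng.choice(multi, size=n_shift, replace=False).tolist())

    annotations: dict[str, PASAnnotation] = {}
    index_rows: list[tuple[str, int]] = []
    tpm_rows: list[np.ndarray] = []
    delta = config.delta_psi
    for i, gene in enumerate(gene_ids):
        n = int(site_counts[i])
        positions = np.sort(rng.choice(np.arange(1, 100_000), size=n, replace=False)) + i * 100_000
        if strands[i] == "-":
            ordered = tuple(int(p) for p in positions[::-1])
        else:
            ordered = tuple(int(p) for p in positions)
        annotations[gene] = PASAnnotation(
            gene_id=gene, chrom="chr1", strand=str(strands[i]), pas_positions=ordered
        )
        base = rng.dirichlet(np.full(n, 2.0))
        if i in shifted and delta > 0:
            direction = int(rng.choice([-1, 1]))
            # blend in endpoint mass so a move of size delta is feasible
            base = (1.0 - 2.0 * delta) * base
            base[0] += delta
            base[-1] += delta
            usage_mut = base.copy()
            if direction > 0:  # distal shift: Psi up in mutant
                usage_mut[0] -= delta
                usage_mut[-1] += delta
            else:
                usage_mut[0] += delta
                usage_mut[-1] -= delta
            truth.shifted_genes[gene] = direction * delta
        else:
            usage_mut = base
        usage_wt = base
        noise = _gamma_noise(rng, config.tpm_noise_cv, (n, len(samples)))
        tpm = np.empty((n, len(samples)))
        tpm[:, :n_mut] = expression[i] * usage_wt[:, None] * noise[:, :n_mut]
        tpm[:, n_mut:] = expression[i] * usage_mut[:, None] * noise[:, n_mut:]
        index_rows.extend((gene, m + 1) for m in range(n))
        tpm_rows.append(tpm)

    quant = pd.DataFrame(
        np.vstack(tpm_rows),
        index=pd.MultiIndex.from_tuples(index_rows, names=["gene_id", "pas_index"]),
        columns=samples,
    )
    return annotations, quant, truth


def default_events(n_cryptic_junctions: int = 2) -> list[CrypticEvent]:
    """A UNC13A-style cryptic-exon event (donor->CE and CE->acceptor) and a
    STMN2-style single cryptic junction event."""
    # coordinates are synthetic placeholders on the genes' chromosomes
    return [
        CrypticEvent(
            event_id="UNC13A",
            chrom="chr19",
            strand="-",
            canonical=(17_642_000, 17_645_000),
            cryptic=((17_642_000, 17_643_100), (17_643_350, 17_645_000))[:n_cryptic_junctions],
        ),
        CrypticEvent(
            event_id="STMN2",
            chrom="chr8",
            strand="+",
            canonical=(79_611_100, 79_636_800),
            cryptic=((79_611_100, 79_616_100),),
        ),
    ]


def simulate_junction_dataset(
    config: SimulationConfig, events: list[CrypticEvent] | None = None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a long-format junction table for cryptic events + background.

    Event records model junction extraction run with a read-level anchor
    filter, so their min_anchor is always >= 6; background junctions
    carry a configurable fraction of sub-6 bp anchors to exercise the
    record-level filter, and share splice sites in runs of three so the
    clustering stage has real connectivity to find.
    """
    config.validate()
    if events is None:
        events = default_events()
    rng = np.random.default_rng([config.seed, _JUNCTION_STREAM])
    groups = sample_names(config)
    truth = SyntheticTruth(event_rho={e.event_id: config.cryptic_rate for e in events})
    rows: list[dict] = []

    for event in events:
        for sample_id, condition in groups.items():
            rho = config.cryptic_rate if condition == "mut" else config.wt_cryptic_rate
            n_cryptic = rng.poisson(config.junction_depth * rho)
            n_canonical = rng.poisson(config.junction_depth * (1.0 - rho))
            junctions = [(event.canonical, n_canonical)] + [(c, n_cryptic) for c in event.cryptic]
            for (start, end), count in junctions:
                if count == 0:
                    continue  # junction files only list observed junctions
                lo, hi = (min(start, end), max(start, end))
                rows.append(
                    {
                        "chrom": event.chrom,
                        "start": lo,
                        "end": hi,
                        "strand": event.strand,
                        "sample_id": sample_id,
                        "count": int(count),
                        "min_anchor": int(rng.integers(6, 31)),
                    }
                )

    # background junctions in runs of three sharing a splice site
    n_bg = config.n_background_junctions
    base_positions = rng.integers(1_000, 1_000_000, size=max(1, n_bg // 3 + 1)) * 10
    for j in range(n_bg):
        anchor_pos = int(base_positions[j // 3])
        start = anchor_pos
        end = anchor_pos + 200 * (j % 3 + 1) + int(rng.integers(0, 50))
        strand = "+" if (j // 3) % 2 == 0 else "-"
        for sample_id in groups:
            count = int(rng.poisson(5))
            if count == 0:
                continue
            short = rng.random() < config.anchor_fail_rate
            rows.append(
                {
                    "chrom": "chr2",
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "sample_id": sample_id,
                    "count": count,
                    "min_anchor": int(rng.integers(1, 6) if short else rng.integers(6, 31)),
                }
            )

    table = pd.DataFrame(rows, columns=JUNCTION_COLUMNS)
    return table, truth


def _planted_log2fc(rng: np.random.Generator, n: int, sd: float, min_abs: float = 0.25) -> np.ndarray:
    """Normal(0, sd) draws with |value| < min_abs resampled away."""
    out = rng.normal(0.0, sd, size=n)
    bad = np.abs(out) < min_abs
    while bad.any():
        out[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(out) < min_abs
    return out


def _nb_counts(rng: np.random.Generator, means: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 1e-12:
        return rng.poisson(means)
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, scale=means * dispersion))


def simulate_count_matrix(
    config: SimulationConfig,
    tardbp_direction: int = 1,
    conditions: tuple[str, str] = ("wt", "mut"),
    _rng: np.random.Generator | None = None,
    _planted: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a genes x samples NB count matrix with planted DE genes.

    ``tardbp_direction`` sets the sign of the TARDBP-like gene's planted
    fold change: +1 for a mutant-style contrast (autoregulation broken,
    transcript up), -1 for a knock-down-style contrast (transcript down).
    """
    config.validate()
    rng = _rng if _rng is not None else np.random.default_rng([config.seed, _COUNT_STREAM])
    groups = sample_names(config, conditions)
    samples = list(groups)
    n_rep = config.n_replicates_per_group

    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes - 1)] + [TARDBP_GENE_ID]
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    base *= config.library_size / base.sum()

    if _planted is None:
        n_de = int(round(config.frac_de * (config.n_genes - 1)))
        de_idx = rng.choice(config.n_genes - 1, size=n_de, replace=False)
        lfcs = _planted_log2fc(rng, n_de, config.de_log2fc_sd)
        planted = {gene_ids[i]: float(f) for i, f in zip(de_idx, lfcs)}
    else:
        planted = dict(_planted)

    lfc = np.zeros(config.n_genes)
    for g, f in planted.items():
        lfc[gene_ids.index(g)] = f
    lfc[-1] = tardbp_direction * config.tardbp_log2fc

    mean_ref = base
    mean_alt = base * 2.0**lfc
    counts = np.empty((config.n_genes, len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        means = mean_ref if j < n_rep else mean_alt
        counts[:, j] = _nb_counts(rng, means, config.nb_dispersion)
    matrix = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    truth = SyntheticTruth(
        de_genes=planted,
        tardbp_gene_id=TARDBP_GENE_ID,
        tardbp_log2fc=float(tardbp_direction * config.tardbp_log2fc),
    )
    return matrix, truth


def simulate_phenocopy_pair(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth, SyntheticTruth]:
    """Paired mutant-style and knock-down-style count matrices.

    Both datasets share the same planted DE genes; a fraction
    ``frac_shared_direction`` of them keep the same fold-change direction
    in the knock-down contrast (the rest are flipped), and the
    TARDBP-like gene is planted up in the mutant contrast but down in the
    knock-down contrast, as autoregulation predicts. Returns
    ``(counts_mut, counts_kd, truth_mut, truth_kd)``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _COUNT_STREAM])
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes - 1)]
    n_de = int(round(config.frac_de * (config.n_genes - 1)))
    de_idx = rng.choice(config.n_genes - 1, size=n_de, replace=False)
    lfcs = _planted_log2fc(rng, n_de, config.de_log2fc_sd)
    planted_mut = {gene_ids[i]: float(f) for i, f in zip(de_idx, lfcs)}
    flip = rng.random(n_de) >= config.frac_shared_direction
    planted_kd = {
        g: (-f if flipped else f)
        for (g, f), flipped in zip(planted_mut.items(), flip)
    }
    counts_mut, truth_mut = simulate_count_matrix(
        config, tardbp_direction=1, conditions=("wt", "mut"), _rng=rng, _planted=planted_mut
    )
    counts_kd, truth_kd = simulate_count_matrix(
        config, tardbp_direction=-1, conditions=("ctrl", "kd"), _rng=rng, _planted=planted_kd
    )
    return counts_mut, counts_kd, truth_mut, truth_kd
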