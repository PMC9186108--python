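"""Configuration objects for simulation and pipeline runs."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-condition RNA-seq study.

    The defaults emulate a wild-type vs mutant design with three
    replicates per genotype, the layout the analysis stages were built
    around. All fractions are in [0, 1].

    Parameters
    ----------
    seed : master seed; each generator derives its own independent
        stream from it with a fixed offset, so the three datasets can be
        regenerated independently.
    n_genes : genes simulated per dataset.
    n_replicates_per_group : biological replicates per condition
        (must be >= 2, otherwise differential testing is impossible).
    pas_count_range : inclusive (min, max) number of polyadenylation
        sites per gene.
    frac_apa_shift : fraction of multi-PAS genes given a planted usage
        shift between conditions.
    delta_psi : magnitude of the planted expected shift of the usage
        metric (mutant minus wild-type), in Psi units.
    frac_de : fraction of genes planted as differentially expressed.
    de_log2fc_sd : standard deviation of planted log2 fold changes
        (values with magnitude below 0.25 are resampled so every planted
        gene clears the calling threshold).
    nb_dispersion : negative-binomial dispersion shared by all genes;
        0 gives Poisson counts.
    library_size : expected total reads per sample.
    cryptic_rate : planted per-read probability rho that a spanning read
        supports the cryptic junctions rather than the canonical one, in
        the mutant condition.
    wt_cryptic_rate : same, in the wild-type condition (default 0: no
        cryptic inclusion without loss of TDP-43 function).
    junction_depth : expected spanning reads per event per sample.
    n_background_junctions : non-event junctions emitted to exercise
        clustering.
    anchor_fail_rate : fraction of background junction records whose
        minimum read anchor falls below the 6 bp extraction cutoff.
    tpm_noise_cv : coefficient of variation of the multiplicative gamma
        replicate noise on PAS-level TPM.
    tardbp_log2fc : magnitude of the planted fold change of the
        autoregulated TARDBP-like gene (sign set per contrast kind).
    frac_shared_direction : in paired phenocopy simulations, the fraction
        of shared DE genes whose planted direction agrees between the
        mutant and knock-down contrasts.
    """

    seed: int = 0
    n_genes: int = 2000
    n_replicates_per_group: int = 3
    pas_count_range: tuple[int, int] = (2, 5)
    frac_apa_shift: float = 0.1
    delta_psi: float = 0.3
    frac_de: float = 0.1
    de_log2fc_sd: float = 1.0
    nb_dispersion: float = 0.01
    library_size: float = 1_000_000.0
    cryptic_rate: float = 0.3
    wt_cryptic_rate: float = 0.0
    junction_depth: float = 100.0
    n_background_junctions: int = 50
    anchor_fail_rate: float = 0.05
    tpm_noise_cv: float = 0.2
    tardbp_log2fc: float = 1.0
    frac_shared_direction: float = 0.8

    def __post_init__(self) -> None:
        self.pas_count_range = tuple(self.pas_count_range)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        fracs = {
            "frac_apa_shift": self.frac_apa_shift,
            "delta_psi": self.delta_psi,
            "frac_de": self.frac_de,
            "cryptic_rate": self.cryptic_rate,
            "wt_cryptic_rate": self.wt_cryptic_rate,
            "anchor_fail_rate": self.anchor_fail_rate,
            "frac_shared_direction": self.frac_shared_direction,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_replicates_per_group < 2:
            raise ValueError(
                "n_replicates_per_group must be >= 2: with a single replicate "
                "per condition no differential test is possible"
            )
        lo, hi = self.pas_count_range
        if lo < 1 or hi < lo:
            raise ValueError(f"pas_count_range must satisfy 1 <= min <= max, got {self.pas_count_range}")
        positive = {
            "n_genes": self.n_genes,
            "library_size": self.library_size,
            "junction_depth": self.junction_depth,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.tpm_noise_cv < 0:
            raise ValueError("tpm_noise_cv must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["pas_count_range"] = list(self.pas_count_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


#: default analysis thresholds, as used throughout the pipeline
DEFAULT_THRESHOLDS = {
    "pas_tpm": 5.0,       # strict: keep PAS with mean TPM > 5
    "min_anchor": 6,      # minimum read overhang on each side of a junction
    "minclureads": 10,    # minimum total reads for an intron cluster
    "deg_alpha": 0.05,    # BH-adjusted p cutoff for DEG calling
    "deg_lfc": 0.25,      # |log2FC| cutoff for DEG calling
    "cluster_alpha": 0.05,  # BH-adjusted p cutoff for differential splicing
    "psi_alpha": 0.01,    # raw p cutoff for differential PAS usage
}


@dataclass
class RunConfig:
    """End-to-end pipeline run configuration (the ``all`` subcommand)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    exclude_genes: tuple[str, ...] = ("TARDBP",)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        for name, value in self.thresholds.items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive, got {value}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**data.get("simulation", {}))
        return cls(
            simulation=sim,
            thresholds=data.get("thresholds", {}),
            exclude_genes=tuple(data.get("exclude_genes", ("TARDBP",))),
        )


def config_hash(path: str | Path) -> str:
    """Short sha256 digest of a config file, recorded in run logs."""
    digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return digest[:12]
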