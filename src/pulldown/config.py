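"""Configuration dataclasses for the pipeline.

Every tunable of the analysis lives here: the synthetic-data study design
(organ panel, run counts, planted truth, count model, background model),
the interactor-calling thresholds, enrichment backgrounds, motif
stringency percentiles and iTRAQ call thresholds. All configs round-trip
losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

DEFAULT_ORGANS = ["embryonic_brain", "spleen", "testis", "thymus", "adult_brain"]


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration values."""


@dataclass
class SynthConfig:
    """Study design for the synthetic AP-MS data generator.

    Defaults emulate the real study's conditions: five organs, 6-10
    tagged knock-in (KI) purification/MS runs and 6-11 mock (WT) runs per
    organ, the bait present in every KI run and never in mock runs,
    over-dispersed (negative-binomial) spectral counts for true
    interactors, and a fixed power-law ranking of sticky background
    contaminants recurring in both genotypes.
    """

    seed: int = 0
    n_proteins: int = 2000
    organs: list[str] = field(default_factory=lambda: list(DEFAULT_ORGANS))
    #: per-organ run counts; None draws uniformly from [6, 10] / [6, 11]
    n_ki_runs: int | None = None
    n_wt_runs: int | None = None
    bait_id: str = "BAIT"
    planted_per_organ: int = 30
    #: fraction of each organ's planted set shared with the other organs
    shared_fraction: float = 0.3
    interactor_count_mean: float = 10.0
    #: NB dispersion phi, var = mean + phi * mean^2; 0 switches to Poisson
    interactor_count_dispersion: float = 0.3
    count_model: str = "negative_binomial"  # or "poisson"
    #: detection probability of the r-th stickiest contaminant ~ r**-exponent
    contaminant_law_exponent: float = 1.0
    contaminant_max_prob: float = 0.9
    n_contaminants: int = 300
    contaminant_count_mean: float = 2.0
    #: probability a planted interactor drops out of a single KI run
    detection_floor: float = 0.05
    bait_count_mean: float = 30.0
    edge_density: float = 0.0005
    core_edge_prob: float = 0.9
    #: probability a planted interactor has a curated edge to the bait itself
    bait_edge_prob: float = 0.1
    #: relative risk of carrying a known-substrate label among planted interactors
    substrate_enrichment: float = 6.6
    substrate_base_rate: float = 0.0195
    #: true KO:KI fold change per protein; None plants 3 gained (4x) + 1 lost (0.1x)
    itraq_effects: dict[str, float] | None = None
    itraq_noise_sd: float = 0.15  # log2 units
    itraq_ki_wt_fold: float = 10.0
    n_annotation_terms: int = 40
    seq_length_range: tuple[int, int] = (100, 1000)

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ConfigError("n_proteins must be positive")
        if not self.organs:
            raise ConfigError("at least one organ is required")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ConfigError("shared_fraction must be in [0, 1]")
        if not 0.0 <= self.detection_floor <= 1.0:
            raise ConfigError("detection_floor must be in [0, 1]")
        if self.n_ki_runs is not None and not 1 <= self.n_ki_runs:
            raise ConfigError("n_ki_runs must be >= 1")
        if self.n_wt_runs is not None and not 1 <= self.n_wt_runs:
            raise ConfigError("n_wt_runs must be >= 1")
        if self.planted_per_organ < 0 or self.planted_per_organ >= self.n_proteins:
            raise ConfigError("planted_per_organ must be in [0, n_proteins)")
        if self.count_model not in ("negative_binomial", "poisson"):
            raise ConfigError(f"unknown count_model {self.count_model!r}")


@dataclass
class ScoringThresholds:
    """Cutoffs for the three-tier interactor classification."""

    alpha_core: float = 0.05
    min_ki_detections: int = 2
    min_ratio: float = 3.0
    alpha_pooled: float = 0.05
    pseudocount: float = 0.5
    #: apply Benjamini-Hochberg to the per-tissue p-values before thresholding
    fdr: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_core < 1.0:
            raise ConfigError("alpha_core must be in (0, 1)")
        if not 0.0 < self.alpha_pooled < 1.0:
            raise ConfigError("alpha_pooled must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be positive")
        if self.min_ki_detections < 0:
            raise ConfigError("min_ki_detections must be >= 0")


@dataclass
class EnrichmentConfig:
    ease_threshold: float = 0.2
    fold_clamp: tuple[float, float] = (1.0, 5.0)
    #: use all called interactors (CORE+CAT2+CAT3); False restricts to CORE
    include_rescued: bool = True
    #: fraction of an organ's interactors a label needs to be flagged
    frequent_label_fraction: float = 0.10


@dataclass
class MotifConfig:
    high_percentile: float = 0.2  # percent of background protein scores
    medium_percentile: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.high_percentile <= self.medium_percentile <= 100:
            raise ConfigError("need 0 < high_percentile <= medium_percentile <= 100")


@dataclass
class ItraqConfig:
    gain_threshold: float = 2.0
    loss_threshold: float = 0.5
    aggregate: str = "median"  # or "mean"
    subtract_mock: bool = False

    def __post_init__(self) -> None:
        if self.aggregate not in ("median", "mean"):
            raise ConfigError(f"unknown aggregate {self.aggregate!r}")
        if not 0 < self.loss_threshold < self.gain_threshold:
            raise ConfigError("need 0 < loss_threshold < gain_threshold")


@dataclass
class PipelineConfig:
    """Full configuration for one end-to-end run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    thresholds: ScoringThresholds = field(default_factory=ScoringThresholds)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)
    itraq: ItraqConfig = field(default_factory=ItraqConfig)
    outdir: str = "pulldown_out"

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        synth = d.pop("synth", {})
        if "seq_length_range" in synth:
            synth["seq_length_range"] = tuple(synth["seq_length_range"])
        enr = d.pop("enrichment", {})
        if "fold_clamp" in enr:
            enr["fold_clamp"] = tuple(enr["fold_clamp"])
        return cls(
            synth=SynthConfig(**synth),
            thresholds=ScoringThresholds(**d.pop("thresholds", {})),
            enrichment=EnrichmentConfig(**enr),
            motif=MotifConfig(**d.pop("motif", {})),
            itraq=ItraqConfig(**d.pop("itraq", {})),
            **d,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
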