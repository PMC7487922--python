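"""Configuration objects for every stage of the editome pipeline.

Each dataclass gathers the numeric thresholds of one stage in a single
auditable place.  Defaults correspond to the thresholds of the published
detection recipe this package implements: base quality >= 25, at most two
allele types, >= 3 reads supporting the minor allele, a 4 bp splice-junction
exclusion window for intronic sites, a 6 bp read-end margin, homopolymer
runs >= 5 nt, and a 0.95 second-best/best alignment-identity ratio for the
multi-mapping check.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict


class ConfigError(ValueError):
    """Raised when a configuration violates its documented invariants."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class SimConfig:
    """Parameters of the synthetic study generator.

    The defaults emulate the structure of the study the pipeline targets:
    a 3-stage x 3-replicate strand-specific RNA-seq design over a small
    genome carrying a SINE-like repeat family, with stage mean editing
    levels matching the overall rates observed at infancy / puberty /
    adulthood (16.63% / 20.87% / 18.86%).
    """

    genome_length: int = 50_000
    n_genes: int = 6
    n_true_sites: int = 500
    stage_levels: Dict[str, float] = field(
        default_factory=lambda: {"Y30": 0.1663, "Y180": 0.2087, "Y300": 0.1886}
    )
    n_replicates: int = 3
    coverage_mean: float = 50.0
    base_error_rate: float = 0.001
    n_het_snps: int = 50
    n_read_end_artifacts: int = 50
    n_homopolymer_artifacts: int = 50
    n_mismap_artifacts: int = 50
    n_background_sites: int = 200
    read_length: int = 150
    read_end_margin: int = 6
    replicate_sd: float = 0.02
    repeat_site_fraction: float = 0.8
    site_level_spread: float = 0.08
    flank_energy_mirnas: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "genome_length", "n_genes", "n_true_sites", "n_replicates",
            "n_het_snps", "n_read_end_artifacts", "n_homopolymer_artifacts",
            "n_mismap_artifacts", "n_background_sites", "read_length",
            "read_end_margin", "flank_energy_mirnas",
        ):
            _check(getattr(self, name) >= 0, f"{name} must be >= 0")
        for name in ("base_error_rate", "repeat_site_fraction"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must be in [0, 1]")
        _check(self.replicate_sd >= 0.0, "replicate_sd must be >= 0")
        _check(self.site_level_spread >= 0.0, "site_level_spread must be >= 0")
        _check(self.coverage_mean > 0, "coverage_mean must be > 0")
        _check(len(self.stage_levels) >= 1, "at least one stage is required")
        for stage, level in self.stage_levels.items():
            _check(0.0 <= level <= 1.0, f"stage level for {stage} not in [0, 1]")
        _check(
            self.read_length >= 2 * self.read_end_margin + 1,
            "read_length must be >= 2 * read_end_margin + 1",
        )

    @property
    def stages(self) -> list[str]:
        return list(self.stage_levels)

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{stage}_r{r + 1}"
            for stage in self.stages
            for r in range(self.n_replicates)
        ]


@dataclass
class DetectionConfig:
    """Thresholds of the candidate-calling and five-filter cascade."""

    min_base_qual: int = 25
    max_allele_types: int = 2
    min_alt_reads: int = 3
    splice_window: int = 4
    read_end_margin: int = 6
    homopolymer_min_run: int = 5
    multimap_flank: int = 25
    multimap_score_ratio: float = 0.95

    def __post_init__(self) -> None:
        for name in (
            "min_base_qual", "max_allele_types", "min_alt_reads",
            "splice_window", "read_end_margin", "homopolymer_min_run",
            "multimap_flank",
        ):
            _check(getattr(self, name) >= 0, f"{name} must be >= 0")
        _check(
            0.0 < self.multimap_score_ratio <= 1.0,
            "multimap_score_ratio must be in (0, 1]",
        )


@dataclass
class QuantConfig:
    """Coverage/quality thresholds for per-site editing-level estimation."""

    min_coverage: int = 10
    min_qual: int = 25
    min_edit_reads: int = 3

    def __post_init__(self) -> None:
        for name in ("min_coverage", "min_qual", "min_edit_reads"):
            _check(getattr(self, name) >= 0, f"{name} must be >= 0")


@dataclass
class DiffConfig:
    """Thresholds for calling differentially edited sites (DESs)."""

    min_delta: float = 0.1
    max_fdr: float = 0.05
    min_defined_per_group: int = 2
    equal_var: bool = True  # Student's t; set False for Welch

    def __post_init__(self) -> None:
        _check(0.0 <= self.min_delta <= 1.0, "min_delta must be in [0, 1]")
        _check(0.0 <= self.max_fdr <= 1.0, "max_fdr must be in [0, 1]")
        _check(self.min_defined_per_group >= 2, "need >= 2 values per group")


@dataclass
class MirnaParams:
    """Scoring scheme of the Miranda-style miRNA target scanner.

    Complementarity scores: Watson-Crick match +5, G:U wobble +1,
    mismatch -3, affine gaps -9/-4; substitution scores are doubled inside
    the seed (miRNA positions 2-8 from the 5' end).  A hit is reported when
    the alignment score reaches ``score_threshold`` and the duplex energy is
    at most ``energy_threshold`` kcal/mol.
    """

    score_threshold: float = 140.0
    energy_threshold: float = -7.0
    match: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_start: int = 2
    seed_end: int = 8
    seed_scale: float = 2.0
    flank: int = 50

    def __post_init__(self) -> None:
        _check(self.gap_open <= 0 and self.gap_extend <= 0, "gap penalties must be <= 0")
        _check(self.seed_start >= 1, "seed_start must be >= 1")
        _check(self.seed_end >= self.seed_start, "seed_end must be >= seed_start")
        _check(self.seed_scale > 0, "seed_scale must be > 0")
        _check(self.flank >= 1, "flank must be >= 1")
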