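"""Configuration objects for simulation and pipeline thresholds."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable

import yaml


class ConfigurationError(ValueError):
    """Raised for invalid simulation or pipeline configuration."""


def _check_probs(pairs: Iterable[tuple[float, float]], what: str) -> None:
    pairs = list(pairs)
    if not pairs:
        raise ConfigurationError(f"{what}: empty distribution")
    total = sum(p for _, p in pairs)
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"{what}: probabilities sum to {total}, not 1")
    if any(p < 0 for _, p in pairs):
        raise ConfigurationError(f"{what}: negative probability")


@dataclass(frozen=True)
class PlatformProfile:
    """Sequencing characteristics for one platform.

    ``error_rate`` is the per-read probability of displaying one specific
    alternate allele in a non-carrier; ``other_allele_rate`` the per-read
    probability of showing a third, spurious allele.
    """

    name: str
    tissue: str
    mean_depth: float
    read_span_bp: int
    base_quality_probs: tuple[tuple[int, float], ...]
    mapping_quality_probs: tuple[tuple[int, float], ...]
    error_rate: float
    error_base_quality_probs: tuple[tuple[int, float], ...]
    other_allele_rate: float = 0.0
    long_read: bool = True

    def validate(self) -> None:
        if self.mean_depth < 0:
            raise ConfigurationError(f"{self.name}: negative depth")
        if self.read_span_bp < 1:
            raise ConfigurationError(f"{self.name}: read span < 1")
        if not 0 <= self.error_rate <= 1:
            raise ConfigurationError(f"{self.name}: error rate outside [0,1]")
        _check_probs(self.base_quality_probs, f"{self.name} base quality")
        _check_probs(self.mapping_quality_probs, f"{self.name} mapping quality")
        _check_probs(self.error_base_quality_probs, f"{self.name} error base quality")


@dataclass(frozen=True)
class RegionTrack:
    """One annotation track carved out of the synthetic genome."""

    name: str
    genome_fraction: float
    germline_multiplier: float = 1.0
    pzm_multiplier: float = 1.0

    def validate(self) -> None:
        if not 0 <= self.genome_fraction < 1:
            raise ConfigurationError(f"{self.name}: fraction outside [0,1)")
        if self.germline_multiplier < 0 or self.pzm_multiplier < 0:
            raise ConfigurationError(f"{self.name}: negative multiplier")


@dataclass(frozen=True)
class ArtifactRates:
    """Expected numbers of injected artifact events per child."""

    dropped_haplotype_runs: float = 0.15
    recurrent_errors: float = 0.25

    def validate(self) -> None:
        if self.dropped_haplotype_runs < 0 or self.recurrent_errors < 0:
            raise ConfigurationError("artifact rates must be >= 0")


def default_platform_profiles() -> tuple[PlatformProfile, ...]:
    return (
        PlatformProfile(
            name="hifi",
            tissue="blood",
            mean_depth=30.0,
            read_span_bp=18_000,
            base_quality_probs=((30, 0.93), (15, 0.05), (5, 0.02)),
            mapping_quality_probs=((60, 0.97), (30, 0.03)),
            error_rate=5e-6,
            error_base_quality_probs=((30, 0.10), (15, 0.55), (5, 0.35)),
            other_allele_rate=5e-6,
            long_read=True,
        ),
        PlatformProfile(
            name="ont",
            tissue="cell_line",
            mean_depth=30.0,
            read_span_bp=30_000,
            base_quality_probs=((25, 0.80), (15, 0.15), (5, 0.05)),
            mapping_quality_probs=((60, 0.95), (40, 0.05)),
            error_rate=1e-4,
            error_base_quality_probs=((25, 0.10), (15, 0.50), (5, 0.40)),
            other_allele_rate=1e-4,
            long_read=True,
        ),
        PlatformProfile(
            name="illumina",
            tissue="blood",
            mean_depth=40.0,
            read_span_bp=150,
            base_quality_probs=((35, 0.95), (15, 0.04), (5, 0.01)),
            mapping_quality_probs=((60, 0.99), (20, 0.01)),
            error_rate=5e-6,
            error_base_quality_probs=((35, 0.10), (15, 0.55), (5, 0.35)),
            other_allele_rate=5e-6,
            long_read=False,
        ),
    )


def default_region_tracks() -> tuple[RegionTrack, ...]:
    return (
        RegionTrack("segdup", 0.05, germline_multiplier=1.185, pzm_multiplier=2.0),
        RegionTrack("tandem_repeat", 0.02),
        RegionTrack("repeatmasker", 0.10),
        RegionTrack("homopolymer", 0.002),
        RegionTrack("exon", 0.03),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Rates are substitutions (or indels) per base pair per generation; age
    slopes are additional mutations per year at the scale of
    ``reference_genome_bp`` of diploid callable sequence, and are scaled
    down proportionally for smaller simulated genomes.
    """

    n_families: int = 42
    quad_fraction: float = 31 / 42
    genome_length: int = 25_000_000
    n_chromosomes: int = 2
    germline_rate: float = 1.30e-8
    pzm_rate: float = 2.30e-9
    germline_indel_rate: float = 1.2e-9
    pzm_indel_rate: float = 3.3e-10
    paternal_fraction: float = 0.799
    pzm_paternal_fraction: float = 0.535
    paternal_age_slope: float = 1.32
    maternal_age_slope: float = 0.46
    reference_genome_bp: float = 2.66e9
    parental_age_mean: float = 31.4
    parental_age_sd: float = 5.0
    parental_age_min: float = 18.0
    mosaic_ab_mean: float = 0.22
    mosaic_ab_concentration: float = 30.0
    germline_ab_mean: float = 0.48
    germline_titv: float = 2.10
    pzm_titv: float = 1.35
    cpg_fraction: float = 0.2
    snp_density: float = 1 / 1200
    snp_window_bp: int = 80_000
    snp_observation_error: float = 0.002
    platform_profiles: tuple[PlatformProfile, ...] = field(
        default_factory=default_platform_profiles
    )
    region_tracks: tuple[RegionTrack, ...] = field(default_factory=default_region_tracks)
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    panel_sites_per_child: int = 2000
    seed: int = 0

    @property
    def total_genome_bp(self) -> int:
        return self.genome_length * self.n_chromosomes

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))

    def profile(self, name: str) -> PlatformProfile:
        for prof in self.platform_profiles:
            if prof.name == name:
                return prof
        raise ConfigurationError(f"unknown platform {name!r}")

    def validate(self) -> None:
        if self.n_families < 1:
            raise ConfigurationError("n_families must be >= 1")
        if not 0 <= self.quad_fraction <= 1:
            raise ConfigurationError("quad_fraction must be in [0,1]")
        if self.genome_length < 0 or self.n_chromosomes < 1:
            raise ConfigurationError("invalid genome dimensions")
        for rate_name in (
            "germline_rate",
            "pzm_rate",
            "germline_indel_rate",
            "pzm_indel_rate",
            "snp_density",
        ):
            if getattr(self, rate_name) < 0:
                raise ConfigurationError(f"{rate_name} must be >= 0")
        for frac_name in ("paternal_fraction", "pzm_paternal_fraction"):
            if not 0 <= getattr(self, frac_name) <= 1:
                raise ConfigurationError(f"{frac_name} must be in [0,1]")
        if not 0 < self.germline_ab_mean <= 0.5:
            raise ConfigurationError("germline_ab_mean must be in (0, 0.5]")
        if not 0 < self.mosaic_ab_mean < self.germline_ab_mean:
            raise ConfigurationError("mosaic_ab_mean must be in (0, germline_ab_mean)")
        if self.mosaic_ab_concentration <= 0:
            raise ConfigurationError("mosaic_ab_concentration must be > 0")
        for prof in self.platform_profiles:
            prof.validate()
        total_frac = 0.0
        for track in self.region_tracks:
            track.validate()
            total_frac += track.genome_fraction
        if total_frac >= 1:
            raise ConfigurationError("region track fractions must sum to < 1")
        self.artifact_rates.validate()

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "platform_profiles" in data:
            data["platform_profiles"] = tuple(
                prof
                if isinstance(prof, PlatformProfile)
                else PlatformProfile(
                    **{
                        **prof,
                        "base_quality_probs": _pairs(prof["base_quality_probs"]),
                        "mapping_quality_probs": _pairs(prof["mapping_quality_probs"]),
                        "error_base_quality_probs": _pairs(
                            prof["error_base_quality_probs"]
                        ),
                    }
                )
                for prof in data["platform_profiles"]
            )
        if "region_tracks" in data:
            data["region_tracks"] = tuple(
                t if isinstance(t, RegionTrack) else RegionTrack(**t)
                for t in data["region_tracks"]
            )
        if "artifact_rates" in data and not isinstance(
            data["artifact_rates"], ArtifactRates
        ):
            data["artifact_rates"] = ArtifactRates(**data["artifact_rates"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls.from_dict(data.get("simulation", data))
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"simulation": self.to_dict()}, fh, sort_keys=False)

    def evolve(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


def _pairs(seq) -> tuple[tuple[int, float], ...]:
    return tuple((int(q), float(p)) for q, p in seq)


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the discovery/validation/phasing/classification cascade.

    Defaults encode the published filter settings; fields without a published
    value (homopolymer length, cell-line-only support, multi-allelic ceiling,
    test significance levels) are implementation choices.
    """

    min_child_gq: int = 20
    cluster_window_bp: int = 1000
    cluster_min_snvs: int = 3
    long_read_min_mapq: int = 59
    high_bq_exclusive: int = 20  # bq > 20 -> HIGH
    low_bq_min: int = 10  # 10 <= bq <= 20 -> LOW, below -> DISCARD
    # parent alt-read ceilings (max high-quality alt, max low-quality alt)
    parent_alt_ceilings: tuple[tuple[str, int, int], ...] = (
        ("hifi", 0, 1),
        ("illumina", 0, 1),
        ("ont", 1, 2),
    )
    child_min_alt_reads: int = 1
    min_supporting_platforms: int = 2
    cellline_only_illumina_hq_alt: int = 2
    recurrence_high_quality_only: bool = True
    nontr_recurrence_allowance: int = 0
    tr_recurrence_allowance: int = 1
    tr_min_mean_ab: float = 0.05
    rm_tr_min_ab: float = 0.10
    rm_min_ab: float = 0.08
    homopolymer_min_len: int = 4
    indel_min_mapq: int = 60
    indel_min_flank_bp: int = 10
    indel_max_other_alleles: int = 2
    sex_ab_epsilon: float = 0.0
    phase_window_bp: int = 80_000
    phase_weight_power: float = 1.0
    hap_pzm_min_ref: int = 2
    hap_min_alt: int = 1
    indel_pzm_min_discordant: int = 4  # "> 3 reads" with a different allele
    alpha_concordance: float = 0.05
    alpha_pooled: float = 0.05
    ci_level: float = 0.95

    def parent_ceiling(self, platform: str) -> tuple[int, int]:
        for name, hq, lq in self.parent_alt_ceilings:
            if name == platform:
                return hq, lq
        raise ConfigurationError(f"unknown platform {platform!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data = data.get("filters", data)
        if "parent_alt_ceilings" in data:
            data["parent_alt_ceilings"] = tuple(
                (str(n), int(h), int(l)) for n, h, l in data["parent_alt_ceilings"]
            )
        return cls(**data)
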