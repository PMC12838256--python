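"""Configuration objects for the synthetic cohort generator.

The simulator emulates a two-population resequencing cohort (cases with the
craniofacial defect vs. phenotypically normal controls) under the
Balding-Nichols model: per-population allele frequencies are Beta-distributed
around an ancestral frequency with a differentiation parameter F that plays
the role of the expected FST. Sweep regions override F locally and shrink
case-population heterozygosity, so both scan statistics (FST and pi-ratio)
respond there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml


class ConfigurationError(ValueError):
    """An invariant of a simulation/phenotype configuration is violated."""


@dataclass(frozen=True)
class SweepRegionSpec:
    """A planted sweep: elevated differentiation plus case diversity loss."""

    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    sweep_fst: float
    case_diversity_factor: float  # in (0, 1]: multiplies case expected het

    def overlaps(self, other: "SweepRegionSpec") -> bool:
        return self.chrom == other.chrom and not (
            self.end_bp < other.start_bp or other.end_bp < self.start_bp
        )


@dataclass
class SimulationConfig:
    """All parameters of the synthetic two-population cohort.

    Defaults mirror the study cohort (145 cases, 30 controls, ~10x depth) on a
    reduced 3 x 2 Mb genome; chromosome count and length are configuration,
    not constants.
    """

    n_case: int = 145
    n_control: int = 30
    n_chromosomes: int = 3
    chrom_length_bp: int = 2_000_000
    snp_density: float = 0.002  # expected SNPs per bp
    background_fst: float = 0.02
    sweep_regions: list[SweepRegionSpec] = field(
        default_factory=lambda: [
            SweepRegionSpec("chr1", 900_001, 1_100_000, 0.5, 0.3)
        ]
    )
    mean_depth: float = 10.0
    corrupt_gq_fraction: float = 0.02  # genotypes given failing GQ (< 20)
    corrupt_info_fraction: float = 0.02  # sites given failing hard-filter INFO
    seed: int = 0

    def __post_init__(self) -> None:
        self.sweep_regions = [
            s if isinstance(s, SweepRegionSpec) else SweepRegionSpec(*s)
            for s in self.sweep_regions
        ]
        self.validate()

    def validate(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ConfigurationError("n_case and n_control must each be >= 2")
        if not (0.0 <= self.background_fst < 1.0):
            raise ConfigurationError("background_fst must lie in [0, 1)")
        if self.n_chromosomes < 1 or self.chrom_length_bp < 1:
            raise ConfigurationError("need >= 1 chromosome of positive length")
        if self.snp_density <= 0:
            raise ConfigurationError("snp_density must be positive")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be positive")
        for frac_name in ("corrupt_gq_fraction", "corrupt_info_fraction"):
            v = getattr(self, frac_name)
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"{frac_name} must lie in [0, 1)")
        chrom_names = set(self.chrom_names)
        for region in self.sweep_regions:
            if region.chrom not in chrom_names:
                raise ConfigurationError(
                    f"sweep region on unknown chromosome {region.chrom!r}"
                )
            if not (1 <= region.start_bp <= region.end_bp <= self.chrom_length_bp):
                raise ConfigurationError(
                    f"sweep region {region} outside chromosome bounds "
                    f"[1, {self.chrom_length_bp}]"
                )
            if not (0.0 < region.case_diversity_factor <= 1.0):
                raise ConfigurationError("case_diversity_factor must be in (0, 1]")
            if not (region.sweep_fst > self.background_fst):
                raise ConfigurationError(
                    f"sweep_fst {region.sweep_fst} must exceed background_fst "
                    f"{self.background_fst}"
                )
            if region.sweep_fst >= 1.0:
                raise ConfigurationError("sweep_fst must be < 1")
        for i, a in enumerate(self.sweep_regions):
            for b in self.sweep_regions[i + 1 :]:
                if a.overlaps(b):
                    raise ConfigurationError(f"sweep regions overlap: {a} / {b}")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names}


#: Default per-trait (case_mean, case_sd, control_mean, control_sd): the
#: published group summaries for maxillary length (mm), mandible length (mm)
#: and incisor angle (degrees).
DEFAULT_TRAITS: dict[str, tuple[float, float, float, float]] = {
    "maxillary_length_mm": (149.12, 22.89, 156.92, 23.04),
    "mandible_length_mm": (197.43, 32.41, 211.46, 23.19),
    "incisor_angle_deg": (104.43, 7.04, 104.66, 8.31),
}


@dataclass
class PhenotypeConfig:
    """Group-wise Normal distributions for each measured cranial trait."""

    traits: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAITS)
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, (cm, cs, km, ks) in self.traits.items():
            if cs <= 0 or ks <= 0:
                raise ConfigurationError(f"trait {name}: SDs must be positive")


def load_simulation_config(path: str) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "sweep_regions" in raw:
        raw["sweep_regions"] = [
            SweepRegionSpec(**r) if isinstance(r, dict) else SweepRegionSpec(*r)
            for r in raw["sweep_regions"]
        ]
    return SimulationConfig(**raw)


def dump_simulation_config(config: SimulationConfig, path: str) -> None:
    data = {
        k: v
        for k, v in vars(config).items()
        if k != "sweep_regions"
    }
    data["sweep_regions"] = [vars(s) for s in config.sweep_regions]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
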