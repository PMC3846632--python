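"""Configuration objects for the simulator and the pipeline.

All randomness in the package flows from a single master seed; each
simulated data product derives a child seed from it by a fixed offset so
that any product can be regenerated independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is out of its valid domain."""


# C. elegans chromosome lengths (bp, WS230-era assembly).
DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    "I": 15_072_434,
    "II": 15_279_421,
    "III": 13_783_801,
    "IV": 17_493_829,
    "V": 20_924_180,
    "X": 17_718_942,
}

# Genes per chromosome on the 4x44K expression design (used as allocation
# weights when distributing a configurable number of genes).
DEFAULT_CHROM_GENE_WEIGHTS: dict[str, int] = {
    "I": 2_969,
    "II": 3_588,
    "III": 2_680,
    "IV": 3_435,
    "V": 5_400,
    "X": 2_809,
}

# Regions with elevated polymorphism rate: (chrom, start, end, rate multiplier).
# Left arm of chromosome II and the middle of chromosome V carry the major
# hotspots of hybridization divergence.
DEFAULT_HOTSPOTS: list[tuple[str, int, int, float]] = [
    ("II", 0, 3_000_000, 4.0),
    ("V", 4_000_000, 16_000_000, 2.5),
]

# WormBase-style gene-class sizes (chemoreceptor superfamilies, C-type
# lectins, F-box, MATH/BTB, nuclear hormone receptors, ...). The float is
# the sampling-weight multiplier applied when site- or group-linked
# polymorphisms are planted, producing the designed class enrichment.
DEFAULT_CLASS_TABLE: dict[str, tuple[int, float]] = {
    "srh": (289, 5.0),
    "str": (219, 5.0),
    "sri": (76, 5.0),
    "srj": (45, 5.0),
    "srz": (104, 5.0),
    "srw": (145, 5.0),
    "srbc": (84, 5.0),
    "srr": (10, 5.0),
    "srab": (27, 5.0),
    "srt": (72, 5.0),
    "clec": (260, 5.0),
    "fbxa": (220, 5.0),
    "fbxb": (113, 5.0),
    "fbxc": (49, 5.0),
    "math": (50, 5.0),
    "bath": (44, 5.0),
    "btb": (21, 5.0),
    "nhr": (282, 5.0),
    "phat": (6, 5.0),
    "scrm": (8, 5.0),
}

# Trait name -> (orsay mean, santeuil mean, outgroup mean, between-strain SD,
# within-strain SD, replicates per strain). Magnitudes follow the measured
# fitness traits of the study populations.
DEFAULT_PHENOTYPE_EFFECTS: dict[str, tuple[float, float, float, float, float, int]] = {
    "population_size_ecoli": (3278.0, 2988.0, 3100.0, 250.0, 550.0, 6),
    "development_time_days": (1.79, 1.79, 1.82, 0.05, 0.04, 4),
    "generation_time_days": (2.00, 1.96, 2.00, 0.06, 0.05, 4),
    "length_um": (1107.0, 1070.0, 1090.0, 40.0, 30.0, 4),
    "length_width_ratio": (24.94, 24.64, 24.80, 0.65, 0.35, 4),
}

# (bacterium A, bacterium B) -> site -> (p on A, p on B, p neither).
DEFAULT_CHOICE_PREFERENCES: dict[tuple[str, str], dict[str, tuple[float, float, float]]] = {
    ("Sphingobacterium", "Lactococcus"): {
        "Orsay": (0.857, 0.055, 0.088),
        "Santeuil": (0.857, 0.055, 0.088),
        "out": (0.857, 0.055, 0.088),
    },
    ("OP50", "Erwinia"): {
        "Orsay": (0.62, 0.28, 0.10),
        "Santeuil": (0.46, 0.44, 0.10),
        "out": (0.60, 0.30, 0.10),
    },
    ("Erwinia", "Rhodococcus"): {
        "Orsay": (0.55, 0.35, 0.10),
        "Santeuil": (0.70, 0.20, 0.10),
        "out": (0.55, 0.35, 0.10),
    },
}

# Per-group modal-allele weight at each microsatellite locus: each genetic
# group concentrates this much frequency on its own modal allele, the rest
# spread over the other alleles.
DEFAULT_MSAT_MODAL_FREQ = 0.8
DEFAULT_MSAT_N_LOCI = 6
DEFAULT_MSAT_ALLELES_PER_LOCUS = 5

# Default planted-effect counts, calibrated to the default 20,000-gene
# universe; scaled proportionally when n_genes differs and the config
# leaves them unset.
DEFAULT_UNIVERSE_SIZE = 20_000
DEFAULT_N_SITE_LINKED_MINOR = 400
DEFAULT_EXPR_DRIVER_COUNTS: dict[str, int] = {
    "dna": 200,
    "site": 300,
    "group": 300,
    "batch": 500,
    "genotype": 250,
}

SITES = ("Orsay", "Santeuil", "out")
GENETIC_GROUPS = ("O", "S1", "S2", "S3", "out")

# Map genetic group -> isolation site of its members.
GROUP_SITE: dict[str, str] = {
    "O": "Orsay",
    "S1": "Santeuil",
    "S2": "Santeuil",
    "S3": "Santeuil",
    "out": "out",
}


@dataclass
class SimConfig:
    """Study design of the synthetic wild-population experiment.

    Defaults emulate a two-site sample of 48 clonal, homozygous strains
    (an orchard population, a woodland population split into one large and
    two small genetic groups, and an out-group) assayed for ~20,000 genes
    on two-probe two-color arrays.
    """

    master_seed: int = 0
    strains_per_group: dict[str, int] = field(
        default_factory=lambda: {"O": 20, "S1": 14, "S2": 3, "S3": 4, "out": 7}
    )
    # One S3 strain was isolated at the orchard site despite clustering with
    # the woodland S3 group; the flag keeps that site/group crossing.
    group_crossing_strain: bool = True
    n_genes: int = 20_000
    probes_per_gene: int = 2
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    chrom_gene_weights: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_GENE_WEIGHTS)
    )
    hotspot_regions: list[tuple[str, int, int, float]] = field(
        default_factory=lambda: list(DEFAULT_HOTSPOTS)
    )
    poly_fraction: float = 0.30
    private_poly_fraction: float = 0.66
    group_linked_fraction: float = 0.06
    multi_carrier_range: tuple[int, int] = (4, 8)
    # None means: the default count (calibrated to the 20,000-gene default
    # universe) scaled proportionally to n_genes
    n_site_linked_minor: int | None = None
    site_minor_effect: float = -0.4
    deletion_effect: float = -1.5
    noise_sd: float = 0.2
    dye_bias_amplitude: float = 0.2
    background_range: tuple[float, float] = (20.0, 60.0)
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.5
    n_batches: int = 2
    class_table: dict[str, tuple[int, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_TABLE)
    )
    # Expression drivers: number of genes whose transcript level is driven
    # by each source of variation; remaining genes are pure noise. None
    # means the defaults below scaled proportionally to n_genes.
    expr_driver_counts: dict[str, int] | None = None
    expr_dna_coefficient: float = 0.8
    expr_effect_sd: float = 0.5
    expr_batch_effect: float = 0.6
    phenotype_effects: dict[str, tuple[float, float, float, float, float, int]] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_EFFECTS)
    )
    choice_preferences: dict[tuple[str, str], dict[str, tuple[float, float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CHOICE_PREFERENCES.items()}
    )
    choice_worms_per_assay: int = 100
    choice_assays_per_strain: int = 2
    msat_n_loci: int = DEFAULT_MSAT_N_LOCI
    msat_alleles_per_locus: int = DEFAULT_MSAT_ALLELES_PER_LOCUS
    msat_modal_freq: float = DEFAULT_MSAT_MODAL_FREQ

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0 or self.probes_per_gene <= 0:
            raise ConfigError("n_genes and probes_per_gene must be positive")
        if any(c <= 0 for c in self.strains_per_group.values()):
            raise ConfigError("strain counts must be positive")
        if set(self.strains_per_group) - set(GENETIC_GROUPS):
            raise ConfigError(
                f"unknown genetic groups: {set(self.strains_per_group) - set(GENETIC_GROUPS)}"
            )
        for name, (frac) in (
            ("poly_fraction", self.poly_fraction),
            ("private_poly_fraction", self.private_poly_fraction),
            ("group_linked_fraction", self.group_linked_fraction),
            ("msat_modal_freq", self.msat_modal_freq),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {frac}")
        if any(l <= 0 for l in self.chromosome_lengths.values()):
            raise ConfigError("chromosome lengths must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if self.n_batches <= 0:
            raise ConfigError("n_batches must be positive")
        for chrom, start, end, rate in self.hotspot_regions:
            if chrom not in self.chromosome_lengths:
                raise ConfigError(f"hotspot on unknown chromosome {chrom!r}")
            if not (0 <= start < end) or rate <= 0:
                raise ConfigError(f"invalid hotspot region {(chrom, start, end, rate)}")

    @property
    def n_strains(self) -> int:
        return sum(self.strains_per_group.values())

    # Fixed offsets for per-component child seeds so each product can be
    # regenerated without the others.
    _SEED_OFFSETS = {
        "design": 1,
        "dna": 2,
        "rna": 3,
        "phenotype": 4,
        "choice": 5,
        "msat": 6,
    }

    def child_seed(self, component: str) -> int:
        return (self.master_seed * 1000 + self._SEED_OFFSETS[component]) % (2**31 - 1)


@dataclass
class RunConfig:
    """Thresholds, sizes and paths for one end-to-end pipeline run."""

    output_dir: str = "wildpopsig_run"
    master_seed: int = 0
    sim: SimConfig | None = None
    minor_threshold: float = 0.5
    major_threshold: float = 1.0
    ma_window: int = 9
    ma_threshold: float = 0.25
    enrichment_min_overlap: int = 3
    enrichment_logp_threshold: float = 2.5
    fdr_target: float = 0.05
    n_permutations: int = 100
    loess_span: float = 0.3
    loess_iterations: int = 3
    background_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = SimConfig(master_seed=self.master_seed)
        for name, v in (
            ("minor_threshold", self.minor_threshold),
            ("major_threshold", self.major_threshold),
            ("ma_window", self.ma_window),
            ("fdr_target", self.fdr_target),
            ("n_permutations", self.n_permutations),
            ("loess_span", self.loess_span),
        ):
            if v <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.minor_threshold > self.major_threshold:
            raise ConfigError("minor_threshold must not exceed major_threshold")
        if self.ma_window % 2 == 0:
            raise ConfigError("ma_window must be odd")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        # YAML-safe: tuple keys to strings
        sim = d["sim"]
        sim["choice_preferences"] = {
            "|".join(k): v for k, v in self.sim.choice_preferences.items()
        }
        Path(path).write_text(yaml.safe_dump(_tuples_to_lists(d), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim_d = d.pop("sim", None)
        sim = None
        if sim_d is not None:
            cp = sim_d.get("choice_preferences")
            if cp is not None:
                sim_d["choice_preferences"] = {
                    tuple(k.split("|")): {s: tuple(p) for s, p in v.items()}
                    for k, v in cp.items()
                }
            for key in ("multi_carrier_range", "background_range"):
                if key in sim_d:
                    sim_d[key] = tuple(sim_d[key])
            if "hotspot_regions" in sim_d:
                sim_d["hotspot_regions"] = [tuple(h) for h in sim_d["hotspot_regions"]]
            if "class_table" in sim_d:
                sim_d["class_table"] = {k: tuple(v) for k, v in sim_d["class_table"].items()}
            if "phenotype_effects" in sim_d:
                sim_d["phenotype_effects"] = {
                    k: tuple(v) for k, v in sim_d["phenotype_effects"].items()
                }
            sim = SimConfig(**sim_d)
        return cls(sim=sim, **d)


def _tuples_to_lists(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj
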