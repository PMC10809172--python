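"""Configuration objects for the synthetic study generator and the analysis pipeline.

The defaults describe a five-sample, four-cohort study of adults with blood
methylation measured on a mix of 450K and EPIC arrays: one large all-female
multi-ethnic cohort, one large family-based cohort, a medium cohort split over
both array generations, and a younger occupational cohort.  Food-group intakes
are driven by a per-person latent "healthy eating" factor so that the three
diet-quality scores computed from them are moderately correlated, and body-mass
index and smoking are both coupled to the same factor to exercise confounding
adjustment downstream.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

#: food-group vocabulary: the union of the components required by the three
#: diet scores (servings/day unless the name carries a unit).
FOOD_GROUPS: tuple[str, ...] = (
    "vegetables",
    "fruits",
    "fruit_juice",
    "nuts",
    "legumes",
    "whole_grains",
    "refined_grains",
    "potatoes",
    "fish",
    "red_processed_meat",
    "dairy_lowfat",
    "dairy_total",
    "eggs",
    "vegetable_oils",
    "tea_coffee",
    "ssb",
    "sweets_desserts",
    "animal_fat",
    "misc_animal",
    "alcohol_g",
    "sodium_mg",
    "mufa_g",
    "sfa_g",
)

SCORE_NAMES: tuple[str, ...] = ("DASH", "HPDI", "MMDS")

#: blood cell types whose estimated fractions enter the EWAS design
CELL_TYPES: tuple[str, ...] = ("NK", "CD8T", "CD4T", "B", "Mono", "Gran")

SMOKING_LEVELS: tuple[str, ...] = ("never", "former", "current")

#: latent healthy-eating factor loadings on log intakes; positive for food
#: groups eaten more by health-conscious participants, negative otherwise.
#: calibrated so that the three scores come out moderately correlated with
#: SDs near published cohort descriptives (part of the correlation between
#: scores also comes from their shared food-group components)
DEFAULT_DIET_LOADINGS: dict[str, float] = {
    "vegetables": 0.11,
    "fruits": 0.11,
    "fruit_juice": -0.04,
    "nuts": 0.09,
    "legumes": 0.08,
    "whole_grains": 0.11,
    "refined_grains": -0.09,
    "potatoes": -0.05,
    "fish": 0.07,
    "red_processed_meat": -0.11,
    "dairy_lowfat": 0.08,
    "dairy_total": -0.02,
    "eggs": -0.03,
    "vegetable_oils": 0.07,
    "tea_coffee": 0.03,
    "ssb": -0.11,
    "sweets_desserts": -0.09,
    "animal_fat": -0.08,
    "misc_animal": -0.06,
    "alcohol_g": 0.0,
    "sodium_mg": -0.07,
    "mufa_g": 0.05,
    "sfa_g": -0.07,
}

#: log-scale intake means (units: servings/day, g/day or mg/day as named)
INTAKE_LOG_MEANS: dict[str, float] = {
    "vegetables": np.log(2.0),
    "fruits": np.log(1.8),
    "fruit_juice": np.log(0.4),
    "nuts": np.log(0.4),
    "legumes": np.log(0.4),
    "whole_grains": np.log(1.2),
    "refined_grains": np.log(1.5),
    "potatoes": np.log(0.6),
    "fish": np.log(0.5),
    "red_processed_meat": np.log(1.0),
    "dairy_lowfat": np.log(0.8),
    "dairy_total": np.log(1.8),
    "eggs": np.log(0.5),
    "vegetable_oils": np.log(1.5),
    "tea_coffee": np.log(2.5),
    "ssb": np.log(0.4),
    "sweets_desserts": np.log(1.0),
    "animal_fat": np.log(0.5),
    "misc_animal": np.log(0.5),
    "alcohol_g": np.log(8.0),
    "sodium_mg": np.log(2500.0),
    "mufa_g": np.log(30.0),
    "sfa_g": np.log(25.0),
}

#: residual log-scale SD of each intake around its latent-factor prediction
INTAKE_LOG_SD = 0.50


@dataclass
class CohortSpec:
    """One cohort (one array sample) of the simulated study."""

    name: str
    n: int
    array: str = "450K"  # '450K' or 'EPIC'
    n_batches: int = 4
    female_fraction: float = 0.5
    multi_ethnic: bool = False
    #: family/chip cluster labels are generated in pairs and a shared family
    #: intercept is planted; the EWAS stage then absorbs the clusters.
    clustered: bool = False
    age_mean: float = 55.0
    age_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"cohort {self.name!r}: n must be positive, got {self.n}")
        if self.array not in ("450K", "EPIC"):
            raise ValueError(f"cohort {self.name!r}: unknown array {self.array!r}")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")


@dataclass
class MqtlConfig:
    """Generator settings for cis-mQTL instruments of the planted CpGs."""

    snps_per_cpg: int = 20
    ld_block_r2: float = 0.3  # r^2 within a 2-SNP LD block
    beta_range: tuple[float, float] = (0.05, 0.15)  # |effect| per SD methylation
    n_exposure: int = 30_000
    maf_range: tuple[float, float] = (0.10, 0.90)
    palindromic_fraction: float = 0.10


@dataclass
class GwasConfig:
    """Generator settings for the outcome GWAS summary statistics."""

    #: causal effect of 1 SD methylation on each trait (log odds for binary)
    theta_per_trait: dict[str, float] = field(
        default_factory=lambda: {"BMI": 0.2, "SBP": 0.15, "TG": 0.1, "T2D": 0.1, "CHD": -0.1}
    )
    binary_traits: tuple[str, ...] = ("T2D", "CHD")
    pleiotropy_sd: float = 0.0
    n_outcome: int = 200_000


def default_cohorts() -> list[CohortSpec]:
    """Five samples in four cohorts, mirroring the unequal sizes, the
    single-sex multi-ethnic sample, the family-based sample, and the
    450K/EPIC split of a typical multi-cohort methylation consortium."""
    return [
        CohortSpec("cohort_a", 1736, "450K", n_batches=6, female_fraction=1.0,
                   multi_ethnic=True, age_mean=64.0, age_sd=7.0),
        CohortSpec("cohort_b", 1843, "450K", n_batches=6, clustered=True,
                   age_mean=66.0, age_sd=9.0),
        CohortSpec("cohort_c", 573, "450K", n_batches=3, age_mean=58.0, age_sd=11.0),
        CohortSpec("cohort_d", 269, "EPIC", n_batches=2, age_mean=56.0, age_sd=7.0),
        CohortSpec("cohort_e", 853, "EPIC", n_batches=4, age_mean=41.0, age_sd=9.0),
    ]


@dataclass
class SimulationConfig:
    """Full specification of a synthetic study; one global seed drives
    deterministic per-cohort substreams."""

    seed: int = 1
    cohorts: list[CohortSpec] = field(default_factory=default_cohorts)
    n_cpgs: int = 2000
    n_diet_cpgs: int = 20
    #: direct effect of 1 SD of diet score on M-values (noise SD is 1,
    #: so this is approximately an M-value SD scale)
    diet_effect_sd: float = 0.07
    #: fraction of diet CpGs that act only through BMI (direct effect 0)
    frac_mediated: float = 0.3
    smoking_effect_sd: float = 0.5
    bmi_effect_sd: float = 0.3
    cell_dirichlet_alpha: tuple[float, ...] = (1.5, 2.4, 4.5, 1.5, 2.1, 18.0)
    batch_effect_sd: float = 0.15
    cell_effect_sd: float = 0.08
    noise_sd: float = 1.0
    latent_diet_loading: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIET_LOADINGS)
    )
    #: liability-scale coupling of smoking to the (negated) latent factor
    smoking_latent_beta: float = 0.5
    bmi_latent_slope: float = 1.2
    bmi_noise_sd: float = 4.4
    family_effect_sd: float = 0.2
    #: fraction of CpGs present on EPIC arrays only
    epic_only_fraction: float = 0.10
    n_smoking_cpgs: int = 100
    n_bmi_cpgs: int = 100
    mqtl: MqtlConfig = field(default_factory=MqtlConfig)
    gwas: GwasConfig = field(default_factory=GwasConfig)

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("at least one cohort is required")
        if self.n_diet_cpgs > self.n_cpgs:
            raise ValueError("n_diet_cpgs cannot exceed n_cpgs")
        if not 0.0 <= self.frac_mediated <= 1.0:
            raise ValueError("frac_mediated must lie in [0, 1]")
        if len(self.cell_dirichlet_alpha) != len(CELL_TYPES):
            raise ValueError(f"cell_dirichlet_alpha needs {len(CELL_TYPES)} entries")
        if any(a <= 0 for a in self.cell_dirichlet_alpha):
            raise ValueError("cell_dirichlet_alpha must be strictly positive")
        unknown = set(self.latent_diet_loading) - set(FOOD_GROUPS)
        if unknown:
            raise ValueError(f"unknown food groups in latent_diet_loading: {sorted(unknown)}")

    def cohort(self, name: str) -> CohortSpec:
        for spec in self.cohorts:
            if spec.name == name:
                return spec
        raise KeyError(f"unknown cohort {name!r}")

    def substream(self, *labels: object) -> np.random.Generator:
        """Deterministic child RNG for a named component of the simulation."""
        key = tuple(zlib.crc32(str(lab).encode()) for lab in labels)
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=key))

    def to_dict(self) -> dict:
        return asdict(self)


def null_config(seed: int = 1,
                cohort_sizes: Sequence[int] = (500, 450, 300, 250),
                n_cpgs: int = 2000) -> SimulationConfig:
    """Global-null study: four modest cohorts, batch and cell structure
    present but no planted diet, BMI or smoking effects on methylation."""
    cohorts = [
        CohortSpec("null_a", cohort_sizes[0], "450K", n_batches=3, female_fraction=1.0),
        CohortSpec("null_b", cohort_sizes[1], "450K", n_batches=3),
        CohortSpec("null_c", cohort_sizes[2], "450K", n_batches=2),
        CohortSpec("null_d", cohort_sizes[3], "EPIC", n_batches=2),
    ]
    return SimulationConfig(
        seed=seed,
        cohorts=cohorts,
        n_cpgs=n_cpgs,
        n_diet_cpgs=0,
        smoking_effect_sd=0.0,
        bmi_effect_sd=0.0,
        n_smoking_cpgs=0,
        n_bmi_cpgs=0,
    )
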