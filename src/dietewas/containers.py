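"""In-memory containers shared across pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DietCpG:
    """Planted diet effect at one CpG.

    ``effect`` is the direct effect of 1 SD of the assigned score on the
    M-value; mediated CpGs have ``effect == 0`` and act on methylation only
    through ``bmi_effect`` (per SD of BMI).
    """

    score: str
    effect: float
    mediated: bool
    bmi_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.mediated and self.effect != 0.0:
            raise ValueError("mediated CpGs must have direct effect 0")


@dataclass
class GroundTruth:
    """Planted simulation parameters, kept for recovery tests."""

    diet_cpgs: dict[str, DietCpG] = field(default_factory=dict)
    smoking_cpgs: dict[str, float] = field(default_factory=dict)
    bmi_cpgs: dict[str, float] = field(default_factory=dict)
    #: (cpg, trait) -> causal effect of 1 SD methylation on the trait
    causal_theta: dict[tuple[str, str], float] = field(default_factory=dict)
    #: (snp, cpg) -> true marginal SNP effect on methylation
    mqtl_effects: dict[tuple[str, str], float] = field(default_factory=dict)

    def direct_cpgs(self) -> list[str]:
        return [c for c, d in self.diet_cpgs.items() if not d.mediated]

    def mediated_cpgs(self) -> list[str]:
        return [c for c, d in self.diet_cpgs.items() if d.mediated]


@dataclass
class CpGUniverse:
    """The CpG panel of the study: annotation (hg19), per-CpG baseline
    M-value, and which array generation carries each probe."""

    annotation: pd.DataFrame  # index cpg; chr, pos, gene, island_relation, position_class, array
    baseline: pd.Series  # index cpg

    def cpgs_for_array(self, array: str) -> pd.Index:
        if array == "EPIC":
            return self.annotation.index
        return self.annotation.index[self.annotation["array"] == "450K"]


@dataclass
class MethylationMatrix:
    """CpG x sample M-value matrix with annotation and batch labels."""

    values: pd.DataFrame  # index cpg, columns participant_id
    annotation: pd.DataFrame  # index cpg (subset matching values)
    batch: pd.Series  # index participant_id
    array: str = "450K"

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("cpg ids must be unique")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("M-values must be finite")
        if list(self.batch.index) != list(self.values.columns):
            self.batch = self.batch.reindex(self.values.columns)

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class StudyData:
    """Everything one synthetic study produces."""

    config: object
    phenotypes: dict[str, pd.DataFrame]
    methylation: dict[str, MethylationMatrix]
    universe: CpGUniverse
    truth: GroundTruth
    mqtl: pd.DataFrame | None = None
    gwas: dict[str, pd.DataFrame] | None = None
    ld: dict[str, pd.DataFrame] | None = None
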