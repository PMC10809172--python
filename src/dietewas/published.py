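"""Bundled summary tables from a published four-cohort diet-quality
meta-EWAS, used as replay inputs.

The package ships three small tables: the printed top-hit meta-analysis
results (effect, SE, p, I^2 per score-CpG pair), the six CpGs re-examined
after BMI adjustment (Model 1 vs Model 2 coefficients), and the cohort
descriptives (sample sizes and female counts).  Replaying the package's own
multiple-testing and attenuation rules on these printed numbers reproduces
the published hit counts without any access-controlled individual-level
data.  The published analysis tested 463,932 CpGs.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .meta import attenuation as _attenuation
from .meta import bonferroni_threshold

#: number of CpGs tested in the published meta-EWAS
PUBLISHED_N_TESTS = 463_932


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("dietewas").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_top_hits() -> pd.DataFrame:
    """Printed top-hit meta-EWAS rows (one per score-CpG pair)."""
    return _load("published_top_hits.tsv")


def load_attenuation_table() -> pd.DataFrame:
    """Printed Model-1/Model-2 coefficients of the BMI-robust CpGs."""
    return _load("published_attenuation.tsv")


def load_cohort_table() -> pd.DataFrame:
    """Published cohort descriptives (five array samples)."""
    return _load("published_cohorts.tsv")


def replay_significance(alpha: float = 0.05) -> dict:
    """Apply the Bonferroni rule to the printed top-hit p-values."""
    hits = load_top_hits()
    threshold = bonferroni_threshold(PUBLISHED_N_TESTS, alpha)
    sig = hits[hits["p"] < threshold]
    return {
        "threshold": threshold,
        "n_rows_significant": int(len(sig)),
        "n_distinct_cpgs": int(sig["cpg"].nunique()),
        "n_per_score": sig.groupby("score")["cpg"].nunique().to_dict(),
    }


def replay_attenuation(threshold: float = 10.0) -> pd.DataFrame:
    """Apply the signed-percent-change rule to the printed M1/M2 betas."""
    table = load_attenuation_table()
    m1 = table.rename(columns={"beta_m1": "beta"})[["cpg", "score", "beta"]]
    m2 = table.rename(columns={"beta_m2": "beta"})[["cpg", "score", "beta"]]
    return _attenuation(m1, m2, threshold=threshold)


def pooled_descriptives() -> dict:
    """Total sample size and pooled female percentage across samples."""
    cohorts = load_cohort_table()
    n = int(cohorts["n"].sum())
    female_pct = 100.0 * cohorts["n_female"].sum() / n
    return {"n_total": n, "female_pct": female_pct}
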