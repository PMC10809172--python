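"""Cross-cohort inverse-variance meta-analysis of per-CpG associations.

Fixed-effect estimates are precision-weighted means; DerSimonian-Laird
moments give the between-cohort variance tau^2 for the random-effects
estimate.  The reported effect per CpG is the fixed one unless heterogeneity
is substantial (I^2 > 0.50 or Cochran Q p < 0.05), in which case the
random-effects estimate is reported.  Multiple testing is controlled both by
Bonferroni across the CpGs analysed in at least two cohorts and by
Benjamini-Hochberg FDR within each score.  Adding BMI to the model and
recomputing the meta-analysis yields the attenuation classification: a CpG
whose coefficient changes by less than 10% (signed) is called
BMI-independent.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class MetaFit:
    k: int
    beta_fixed: float
    se_fixed: float
    Q: float
    p_Q: float
    I2: float
    tau2: float
    beta_random: float
    se_random: float
    single_study: bool = False


def inverse_variance_meta(betas, ses) -> MetaFit:
    """Fixed and DerSimonian-Laird random-effects pooling of one CpG.

    A single study passes through with the single_study flag set.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.shape != s.shape or b.ndim != 1:
        raise ValueError("betas and ses must be 1-d arrays of equal length")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    k = b.size
    if k == 1:
        return MetaFit(1, b[0], s[0], 0.0, 1.0, 0.0, 0.0, b[0], s[0],
                       single_study=True)
    w = 1.0 / s ** 2
    bf = float(np.sum(w * b) / np.sum(w))
    sef = float(np.sqrt(1.0 / np.sum(w)))
    Q = float(np.sum(w * (b - bf) ** 2))
    p_Q = float(stats.chi2.sf(Q, k - 1))
    I2 = float(max(0.0, (Q - (k - 1)) / Q)) if Q > 0 else 0.0
    c = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = float(max(0.0, (Q - (k - 1)) / c)) if c > 0 else 0.0
    wr = 1.0 / (s ** 2 + tau2)
    br = float(np.sum(wr * b) / np.sum(wr))
    ser = float(np.sqrt(1.0 / np.sum(wr)))
    return MetaFit(k, bf, sef, Q, p_Q, I2, tau2, br, ser)


def select_effect(fit: MetaFit, i2_threshold: float = 0.50,
                  q_alpha: float = 0.05) -> tuple[str, float, float, float]:
    """Report the random-effects triplet under substantial heterogeneity
    (I^2 > 0.50 or Q-test p < 0.05), else the fixed-effects triplet."""
    if fit.I2 > i2_threshold or fit.p_Q < q_alpha:
        chosen, beta, se = "random", fit.beta_random, fit.se_random
    else:
        chosen, beta, se = "fixed", fit.beta_fixed, fit.se_fixed
    p = float(np.clip(2.0 * stats.norm.sf(abs(beta / se)), 5e-324, 1.0))
    return chosen, beta, se, p


def bonferroni_threshold(m_tests: int, alpha: float = 0.05) -> float:
    if m_tests <= 0:
        raise ValueError("m_tests must be positive")
    return alpha / m_tests


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def meta_analyse(records: pd.DataFrame, i2_threshold: float = 0.50,
                 q_alpha: float = 0.05, alpha: float = 0.05,
                 m_tests: int | None = None) -> pd.DataFrame:
    """Meta-analyse per-cohort EWAS records grouped by (cpg, score).

    ``records`` needs columns cpg, score, cohort, beta, se (one model at a
    time).  CpGs measured in a single cohort pass through flagged.  The
    Bonferroni test count defaults to the number of CpGs analysed in at
    least two cohorts; FDR is computed within each score.
    """
    required = {"cpg", "score", "cohort", "beta", "se"}
    missing = required - set(records.columns)
    if missing:
        raise KeyError(f"records missing columns: {sorted(missing)}")
    rows = []
    for (cpg, score), grp in records.groupby(["cpg", "score"], sort=True):
        fit = inverse_variance_meta(grp["beta"].to_numpy(), grp["se"].to_numpy())
        chosen, beta, se, p = select_effect(fit, i2_threshold, q_alpha)
        if fit.single_study and "p" in grp.columns:
            # no pooling happened: keep the cohort-level (t-based) p-value
            p = float(grp["p"].iloc[0])
        rows.append({
            "cpg": cpg, "score": score, "k": fit.k,
            "beta_fixed": fit.beta_fixed, "se_fixed": fit.se_fixed,
            "beta_random": fit.beta_random, "se_random": fit.se_random,
            "Q": fit.Q, "p_Q": fit.p_Q, "I2": fit.I2, "tau2": fit.tau2,
            "chosen": chosen, "beta": beta, "se": se, "p": p,
            "single_study": fit.single_study,
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if m_tests is None:
        m_tests = int((out.groupby("cpg")["k"].max() >= 2).sum())
        m_tests = max(m_tests, 1)
    threshold = bonferroni_threshold(m_tests, alpha)
    out["bonferroni_hit"] = out["p"] < threshold
    out["fdr_q"] = np.nan
    for score, idx in out.groupby("score").groups.items():
        out.loc[idx, "fdr_q"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    out.attrs["m_tests"] = m_tests
    out.attrs["bonferroni_threshold"] = threshold
    return out


def flag_hits(meta: pd.DataFrame, threshold: float) -> pd.DataFrame:
    out = meta.copy()
    out["bonferroni_hit"] = out["p"] < threshold
    return out


def attenuation(meta_m1: pd.DataFrame, meta_m2: pd.DataFrame,
                threshold: float = 10.0) -> pd.DataFrame:
    """Signed percentage change of the coefficient after BMI adjustment:
    ``(beta_m1 - beta_m2) / beta_m1 * 100``.

    A signed change below the threshold (default 10%) marks the association
    as BMI-independent; a negative change means the coefficient got stronger
    after adjustment.  CpGs with beta_m1 == 0 are flagged undefined.
    """
    merged = meta_m1[["cpg", "score", "beta"]].merge(
        meta_m2[["cpg", "score", "beta"]], on=["cpg", "score"],
        suffixes=("_m1", "_m2"))
    b1 = merged["beta_m1"].to_numpy()
    b2 = merged["beta_m2"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = (b1 - b2) / b1 * 100.0
    undefined = b1 == 0
    pct = np.where(undefined, np.nan, pct)
    return pd.DataFrame({
        "cpg": merged["cpg"], "score": merged["score"],
        "beta_m1": b1, "beta_m2": b2, "pct_change": pct,
        "bmi_independent": np.where(undefined, False, pct < threshold),
        "undefined": undefined,
    })


def leave_cohort_out(records: pd.DataFrame, cohort: str, **meta_kwargs) -> pd.DataFrame:
    """Re-run the meta-analysis without the named cohort (sensitivity)."""
    if cohort not in set(records["cohort"]):
        raise KeyError(f"unknown cohort {cohort!r}")
    return meta_analyse(records[records["cohort"] != cohort], **meta_kwargs)


def coefficient_correlation(meta_a: pd.DataFrame, meta_b: pd.DataFrame) -> float:
    """Pearson correlation of per-CpG meta coefficients between two scores."""
    merged = meta_a[["cpg", "beta"]].merge(meta_b[["cpg", "beta"]], on="cpg",
                                           suffixes=("_a", "_b"))
    if len(merged) < 10:
        raise ValueError("need at least 10 shared CpGs")
    return float(np.corrcoef(merged["beta_a"], merged["beta_b"])[0, 1])
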