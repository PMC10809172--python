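"""Two-sample Mendelian randomization of methylation on cardiometabolic
traits.

Methylation at a CpG (exposure) is instrumented by its cis-mQTLs; outcome
effects come from GWAS summary statistics.  Instruments are LD-pruned
(greedy, best p-value first, r^2 < 0.8), harmonized to the exposure effect
allele (palindromic SNPs with allele frequencies near 0.5 dropped), and
Steiger-filtered to remove variants explaining more outcome than exposure
variance.  The main estimator is the multiplicative random-effects
inverse-variance weighted (IVW) slope through the origin; MR-Egger and the
weighted median act as pleiotropy-robust sensitivity estimators, and an
assumption checklist (Egger intercept, estimator concordance, Cochran and
Ruecker heterogeneity, instrument strength F > 10) gates the validity flag.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
VALID_ALLELES = {"A", "C", "G", "T"}


@dataclass
class MREstimate:
    beta: float
    se: float
    p: float
    n_snps: int


@dataclass
class EggerFit:
    slope: float
    slope_se: float
    slope_p: float
    intercept: float
    intercept_se: float
    intercept_p: float
    Q_rucker: float
    p_Q_rucker: float
    n_snps: int


@dataclass
class MRResult:
    cpg: str
    outcome: str
    n_snps: int
    ivw: MREstimate | None
    egger: EggerFit | None
    wmedian: MREstimate | None
    Q_cochran: float = np.nan
    p_Qc: float = np.nan
    mean_F: float = np.nan
    checks: dict = field(default_factory=dict)
    valid: bool = False
    binary: bool = False

    def odds_ratio(self) -> tuple[float, float, float]:
        """OR with 95% CI for binary outcomes."""
        if self.ivw is None:
            raise ValueError("no IVW estimate")
        lo = self.ivw.beta - 1.959963984540054 * self.ivw.se
        hi = self.ivw.beta + 1.959963984540054 * self.ivw.se
        return float(np.exp(self.ivw.beta)), float(np.exp(lo)), float(np.exp(hi))


def select_instruments(mqtl: pd.DataFrame, ld: pd.DataFrame | None = None,
                       p_max: float = 1e-8, r2_max: float = 0.8) -> pd.DataFrame:
    """Significance filter then greedy LD pruning, best p-value first.

    A SNP is kept only if its r^2 with every previously kept SNP is below
    ``r2_max``.  An empty result means the CpG has no usable instruments.
    """
    if "cpg" in mqtl.columns and mqtl["cpg"].nunique() > 1:
        raise ValueError("instrument records must share one CpG")
    sig = mqtl[mqtl["p"] < p_max].sort_values(["p", "snp"], kind="mergesort")
    if ld is None or sig.empty:
        return sig.reset_index(drop=True)
    kept: list[str] = []
    for snp in sig["snp"]:
        if snp in ld.index:
            r2 = ld.loc[snp, kept].to_numpy(dtype=float) if kept else np.array([])
            if np.any(r2 >= r2_max):
                continue
        kept.append(snp)
    return sig[sig["snp"].isin(kept)].reset_index(drop=True)


def align_outcome(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Orient outcome records to the exposure effect allele.

    Swapped alleles flip the outcome beta sign and frequency; records whose
    alleles are incompatible with the exposure's are dropped.  Alignment is
    idempotent: re-aligning an aligned table changes nothing.
    """
    for name, df in (("exposure", exposure), ("outcome", outcome)):
        if df["snp"].duplicated().any():
            dups = df.loc[df["snp"].duplicated(), "snp"].tolist()
            raise ValueError(f"duplicate SNP rows in {name}: {dups}")
        bad = ~(df["effect_allele"].isin(VALID_ALLELES)
                & df["other_allele"].isin(VALID_ALLELES))
        if bad.any():
            raise ValueError(f"invalid alleles in {name} records")
    exp = exposure.set_index("snp")
    rows = []
    for _, rec in outcome.iterrows():
        if rec["snp"] not in exp.index:
            continue
        e = exp.loc[rec["snp"]]
        if rec["effect_allele"] == e["effect_allele"] \
                and rec["other_allele"] == e["other_allele"]:
            rows.append(rec)
        elif rec["effect_allele"] == e["other_allele"] \
                and rec["other_allele"] == e["effect_allele"]:
            flipped = rec.copy()
            flipped["effect_allele"] = e["effect_allele"]
            flipped["other_allele"] = e["other_allele"]
            flipped["beta"] = -rec["beta"]
            flipped["eaf"] = 1.0 - rec["eaf"]
            rows.append(flipped)
        # else: allele-incompatible, dropped
    return pd.DataFrame(rows).reset_index(drop=True)


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindrome_window: tuple[float, float] = (0.42, 0.58)) -> pd.DataFrame:
    """Build the harmonized instrument table for one CpG/outcome pair.

    Palindromic (A/T, C/G) SNPs with exposure allele frequency strictly
    inside ``palindrome_window`` are dropped because their strand cannot be
    resolved.
    """
    aligned = align_outcome(exposure, outcome)
    if aligned.empty:
        return pd.DataFrame(columns=["snp", "beta_exp", "se_exp", "beta_out",
                                     "se_out", "eaf", "palindromic", "F",
                                     "wald_ratio"])
    exp = exposure.set_index("snp").loc[aligned["snp"]]
    pal = [
        (ea, oa) in PALINDROMIC
        for ea, oa in zip(exp["effect_allele"], exp["other_allele"])
    ]
    out = pd.DataFrame({
        "snp": aligned["snp"].to_numpy(),
        "beta_exp": exp["beta"].to_numpy(dtype=float),
        "se_exp": exp["se"].to_numpy(dtype=float),
        "beta_out": aligned["beta"].to_numpy(dtype=float),
        "se_out": aligned["se"].to_numpy(dtype=float),
        "eaf": exp["eaf"].to_numpy(dtype=float),
        "palindromic": np.asarray(pal, dtype=bool),
    })
    lo, hi = palindrome_window
    drop = out["palindromic"] & (out["eaf"] > lo) & (out["eaf"] < hi)
    out = out.loc[~drop].reset_index(drop=True)
    out["F"] = (out["beta_exp"] / out["se_exp"]) ** 2
    out["wald_ratio"] = out["beta_out"] / out["beta_exp"]
    return out


def steiger_filter(instruments: pd.DataFrame, n_exp: int, n_out: int) -> pd.DataFrame:
    """Keep SNPs explaining strictly more exposure than outcome variance.

    Variance explained is approximated from the F statistic and sample size,
    r^2 = F / (F + n - 2); ties fail the strict inequality and are removed.
    """
    if n_exp <= 2 or n_out <= 2:
        raise ValueError("sample sizes must exceed 2")
    F_exp = (instruments["beta_exp"] / instruments["se_exp"]) ** 2
    F_out = (instruments["beta_out"] / instruments["se_out"]) ** 2
    r2_exp = F_exp / (F_exp + n_exp - 2)
    r2_out = F_out / (F_out + n_out - 2)
    return instruments.loc[r2_exp > r2_out].reset_index(drop=True)


def ivw_mre(instruments: pd.DataFrame) -> MREstimate:
    """Multiplicative random-effects IVW: weighted regression of outcome on
    exposure effects through the origin (weights 1/se_out^2); the SE is
    scaled by sqrt(max(1, Q/(J-1)))."""
    J = len(instruments)
    if J < 2:
        raise ValueError("IVW needs at least 2 instruments")
    bx = instruments["beta_exp"].to_numpy(dtype=float)
    by = instruments["beta_out"].to_numpy(dtype=float)
    w = 1.0 / instruments["se_out"].to_numpy(dtype=float) ** 2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx ** 2))
    se0 = float(np.sqrt(1.0 / np.sum(w * bx ** 2)))
    Q = float(np.sum(w * (by - beta * bx) ** 2))
    phi = Q / (J - 1)
    se = se0 * np.sqrt(max(1.0, phi))
    p = float(np.clip(2.0 * stats.norm.sf(abs(beta / se)), 5e-324, 1.0))
    return MREstimate(beta, float(se), p, J)


def mr_egger(instruments: pd.DataFrame) -> EggerFit:
    """MR-Egger weighted regression with intercept (directional pleiotropy).

    Exposure effects are orientation-fixed to positive by flipping SNP signs
    first.  Ruecker's Q is the weighted residual sum of squares on J-2 df;
    the multiplicative dispersion sqrt(max(1, Q_r/(J-2))) scales both SEs
    and p-values come from a t distribution on J-2 df.
    """
    J = len(instruments)
    if J < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    flip = np.sign(instruments["beta_exp"].to_numpy(dtype=float))
    flip[flip == 0] = 1.0
    bx = instruments["beta_exp"].to_numpy(dtype=float) * flip
    by = instruments["beta_out"].to_numpy(dtype=float) * flip
    w = 1.0 / instruments["se_out"].to_numpy(dtype=float) ** 2
    X = np.column_stack([np.ones(J), bx])
    WX = X * w[:, None]
    XtWX_inv = np.linalg.inv(X.T @ WX)
    coef = XtWX_inv @ (WX.T @ by)
    resid = by - X @ coef
    Q_r = float(np.sum(w * resid ** 2))
    p_Qr = float(stats.chi2.sf(Q_r, J - 2))
    phi = max(1.0, Q_r / (J - 2))
    cov = XtWX_inv * phi
    se = np.sqrt(np.diag(cov))
    t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), J - 2)
    return EggerFit(float(coef[1]), float(se[1]), float(p[1]),
                    float(coef[0]), float(se[0]), float(p[0]),
                    Q_r, p_Qr, J)


def weighted_median(instruments: pd.DataFrame, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted median of the per-SNP Wald ratios.

    Weights are the inverse Wald-ratio variances (delta method on the
    outcome SE); the estimate interpolates the cumulative weight at 0.5 and
    the SE comes from a seeded parametric bootstrap.
    """
    J = len(instruments)
    if J < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    bx = instruments["beta_exp"].to_numpy(dtype=float)
    by = instruments["beta_out"].to_numpy(dtype=float)
    sx = instruments["se_exp"].to_numpy(dtype=float)
    sy = instruments["se_out"].to_numpy(dtype=float)
    w = bx ** 2 / sy ** 2

    def _wmedian(ratios: np.ndarray, weights: np.ndarray) -> float:
        order = np.argsort(ratios)
        r = ratios[order]
        ww = weights[order]
        cum = (np.cumsum(ww) - 0.5 * ww) / np.sum(ww)
        return float(np.interp(0.5, cum, r))

    est = _wmedian(by / bx, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = bx + sx * rng.standard_normal(J)
        bys = by + sy * rng.standard_normal(J)
        boots[i] = _wmedian(bys / bxs, bxs ** 2 / sy ** 2)
    se = float(np.std(boots, ddof=1))
    p = float(np.clip(2.0 * stats.norm.sf(abs(est / se)), 5e-324, 1.0))
    return MREstimate(est, se, p, J)


def cochran_q(instruments: pd.DataFrame, beta_ivw: float) -> tuple[float, float]:
    """Cochran's Q around the IVW slope, chi-square on J-1 df."""
    J = len(instruments)
    if J < 2:
        raise ValueError("Cochran's Q needs at least 2 instruments")
    bx = instruments["beta_exp"].to_numpy(dtype=float)
    by = instruments["beta_out"].to_numpy(dtype=float)
    w = 1.0 / instruments["se_out"].to_numpy(dtype=float) ** 2
    Q = float(np.sum(w * (by - beta_ivw * bx) ** 2))
    return Q, float(stats.chi2.sf(Q, J - 1))


def assess_assumptions(ivw: MREstimate | None, egger: EggerFit | None,
                       wmedian: MREstimate | None, p_Qc: float,
                       mean_F: float, alpha: float = 0.05) -> tuple[dict, bool]:
    """The pleiotropy/strength checklist gating a result's validity.

    egger_intercept_ok: intercept not significantly non-zero;
    concordance_ok: IVW, Egger slope and weighted median agree in sign;
    heterogeneity_ok: neither Cochran's nor Ruecker's Q significant;
    strength_ok: mean instrument F strictly greater than 10.
    A missing estimator marks its check unknown (None) and voids validity.
    """
    checks: dict[str, bool | None] = {}
    checks["egger_intercept_ok"] = (egger.intercept_p >= alpha) if egger else None
    if ivw is not None and egger is not None and wmedian is not None:
        signs = {np.sign(ivw.beta), np.sign(egger.slope), np.sign(wmedian.beta)}
        checks["concordance_ok"] = len(signs) == 1
    else:
        checks["concordance_ok"] = None
    if egger is not None and np.isfinite(p_Qc):
        checks["heterogeneity_ok"] = (p_Qc >= alpha) and (egger.p_Q_rucker >= alpha)
    else:
        checks["heterogeneity_ok"] = None
    checks["strength_ok"] = bool(mean_F > 10) if np.isfinite(mean_F) else None
    valid = all(v is True for v in checks.values())
    return checks, valid


def run_mr(cpg: str, outcome: str, exposure: pd.DataFrame, outcome_stats: pd.DataFrame,
           ld: pd.DataFrame | None = None, *, n_exp: int | None = None,
           n_out: int | None = None, p_max: float = 1e-8, r2_max: float = 0.8,
           palindrome_window: tuple[float, float] = (0.42, 0.58),
           n_boot: int = 1000, seed: int = 0, binary: bool = False) -> MRResult:
    """Full single-CpG/single-outcome MR: instrument selection, harmonization,
    Steiger filtering, estimation and the assumption checklist."""
    n_exp = int(n_exp if n_exp is not None else exposure["n"].iloc[0])
    n_out = int(n_out if n_out is not None else outcome_stats["n"].iloc[0])
    instruments = select_instruments(exposure, ld, p_max=p_max, r2_max=r2_max)
    if instruments.empty:
        return MRResult(cpg, outcome, 0, None, None, None, binary=binary)
    harm = harmonize(instruments, outcome_stats, palindrome_window)
    harm = steiger_filter(harm, n_exp, n_out)
    J = len(harm)
    if J < 2:
        return MRResult(cpg, outcome, J, None, None, None, binary=binary)
    ivw = ivw_mre(harm)
    Q, p_Qc = cochran_q(harm, ivw.beta)
    egger = mr_egger(harm) if J >= 3 else None
    wmed = weighted_median(harm, n_boot=n_boot, seed=seed) if J >= 3 else None
    mean_F = float(harm["F"].mean())
    checks, valid = assess_assumptions(ivw, egger, wmed, p_Qc, mean_F)
    return MRResult(cpg, outcome, J, ivw, egger, wmed, Q, p_Qc, mean_F,
                    checks, valid, binary)
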