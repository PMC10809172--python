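"""Per-cohort epigenome-wide association of a standardized diet score with
M-values.

Model 1 adjusts for age, total energy intake, sex (omitted in single-sex
cohorts), smoking status, five of the six blood-cell fractions (granulocytes
dropped to avoid exact collinearity with the intercept), an ethnicity dummy
in multi-ethnic cohorts, and k surrogate variables; Model 2 adds BMI.
Family/chip clustering is handled by within-cluster demeaning (fixed-effects
absorption) rather than a random-effects mixed model, which is deterministic
and has no iterative variance-component fit.

Surrogate variables are the top principal components of the sample-space
residuals after regressing each CpG on the base design ("SVA-lite").
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import CELL_TYPES

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)


def m_from_intensities(meth, unmeth, alpha: float = 1.0):
    """M-value from methylated/unmethylated probe intensities:
    ``log2((meth + alpha) / (unmeth + alpha))`` with offset ``alpha = 1``."""
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if np.any(meth < 0) or np.any(unmeth < 0):
        raise ValueError("intensities must be non-negative")
    return np.log2((meth + alpha) / (unmeth + alpha))


def m_from_beta(beta):
    """M-value from a beta-value (proportion methylated): ``log2(b/(1-b))``."""
    beta = np.asarray(beta, dtype=float)
    if np.any(beta <= 0) or np.any(beta >= 1):
        raise ValueError("beta-values must lie strictly in (0, 1)")
    return np.log2(beta / (1.0 - beta))


def scale_mvalues(values: pd.DataFrame) -> pd.DataFrame:
    """Standardize each CpG row to mean 0, SD 1 (n-1 denominator).

    Zero-variance CpGs are dropped with a warning; effect sizes downstream
    are then on the M-value SD scale.
    """
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance CpGs", int((~keep).sum()))
    arr = arr[keep]
    arr = (arr - arr.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return pd.DataFrame(arr, index=values.index[keep], columns=values.columns)


def build_design(phenotypes: pd.DataFrame, score_z: pd.Series, model: str = "M1",
                 surrogates: np.ndarray | None = None,
                 include_smoking: bool = True) -> pd.DataFrame:
    """Design matrix for one cohort/score/model, columns named.

    The score column is called ``score``; smoking enters as former/current
    dummies with never-smokers as the reference; the sex dummy is omitted in
    single-sex cohorts and the ethnicity dummy only appears when more than
    one ethnicity is present.
    """
    if model not in ("M1", "M2"):
        raise ValueError(f"unknown model {model!r}")
    needed = ["age", "energy", "sex", "smoking"] + list(CELL_TYPES)
    if model == "M2":
        needed.append("bmi")
    missing = [c for c in needed if c not in phenotypes.columns]
    if missing:
        raise KeyError(f"missing covariates: {missing}")

    X = pd.DataFrame(index=phenotypes.index)
    X["intercept"] = 1.0
    X["score"] = np.asarray(score_z, dtype=float)
    X["age"] = phenotypes["age"].astype(float)
    X["energy"] = phenotypes["energy"].astype(float)
    if phenotypes["sex"].nunique() > 1:
        X["sex_M"] = (phenotypes["sex"] == "M").astype(float)
    if include_smoking:
        # never-smokers are the reference; a level absent from the cohort
        # contributes no column
        for level in ("former", "current"):
            if (phenotypes["smoking"] == level).any():
                X[f"smoking_{level}"] = \
                    (phenotypes["smoking"] == level).astype(float)
    for cell in CELL_TYPES[:-1]:  # granulocytes dropped
        X[cell] = phenotypes[cell].astype(float)
    if "ethnicity" in phenotypes.columns and phenotypes["ethnicity"].nunique() > 1:
        X["ethnicity_nonwhite"] = (phenotypes["ethnicity"] != "white").astype(float)
    if surrogates is not None and np.size(surrogates):
        sv = np.atleast_2d(np.asarray(surrogates, dtype=float))
        if sv.shape[0] != len(phenotypes):
            sv = sv.T
        for j in range(sv.shape[1]):
            X[f"sv{j + 1}"] = sv[:, j]
    if model == "M2":
        X["bmi"] = phenotypes["bmi"].astype(float)

    arr = X.to_numpy()
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        _, r, piv = _qr_pivot(arr)
        d = np.abs(np.diag(r))
        bad = [X.columns[piv[i]] for i in range(len(d)) if d[i] < 1e-8 * d[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X


def _qr_pivot(arr: np.ndarray):
    from scipy.linalg import qr
    return qr(arr, mode="economic", pivoting=True)


def estimate_surrogates(values: pd.DataFrame, design: pd.DataFrame, k: int,
                        max_cpgs: int = 2000) -> np.ndarray:
    """Top-k principal components of sample-space residuals.

    Each CpG is regressed on the base design; the residual matrix's leading
    right singular vectors (length n samples) are returned as orthonormal
    columns, each with its first non-negligible loading made positive.  For
    speed on large panels, an evenly spaced subset of at most ``max_cpgs``
    CpGs is used.
    """
    n = design.shape[0]
    if k <= 0:
        return np.empty((n, 0))
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    Y = values.to_numpy(dtype=float)
    if Y.shape[0] > max_cpgs:
        step = int(np.ceil(Y.shape[0] / max_cpgs))
        Y = Y[::step]
    X = design.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    R = Y - (X @ coef).T
    # eigen-decomposition on the smaller Gram matrix
    if R.shape[0] <= R.shape[1]:
        G = R @ R.T
        w, U = np.linalg.eigh(G)
        order = np.argsort(w)[::-1][:k]
        sv = np.sqrt(np.maximum(w[order], 1e-30))
        V = (R.T @ U[:, order]) / sv
    else:
        G = R.T @ R
        w, V = np.linalg.eigh(G)
        V = V[:, np.argsort(w)[::-1][:k]]
    # orthonormalize defensively and fix signs
    Q, _ = np.linalg.qr(V)
    for j in range(Q.shape[1]):
        nz = np.nonzero(np.abs(Q[:, j]) > 1e-12)[0]
        if nz.size and Q[nz[0], j] < 0:
            Q[:, j] = -Q[:, j]
    return Q


def _demean_within(arr: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    sums = np.zeros((n_groups,) + arr.shape[1:])
    np.add.at(sums, codes, arr)
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    means = sums / counts.reshape((n_groups,) + (1,) * (arr.ndim - 1))
    return arr - means[codes]


def fit_ewas(values: pd.DataFrame, design: pd.DataFrame, score_col: str = "score",
             cluster_id: pd.Series | None = None,
             cluster_mode: str = "robust") -> pd.DataFrame:
    """Per-CpG least squares of M-values on the design matrix.

    Returns beta/se/p (two-sided t) for the score column, one row per CpG.
    Family/chip clustering (``cluster_id``) is handled either by
    ``cluster_mode="robust"`` — OLS point estimates with Liang-Zeger
    cluster-robust standard errors (CR1 scaling, t on G-1 df), the default,
    which like a random-effects mixed model keeps between-cluster
    information — or by ``cluster_mode="absorb"`` — within-cluster demeaning
    (fixed-effects absorption) with the residual degrees of freedom reduced
    by the number of clusters.
    """
    if cluster_mode not in ("robust", "absorb"):
        raise ValueError(f"unknown cluster_mode {cluster_mode!r}")
    Y = values.to_numpy(dtype=float)
    finite = np.isfinite(Y).all(axis=1)
    if not finite.all():
        logger.warning("skipping %d CpGs with non-finite M-values",
                       int((~finite).sum()))
        Y = Y[finite]
    index = values.index[finite]
    X = design.to_numpy(dtype=float)
    cols = list(design.columns)
    n = X.shape[0]
    if Y.shape[1] != n:
        raise ValueError("methylation and design sample counts differ")

    codes = n_groups = None
    if cluster_id is not None:
        labels, codes = np.unique(np.asarray(cluster_id), return_inverse=True)
        n_groups = len(labels)
    if cluster_id is not None and cluster_mode == "absorb":
        Y = _demean_within(Y.T, codes, n_groups).T
        keep = [c for c in cols if c != "intercept"]
        X = _demean_within(design[keep].to_numpy(dtype=float), codes, n_groups)
        cols = keep
        dof = n - n_groups - X.shape[1]
        codes = None  # conventional (homoskedastic) SEs after absorption
    else:
        dof = n - X.shape[1]
    if dof < 3:
        raise ValueError(f"not enough residual degrees of freedom (dof={dof})")

    j = cols.index(score_col)
    XtX_inv = np.linalg.pinv(X.T @ X)
    proj = XtX_inv @ X.T
    B = Y @ proj.T
    resid = Y - B @ X.T
    beta = B[:, j]
    if codes is not None:
        # sandwich variance of the score coefficient: per cluster g,
        # var_j = sum_g (a' X_g' r_g)^2 with a = (X'X)^-1 e_j
        a = XtX_inv[:, j]
        u = X @ a
        var = np.zeros(Y.shape[0])
        for g in range(n_groups):
            idx = np.flatnonzero(codes == g)
            var += (resid[:, idx] @ u[idx]) ** 2
        cr1 = (n_groups / (n_groups - 1)) * ((n - 1) / dof)
        se = np.sqrt(cr1 * var)
        t_dof = n_groups - 1
    else:
        sigma2 = (resid ** 2).sum(axis=1) / dof
        se = np.sqrt(sigma2 * XtX_inv[j, j])
        t_dof = dof
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), t_dof)
    p = np.clip(p, 5e-324, 1.0)
    return pd.DataFrame({"beta": beta, "se": se, "p": p, "n": n},
                        index=pd.Index(index, name="cpg"))


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: the median association chi-square statistic
    divided by the null median (~0.455)."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 100:
        raise ValueError("need at least 100 p-values to estimate lambda")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def stratified_ewas(values: pd.DataFrame, phenotypes: pd.DataFrame,
                    score_z: pd.Series, model: str = "M1",
                    surrogates: np.ndarray | None = None,
                    cluster_id: pd.Series | None = None) -> dict[str, pd.DataFrame]:
    """EWAS separately in never vs ever (former + current) smokers.

    Smoking dummies are removed from the stratum designs.  Strata too small
    to fit are skipped with a warning.
    """
    strata = {
        "never": phenotypes["smoking"] == "never",
        "ever": phenotypes["smoking"].isin(["former", "current"]),
    }
    out: dict[str, pd.DataFrame] = {}
    for name, mask in strata.items():
        sub = phenotypes.loc[mask]
        if sub.empty:
            logger.warning("stratum %r is empty; skipped", name)
            continue
        sv = None
        if surrogates is not None and np.size(surrogates):
            sv = np.asarray(surrogates)[np.asarray(mask), :]
        design = build_design(sub, score_z.loc[mask], model=model, surrogates=sv,
                              include_smoking=False)
        if design.shape[0] <= design.shape[1] + 2:
            logger.warning("stratum %r too small (n=%d); skipped", name, len(sub))
            continue
        vals = values.loc[:, sub["participant_id"]]
        cl = cluster_id.loc[mask] if cluster_id is not None else None
        out[name] = fit_ewas(vals, design, cluster_id=cl)
    return out
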