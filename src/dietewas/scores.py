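"""Diet-quality indices from food-group intakes.

Three food-based scores are computed per cohort:

* **DASH** (Dietary Approaches to Stop Hypertension), 8 components scored
  1-5 by cohort-specific quintiles (sodium, sugar-sweetened beverages and
  red/processed meat reverse-scored), total range 8-40.
* **HPDI** (Healthful Plant-based Diet Index), 18 components scored 1-5 by
  quintiles: 7 healthy plant foods positive, 5 less-healthy plant foods and
  6 animal foods reverse-scored, total range 18-90.
* **MMDS** (Modified Mediterranean Diet Score), 8 monotone components scored
  0-3 by cohort quartiles (red/processed meat reverse), plus 3 points for
  moderate alcohol intake inside a sex-specific window, total range 0-27.

Quantile scoring uses average ranks with right-closed bin boundaries, which
makes the scores invariant to any strictly monotone transform of an intake.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DASH_POSITIVE = ("fruits", "vegetables", "nuts_legumes", "dairy_lowfat", "whole_grains")
DASH_NEGATIVE = ("sodium_mg", "ssb", "red_processed_meat")

HPDI_HEALTHY_PLANT = ("whole_grains", "fruits", "vegetables", "nuts", "legumes",
                      "vegetable_oils", "tea_coffee")
HPDI_UNHEALTHY_PLANT = ("fruit_juice", "refined_grains", "potatoes", "ssb",
                        "sweets_desserts")
HPDI_ANIMAL = ("animal_fat", "dairy_total", "eggs", "fish", "red_processed_meat",
               "misc_animal")

MMDS_POSITIVE = ("vegetables", "fruits", "nuts", "legumes", "whole_grains", "fish",
                 "mufa_sfa_ratio")
MMDS_NEGATIVE = ("red_processed_meat",)

#: moderate-alcohol window (g/day) scoring 3 points, by sex
DEFAULT_ALCOHOL_WINDOWS = {"F": (5.0, 25.0), "M": (10.0, 50.0)}

#: default sex-specific plausible energy-intake bounds (kcal/day)
DEFAULT_ENERGY_BOUNDS = {"F": (500.0, 3500.0), "M": (800.0, 4200.0)}


def quantile_scores(values, n_bins: int, *, reverse: bool = False,
                    low: int = 1) -> np.ndarray:
    """Score a component into ``low .. low+n_bins-1`` by empirical quantiles.

    Ties take average ranks; bin boundaries are right-closed, so a value
    sitting exactly on a boundary falls into the lower bin.  A constant
    component has no quantiles: every participant receives the (rounded)
    midpoint score and a warning is emitted.
    """
    x = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("component contains non-finite values")
    if np.unique(x).size == 1:
        warnings.warn("constant component: assigning midpoint score", stacklevel=2)
        mid = int(round(low + (n_bins - 1) / 2))
        return np.full(x.shape, mid, dtype=int)
    ranks = stats.rankdata(x)
    edges = np.quantile(ranks, np.arange(1, n_bins) / n_bins)
    bins = np.searchsorted(edges, ranks, side="left")
    if reverse:
        bins = (n_bins - 1) - bins
    return (low + bins).astype(int)


def filter_implausible_energy(table: pd.DataFrame,
                              bounds: dict[str, tuple[float, float]] | None = None
                              ) -> pd.DataFrame:
    """Drop energy under- and over-reporters using sex-specific bounds.

    Rows with a missing energy value are removed with a warning.  The number
    of removals is logged.
    """
    bounds = bounds if bounds is not None else DEFAULT_ENERGY_BOUNDS
    for sex, (lo, hi) in bounds.items():
        if lo <= 0 or hi <= 0 or lo >= hi:
            raise ValueError(f"invalid energy bounds for sex {sex!r}: ({lo}, {hi})")
    energy = pd.to_numeric(table["energy"], errors="coerce")
    missing = energy.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} rows with missing energy removed")
    lo = table["sex"].map({s: b[0] for s, b in bounds.items()})
    hi = table["sex"].map({s: b[1] for s, b in bounds.items()})
    keep = (~missing) & (energy >= lo) & (energy <= hi)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("energy filter removed %d of %d participants", n_removed, len(table))
    out = table.loc[keep].copy()
    out.attrs["n_energy_excluded"] = n_removed
    return out


def _require(table: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise KeyError(f"missing intake columns: {missing}")


def _complete_mask(table: pd.DataFrame, columns, score: str) -> pd.Series:
    ok = table[list(columns)].notna().all(axis=1)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("%s: %d participants excluded for missing intakes", score, n_excluded)
    return ok


def compute_dash(table: pd.DataFrame) -> pd.Series:
    """DASH score per participant (range 8-40); NaN where an intake is missing."""
    base = ("fruits", "vegetables", "nuts", "legumes", "dairy_lowfat",
            "whole_grains", "sodium_mg", "ssb", "red_processed_meat")
    _require(table, base)
    ok = _complete_mask(table, base, "DASH")
    sub = table.loc[ok]
    comp = pd.DataFrame(index=sub.index)
    comp["nuts_legumes"] = sub["nuts"] + sub["legumes"]
    for c in ("fruits", "vegetables", "dairy_lowfat", "whole_grains",
              "sodium_mg", "ssb", "red_processed_meat"):
        comp[c] = sub[c]
    total = np.zeros(len(sub), dtype=int)
    for c in DASH_POSITIVE:
        total += quantile_scores(comp[c], 5)
    for c in DASH_NEGATIVE:
        total += quantile_scores(comp[c], 5, reverse=True)
    out = pd.Series(np.nan, index=table.index, name="dash_raw")
    out.loc[ok] = total
    return out


def compute_hpdi(table: pd.DataFrame) -> pd.Series:
    """HPDI score per participant (range 18-90); NaN where an intake is missing."""
    needed = HPDI_HEALTHY_PLANT + HPDI_UNHEALTHY_PLANT + HPDI_ANIMAL
    _require(table, needed)
    ok = _complete_mask(table, needed, "HPDI")
    sub = table.loc[ok]
    total = np.zeros(len(sub), dtype=int)
    for c in HPDI_HEALTHY_PLANT:
        total += quantile_scores(sub[c], 5)
    for c in HPDI_UNHEALTHY_PLANT + HPDI_ANIMAL:
        total += quantile_scores(sub[c], 5, reverse=True)
    out = pd.Series(np.nan, index=table.index, name="hpdi_raw")
    out.loc[ok] = total
    return out


def compute_mmds(table: pd.DataFrame,
                 alcohol_windows: dict[str, tuple[float, float]] | None = None,
                 ratio_cap_quantile: float = 0.99) -> pd.Series:
    """MMDS score per participant (range 0-27); NaN where an intake is missing.

    The MUFA:SFA ratio is capped at its cohort ``ratio_cap_quantile`` before
    quartile binning so that near-zero SFA intakes cannot blow the ratio up.
    """
    alcohol_windows = alcohol_windows or DEFAULT_ALCOHOL_WINDOWS
    needed = ("vegetables", "fruits", "nuts", "legumes", "whole_grains", "fish",
              "red_processed_meat", "mufa_g", "sfa_g", "alcohol_g")
    _require(table, needed)
    ok = _complete_mask(table, needed, "MMDS")
    sub = table.loc[ok]
    with np.errstate(divide="ignore"):
        ratio = np.asarray(sub["mufa_g"], float) / np.asarray(sub["sfa_g"], float)
    finite = np.isfinite(ratio)
    if not finite.all():
        cap_base = ratio[finite]
        cap = np.quantile(cap_base, ratio_cap_quantile) if cap_base.size else 1.0
        ratio = np.where(finite, ratio, cap)
    ratio = np.minimum(ratio, np.quantile(ratio, ratio_cap_quantile))

    total = np.zeros(len(sub), dtype=int)
    for c in ("vegetables", "fruits", "nuts", "legumes", "whole_grains", "fish"):
        total += quantile_scores(sub[c], 4, low=0)
    total += quantile_scores(ratio, 4, low=0)
    total += quantile_scores(sub["red_processed_meat"], 4, low=0, reverse=True)

    lo = sub["sex"].map({s: w[0] for s, w in alcohol_windows.items()})
    hi = sub["sex"].map({s: w[1] for s, w in alcohol_windows.items()})
    alcohol = pd.to_numeric(sub["alcohol_g"])
    total += np.where((alcohol >= lo) & (alcohol <= hi), 3, 0)

    out = pd.Series(np.nan, index=table.index, name="mmds_raw")
    out.loc[ok] = total
    return out


def compute_all_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Raw MMDS/DASH/HPDI for one cohort, indexed like ``table``."""
    return pd.DataFrame(
        {
            "participant_id": table["participant_id"],
            "mmds_raw": compute_mmds(table),
            "dash_raw": compute_dash(table),
            "hpdi_raw": compute_hpdi(table),
        },
        index=table.index,
    )


RAW_TO_Z = {"mmds_raw": "mmds_z", "dash_raw": "dash_z", "hpdi_raw": "hpdi_z"}
SCORE_TO_RAW = {"MMDS": "mmds_raw", "DASH": "dash_raw", "HPDI": "hpdi_raw"}
SCORE_TO_Z = {"MMDS": "mmds_z", "DASH": "dash_z", "HPDI": "hpdi_z"}


def standardize_scores(scores: pd.DataFrame,
                       cohort: pd.Series | None = None) -> pd.DataFrame:
    """Per-cohort z-standardization of the raw scores (n-1 denominator).

    ``cohort`` assigns each row to a cohort; omitted means a single cohort.
    A score that is constant within a cohort raises a ValueError naming it.
    """
    out = scores.copy()
    groups = cohort if cohort is not None else pd.Series("all", index=scores.index)
    for raw, z in RAW_TO_Z.items():
        if raw not in scores.columns:
            continue
        col = scores[raw]
        zvals = pd.Series(np.nan, index=scores.index)
        for name, idx in col.groupby(groups).groups.items():
            vals = col.loc[idx]
            sd = vals.std(ddof=1)
            if not sd > 0:
                raise ValueError(f"score {raw!r} is constant in cohort {name!r}")
            zvals.loc[idx] = (vals - vals.mean()) / sd
        out[z] = zvals
    return out


def score_correlations(scores: pd.DataFrame) -> pd.DataFrame:
    """3x3 Pearson correlation matrix of the raw scores for one cohort."""
    cols = [c for c in ("mmds_raw", "dash_raw", "hpdi_raw") if c in scores.columns]
    sub = scores[cols].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 participants with complete scores")
    constant = [c for c in cols if sub[c].nunique() == 1]
    if constant:
        warnings.warn(f"constant scores, correlation undefined: {constant}")
    with np.errstate(invalid="ignore"):
        return sub.corr(method="pearson")
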