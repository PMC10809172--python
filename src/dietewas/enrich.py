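"""Overrepresentation tests for genes and CpG categories.

The gene engine is a one-sided hypergeometric test of a foreground gene list
against user-supplied gene-set collections (GMT format); the category engine
runs per-category 2x2 Fisher exact tests of hit CpGs versus the tested
background for positional classes, island relation or chromatin-state
labels.  No probe-number bias correction is applied: genes annotated to many
CpGs are more likely to be hit, so background choice matters.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .meta import bh_fdr


def gene_overrepresentation(foreground, background,
                            collection: dict[str, set[str]]) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of the foreground in each set.

    The universe for each set is the background; set members outside the
    background are ignored.  BH FDR is computed across sets.
    """
    fg = set(foreground)
    bg = set(background)
    stray = fg - bg
    if stray:
        raise ValueError(f"foreground genes absent from background: {sorted(stray)}")
    if not collection:
        raise ValueError("empty gene-set collection")
    rows = []
    N, k = len(bg), len(fg)
    for name, members in collection.items():
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        m = len(set(members) & bg)
        x = len(set(members) & fg)
        # P(X >= x) for X ~ Hypergeom(N, m, k)
        p = float(stats.hypergeom.sf(x - 1, N, m, k)) if m else 1.0
        rows.append({"set": name, "set_size": m, "overlap": x,
                     "p": min(max(p, 5e-324), 1.0)})
    out = pd.DataFrame(rows)
    out["fdr_q"] = bh_fdr(out["p"].to_numpy())
    return out


def category_overrepresentation(hit_categories: pd.Series,
                                background_categories: pd.Series) -> pd.DataFrame:
    """Per-category Fisher exact test of hit CpGs vs the non-hit background.

    ``background_categories`` covers every tested CpG (hits included).  A
    zero-margin table gives p = 1 with the degenerate flag set.
    """
    hits = pd.Series(hit_categories)
    bg = pd.Series(background_categories)
    if len(hits) > len(bg):
        raise ValueError("more hits than background CpGs")
    n_hit, n_bg = len(hits), len(bg)
    rows = []
    for cat in sorted(bg.unique()):
        a = int((hits == cat).sum())           # hits in category
        b = n_hit - a                          # hits outside
        c = int((bg == cat).sum()) - a         # non-hit in category
        d = (n_bg - n_hit) - c                 # non-hit outside
        table = np.array([[a, b], [c, d]])
        degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
        if degenerate:
            odds, p = np.nan, 1.0
        else:
            odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"category": cat, "hits_in": a, "background_in": a + c,
                     "odds_ratio": odds, "p": p, "degenerate": degenerate})
    out = pd.DataFrame(rows)
    out["fdr_q"] = bh_fdr(out["p"].to_numpy())
    return out
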