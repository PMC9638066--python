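"""Stage-wise correlation screening of vegetation indices against traits.

For each (index, stage) cell, the sample Pearson correlation between
plot-level index values and the trait is computed with its two-sided
t-distribution p-value (significance starred at 0.05 and 0.01).  NUE traits
exclude the unfertilized plots, where they are undefined.

A generality score summarizes how robust each index is across acquisition
dates: per stage, indices are ranked by |r| (rank 1 = strongest, ties
averaged), then

    score = w * mean(rank over stages) + (1 - w) * max(rank over stages)

with w in [0, 1] (default 0.5); lower is better.  This weighted mean/max
rank-sum is a documented reconstruction of the rank-aggregation idea behind
date-robust index selection, not a published formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, InvalidConfigError

TRAIT_COLUMNS = {"yield": "yield_kg_ha", "npfp": "npfp", "anue": "anue"}


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p-value (t distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidConfigError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise InvalidConfigError("need n >= 3 for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateFitError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ScreeningResult:
    """r / p matrices (index x stage) plus significance flags for one trait."""

    trait: str
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    significance: pd.DataFrame  # "", "*", or "**"

    def stars(self, alpha1: float = 0.05, alpha2: float = 0.01) -> pd.DataFrame:
        out = self.p.map(lambda v: "**" if v < alpha2 else ("*" if v < alpha1 else "NS"))
        return out


def correlation_screen(vi_table: pd.DataFrame, trait_table: pd.DataFrame, trait: str) -> ScreeningResult:
    """Full (index x stage) correlation matrix of plot VI values vs one trait."""
    if trait not in TRAIT_COLUMNS:
        raise InvalidConfigError(f"trait must be one of {sorted(TRAIT_COLUMNS)}")
    col = TRAIT_COLUMNS[trait]
    tvals = trait_table[["plot_id", col]].dropna()
    merged = vi_table.merge(tvals, on="plot_id", how="inner")

    indices = list(dict.fromkeys(vi_table["index"]))
    stages = list(dict.fromkeys(vi_table["stage"]))
    r = pd.DataFrame(np.nan, index=indices, columns=stages)
    p = pd.DataFrame(np.nan, index=indices, columns=stages)
    n = pd.DataFrame(0, index=indices, columns=stages)
    for (idx, stage), cell in merged.groupby(["index", "stage"], sort=False):
        n.loc[idx, stage] = len(cell)
        if len(cell) < 3:
            continue  # flagged by NaN r/p; not fatal
        try:
            r_val, p_val = pearson_r(cell["value"], cell[col])
        except DegenerateFitError:
            continue
        r.loc[idx, stage] = r_val
        p.loc[idx, stage] = p_val
    sig = p.map(lambda v: "**" if v < 0.01 else ("*" if v < 0.05 else ("NS" if np.isfinite(v) else "")))
    return ScreeningResult(trait=trait, r=r, p=p, n=n, significance=sig)


def generality_score(screen: ScreeningResult, w: float = 0.5) -> pd.DataFrame:
    """Stage-robustness ranking of indices from their |r| ranks (lower = better)."""
    if not 0 <= w <= 1:
        raise InvalidConfigError("weight w must lie in [0, 1]")
    r_abs = screen.r.abs()
    if r_abs.shape[0] < 2 or r_abs.shape[1] < 1:
        raise InvalidConfigError("need >= 2 indices and >= 1 stage")
    # per-stage ranks: rank 1 = largest |r|, ties -> average rank
    ranks = r_abs.apply(lambda colvals: pd.Series(
        stats.rankdata(-colvals.to_numpy(), method="average"), index=colvals.index
    ))
    score = w * ranks.mean(axis=1) + (1 - w) * ranks.max(axis=1)
    out = pd.DataFrame({
        "mean_rank": ranks.mean(axis=1),
        "max_rank": ranks.max(axis=1),
        "score": score,
    })
    out["rank"] = stats.rankdata(out["score"].to_numpy(), method="average")
    return out.sort_values("score")
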