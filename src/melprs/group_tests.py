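"""Nonparametric comparison of score distributions across phenotypic strata.

Score distributions are compared among groups (case vs. control, or
phenotype categories within cases) with the Kruskal-Wallis rank test,
tie-corrected, with a chi-square approximation for the p-value. The
stratum summary mirrors the stratified descriptive tables of a
case-control PRS study: n, mean (SD), median (Q1, Q3) per stratum plus
the Kruskal-Wallis p-value, with missing phenotype values excluded
pairwise per comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["KWResult", "kruskal_wallis", "strata_summary"]


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p_value: float


def kruskal_wallis(groups: Sequence[np.ndarray]) -> KWResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (df = groups - 1).

    All values are ranked jointly with midranks for ties;
    H = [12/(N(N+1))] * sum n_j (Rbar_j - Rbar)^2, divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N). Raises when fewer than two
    groups, an empty group, or all values identical (H undefined after
    tie correction).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    if sum(g.size for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical; H undefined after tie correction")
    h, p = stats.kruskal(*groups)
    return KWResult(H=float(h), df=len(groups) - 1, p_value=float(p))


def _fmt(x: float, nd: int = 3) -> str:
    return f"{x:.{nd}f}"


def strata_summary(
    scores: np.ndarray,
    phenotype: pd.Series | np.ndarray,
    variable: str = "phenotype",
) -> tuple[pd.DataFrame, KWResult]:
    """Per-stratum score summaries plus a Kruskal-Wallis comparison.

    Individuals with a missing phenotype value are excluded from this
    comparison only. Strata left empty after exclusion are omitted with a
    warning. Quartiles use linear interpolation between order statistics,
    the same quantile rule as the decile cutpoints.

    Returns a table with columns (variable, stratum, n, mean_sd,
    median_q1_q3, p_value — 3 d.p., p on the first row only) and the raw
    test result.
    """
    scores = np.asarray(scores, dtype=float)
    pheno = pd.Series(phenotype).reset_index(drop=True)
    if len(pheno) != scores.size:
        raise ValueError("scores and phenotype must have the same length")
    present = pheno.notna().to_numpy() & ~np.isnan(scores)
    all_strata = list(pd.unique(pheno.dropna()))
    pheno = pheno[present]
    vals = scores[present]

    strata = [s for s in all_strata if (pheno == s).any()]
    dropped = set(all_strata) - set(strata)
    for s in dropped:
        warnings.warn(f"stratum {s!r} empty after missing-value exclusion; omitted")

    group_values = [vals[(pheno == s).to_numpy()] for s in strata]
    kw = kruskal_wallis(group_values)

    rows = []
    for i, (s, g) in enumerate(zip(strata, group_values)):
        mean = _fmt(g.mean())
        sd = _fmt(g.std(ddof=1)) if g.size > 1 else ""
        q1, med, q3 = (np.quantile(g, q) for q in (0.25, 0.5, 0.75))
        rows.append(
            {
                "variable": variable,
                "stratum": str(s),
                "n": int(g.size),
                "mean_sd": f"{mean} ({sd})" if sd else mean,
                "median_q1_q3": f"{_fmt(med)} ({_fmt(q1)}, {_fmt(q3)})",
                "p_value": _fmt(kw.p_value) if i == 0 else "",
            }
        )
    return pd.DataFrame(rows), kw
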