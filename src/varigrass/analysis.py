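"""Cohort-level statistics and reporting.

Summary statistics, Scott's-rule histogram binning, ordinary
least-squares trend fits with R^2 for the standard metric pairs (process
ethanol yield vs FCMF, field ethanol yield vs biomass yield, MFSP and the
three life-cycle impacts vs biomass yield, ...), filter tallies, and
process-contribution reports for representative genotypes spanning the
yield and FCMF ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lca import IMPACTS, STAGES, ImpactResult

__all__ = [
    "RegressionResult",
    "CohortSummary",
    "scott_bin_width",
    "fit_r2",
    "summarize_cohort",
    "select_pca_variants",
    "contribution_shares",
    "contribution_report",
]

#: Metric columns summarized for a results table.
METRIC_COLUMNS = (
    "commercial_yield_Mg_ha",
    "fcmf",
    "process_yield_L_Mg",
    "field_yield_L_ha",
    "mfsp_usd_L",
    "gwp_g_L",
    "ced_MJ_L",
    "aware_m3_L",
)

#: (x, y) regression pairs reported by default: the six standard
#: metric-vs-driver panels plus the three impact-vs-yield trends.
DEFAULT_REGRESSIONS = (
    ("fcmf", "mfsp_usd_L"),
    ("commercial_yield_Mg_ha", "mfsp_usd_L"),
    ("fcmf", "process_yield_L_Mg"),
    ("commercial_yield_Mg_ha", "process_yield_L_Mg"),
    ("fcmf", "field_yield_L_ha"),
    ("commercial_yield_Mg_ha", "field_yield_L_ha"),
    ("commercial_yield_Mg_ha", "gwp_g_L"),
    ("commercial_yield_Mg_ha", "ced_MJ_L"),
    ("commercial_yield_Mg_ha", "aware_m3_L"),
)


def scott_bin_width(sd: float, n: int) -> float:
    """Scott's normal reference rule: 3.49 * s * n^(-1/3)."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 3.49 * sd * n ** (-1.0 / 3.0)


@dataclass(frozen=True)
class RegressionResult:
    x: str
    y: str
    slope: float
    intercept: float
    r2: float


def fit_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Unweighted OLS fit of y on x: (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in x")
    fit = sps.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


@dataclass(frozen=True)
class CohortSummary:
    metrics: pd.DataFrame  # index metric; columns mean, sd, cv, min, max
    regressions: tuple[RegressionResult, ...]
    filter_tally: Mapping[str, int] = field(default_factory=dict)
    n: int = 0


def summarize_cohort(
    results: pd.DataFrame,
    filter_tally: Mapping[str, int] | None = None,
    regression_pairs: Sequence[tuple[str, str]] = DEFAULT_REGRESSIONS,
) -> CohortSummary:
    """Summary statistics and trend fits over the passed-genotype table.

    ``results`` has one row per passed genotype with the METRIC_COLUMNS.
    Regressions whose x has zero variance are reported with NaN slope and
    R^2 rather than raising (degenerate cohorts).  Order-invariant.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 passed genotypes to summarize")
    rows = {}
    for col in METRIC_COLUMNS:
        if col not in results.columns:
            continue
        v = results[col].to_numpy(dtype=float)
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        rows[col] = {
            "mean": mean,
            "sd": sd,
            "cv": sd / mean if mean != 0 else math.nan,
            "min": float(v.min()),
            "max": float(v.max()),
            "scott_bin_width": scott_bin_width(sd, len(v)),
        }
    regs = []
    for xcol, ycol in regression_pairs:
        if xcol not in results.columns or ycol not in results.columns:
            continue
        try:
            slope, intercept, r2 = fit_r2(results[xcol], results[ycol])
        except ValueError:
            slope = intercept = r2 = math.nan
        regs.append(RegressionResult(xcol, ycol, slope, intercept, r2))
    return CohortSummary(
        metrics=pd.DataFrame(rows).T,
        regressions=tuple(regs),
        filter_tally=dict(filter_tally or {}),
        n=len(results),
    )


def select_pca_variants(
    results: pd.DataFrame,
    k: int = 4,
    yield_col: str = "commercial_yield_Mg_ha",
    fcmf_col: str = "fcmf",
) -> list[str]:
    """Representative genotypes spanning the yield and FCMF ranges.

    Deterministic corner-and-extreme selection: the min/max-yield and
    min/max-FCMF genotypes first, then evenly spaced yield quantiles to
    fill up to ``k`` without duplicates.  Ties on an extreme are broken by
    lexicographic genotype_id.
    """
    if k < 4:
        raise ValueError("k must be >= 4 (the four extremes)")
    if k > len(results):
        raise ValueError(f"k={k} exceeds cohort size {len(results)}")
    df = results.sort_values("genotype_id").reset_index(drop=True)

    def extreme(col: str, best: str) -> str:
        v = df[col]
        target = v.min() if best == "min" else v.max()
        return str(df.loc[v == target, "genotype_id"].iloc[0])

    chosen: list[str] = []
    for col, best in (
        (yield_col, "min"),
        (yield_col, "max"),
        (fcmf_col, "min"),
        (fcmf_col, "max"),
    ):
        gid = extreme(col, best)
        if gid not in chosen:
            chosen.append(gid)
    if len(chosen) < k:
        ordered = df.sort_values([yield_col, "genotype_id"]).reset_index(drop=True)
        for q in np.linspace(0.0, 1.0, k * 3):
            idx = int(round(q * (len(ordered) - 1)))
            gid = str(ordered.loc[idx, "genotype_id"])
            if gid not in chosen:
                chosen.append(gid)
            if len(chosen) == k:
                break
    return chosen[:k]


def contribution_shares(result: ImpactResult) -> dict[str, dict[str, float]]:
    """Per-stage impact shares (summing to 1 per impact) for one genotype."""
    shares: dict[str, dict[str, float]] = {}
    for imp in IMPACTS:
        contrib = result.contributions[imp]
        total = sum(contrib.values())
        if total <= 0:
            raise ValueError(f"non-positive total for impact {imp!r}")
        shares[imp] = {stage: contrib[stage] / total for stage in STAGES}
    return shares


def contribution_report(
    impact_results: Mapping[str, ImpactResult],
    selected: Sequence[str],
) -> pd.DataFrame:
    """Long-format process-contribution table for the selected genotypes."""
    rows = []
    for gid in selected:
        try:
            res = impact_results[gid]
        except KeyError:
            raise KeyError(f"no impact result for genotype {gid!r}") from None
        shares = contribution_shares(res)
        for imp in IMPACTS:
            for stage in STAGES:
                rows.append(
                    {
                        "genotype_id": gid,
                        "impact": imp,
                        "stage": stage,
                        "share": shares[imp][stage],
                    }
                )
    return pd.DataFrame(rows)
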