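"""Breeding-plot to commercial-scale yield projection.

Gridded breeding plots measure per-plant biomass at planting densities far
below commercial sward seeding rates.  This module converts year-3
per-plant dry mass at each common-garden site into a per-area yield
(mass x planting density), combines sites by a weighted average (the site
closest to commercial density is weighted more heavily), and applies two
multiplicative corrections: a sward factor (default 1.4, spaced plants to
dense swards) and a commercial factor (default 0.5, plot scale to
commercial scale on marginal land).

Genotypes are then screened by three exclusion filters, applied in order:

1. mortality  - any dead replicate at any site excludes the genotype;
2. cv_exceeded - replicate coefficient of variation (population SD / mean
   of per-plant mass) above the cutoff (default 1.0, strict) at any site
   with at least two replicates;
3. below_cutoff - projected commercial yield below the cutoff
   (default 7.5 dry Mg/ha, strict: exactly 7.5 passes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_cohort import GenotypeRecord, SiteSpec

__all__ = [
    "ScalingFactors",
    "FailureReason",
    "CommercialYieldEstimate",
    "per_area_yield",
    "combine_and_scale",
    "apply_filters",
    "estimate_commercial_yield",
    "estimate_cohort",
]

#: kg/m^2 to dry Mg/ha.
KG_M2_TO_MG_HA = 10.0


@dataclass(frozen=True)
class ScalingFactors:
    """Correction factors and exclusion cutoffs for commercial projection."""

    sward_factor: float = 1.4
    commercial_factor: float = 0.5
    yield_cutoff: float = 7.5
    cv_cutoff: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sward_factor", "commercial_factor", "yield_cutoff", "cv_cutoff"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


class FailureReason(str, Enum):
    MORTALITY = "mortality"
    CV_EXCEEDED = "cv_exceeded"
    BELOW_CUTOFF = "below_cutoff"
    NONE = "none"


@dataclass(frozen=True)
class CommercialYieldEstimate:
    """Projected commercial yield for one genotype plus its filter verdict."""

    genotype_id: str
    commercial_yield: float  # dry Mg/ha/yr
    per_site_yields: Mapping[str, float] = field(default_factory=dict)
    passed: bool = False
    failure_reason: FailureReason = FailureReason.NONE

    def __post_init__(self) -> None:
        if self.commercial_yield < 0:
            raise ValueError("commercial_yield must be >= 0")
        if self.passed != (self.failure_reason is FailureReason.NONE):
            raise ValueError("passed must be equivalent to failure_reason == none")


def per_area_yield(mean_plant_mass: float, density: float) -> float:
    """Per-area yield in dry Mg/ha from mean plant mass (kg) and density (m^-2).

    1 kg/m^2 == 10 Mg/ha.
    """
    if mean_plant_mass < 0 or density < 0:
        raise ValueError("mass and density must be >= 0")
    return mean_plant_mass * density * KG_M2_TO_MG_HA


def combine_and_scale(
    per_site_yields: Mapping[str, float],
    site_weights: Mapping[str, float],
    factors: ScalingFactors = ScalingFactors(),
) -> float:
    """Weighted mean of per-site yields, scaled to commercial conditions.

    Weights are renormalized over the sites actually present, then the
    sward and commercial factors are applied in sequence.  Invariant to
    site ordering and linear in the yields.
    """
    if not per_site_yields:
        raise ValueError("at least one site yield required")
    wsum = 0.0
    acc = 0.0
    for site, y in per_site_yields.items():
        try:
            w = site_weights[site]
        except KeyError:
            raise KeyError(f"no weight for site {site!r}") from None
        if w <= 0:
            raise ValueError(f"weight for site {site!r} must be > 0")
        acc += w * y
        wsum += w
    weighted = acc / wsum
    return weighted * factors.sward_factor * factors.commercial_factor


def _site_replicate_cv(masses: Sequence[float]) -> float | None:
    """Replicate CV (population SD over mean) or None if undefined.

    Undefined when fewer than two replicates, or when the mean is zero
    while survivors exist (flagged by the caller as cv_exceeded).
    """
    if len(masses) < 2:
        return None
    arr = np.asarray(masses, dtype=float)
    mean = arr.mean()
    if mean == 0.0:
        return math.inf
    return float(arr.std(ddof=0) / mean)


def apply_filters(
    record: "GenotypeRecord",
    estimate: CommercialYieldEstimate,
    factors: ScalingFactors = ScalingFactors(),
) -> CommercialYieldEstimate:
    """Attach the exclusion-filter verdict to a computed yield estimate.

    Checks, in order: mortality in any replicate at any site; replicate CV
    above the cutoff at any site with >= 2 replicates (strict inequality);
    commercial yield strictly below the yield cutoff.  A site whose mean
    mass is zero despite survivors has an undefined CV and is treated as
    cv_exceeded.
    """
    reason = FailureReason.NONE
    if any(not obs.survived for obs in record.observations):
        reason = FailureReason.MORTALITY
    else:
        by_site: dict[str, list[float]] = {}
        for obs in record.observations:
            by_site.setdefault(obs.site, []).append(obs.year3_dry_mass)
        for masses in by_site.values():
            cv = _site_replicate_cv(masses)
            if cv is not None and cv > factors.cv_cutoff:
                reason = FailureReason.CV_EXCEEDED
                break
        else:
            if estimate.commercial_yield < factors.yield_cutoff:
                reason = FailureReason.BELOW_CUTOFF
    return CommercialYieldEstimate(
        genotype_id=estimate.genotype_id,
        commercial_yield=estimate.commercial_yield,
        per_site_yields=estimate.per_site_yields,
        passed=reason is FailureReason.NONE,
        failure_reason=reason,
    )


def estimate_commercial_yield(
    record: "GenotypeRecord",
    sites: Iterable["SiteSpec"],
    factors: ScalingFactors = ScalingFactors(),
) -> CommercialYieldEstimate:
    """Full per-genotype projection: per-site yields, weighting, filters.

    Site mean plant mass includes dead plants at zero mass; such genotypes
    are excluded by the mortality filter anyway, so the convention only
    affects the (reported, unused) yield of excluded genotypes.
    """
    site_specs = {s.name: s for s in sites}
    by_site: dict[str, list[float]] = {}
    for obs in record.observations:
        if obs.site not in site_specs:
            raise KeyError(f"observation at unknown site {obs.site!r}")
        by_site.setdefault(obs.site, []).append(obs.year3_dry_mass)
    per_site = {
        name: per_area_yield(float(np.mean(masses)), site_specs[name].planting_density)
        for name, masses in by_site.items()
    }
    weights = {name: site_specs[name].site_weight for name in per_site}
    commercial = combine_and_scale(per_site, weights, factors)
    raw = CommercialYieldEstimate(
        genotype_id=record.genotype_id,
        commercial_yield=commercial,
        per_site_yields=per_site,
        passed=True,
        failure_reason=FailureReason.NONE,
    )
    return apply_filters(record, raw, factors)


def estimate_cohort(
    records: Iterable["GenotypeRecord"],
    sites: Iterable["SiteSpec"],
    factors: ScalingFactors = ScalingFactors(),
) -> pd.DataFrame:
    """Tabulate estimates for a cohort.

    Returns a DataFrame with columns genotype_id, commercial_yield_Mg_ha,
    passed, failure_reason (the estimates CSV schema).
    """
    sites = list(sites)
    rows = []
    for rec in records:
        est = estimate_commercial_yield(rec, sites, factors)
        rows.append(
            {
                "genotype_id": est.genotype_id,
                "commercial_yield_Mg_ha": est.commercial_yield,
                "passed": est.passed,
                "failure_reason": est.failure_reason.value,
            }
        )
    return pd.DataFrame(rows)
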