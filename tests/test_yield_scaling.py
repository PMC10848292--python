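import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from varigrass.synthetic_cohort import (
    GenotypeRecord,
    PlantObservation,
    default_config,
    default_sites,
    generate_cohort,
)
from varigrass.composition import RawComposition
from varigrass.yield_scaling import (
    CommercialYieldEstimate,
    FailureReason,
    ScalingFactors,
    apply_filters,
    combine_and_scale,
    estimate_commercial_yield,
    per_area_yield,
)

COMP = RawComposition(0.4, 0.25, 0.01, 0.03, 0.19, 0.68, 0.03)


def record_from_masses(masses_by_site, gid="G1", dead=()):
    obs = []
    for site, masses in masses_by_site.items():
        for i, m in enumerate(masses, start=1):
            is_dead = (site, i) in dead
            obs.append(
                PlantObservation(gid, site, i, 0.0 if is_dead else m, not is_dead)
            )
    return GenotypeRecord(gid, tuple(obs), COMP)


class TestPerAreaYield:
    @pytest.mark.parametrize(
        "mass,density,expected",
        [(3.0, 1.20, 36.0), (0.0, 5.0, 0.0), (4.0, 0.17, 6.8)],
    )
    def test_unit_arithmetic(self, mass, density, expected):
        assert per_area_yield(mass, density) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            per_area_yield(-1.0, 1.0)


class TestCombineAndScale:
    def test_three_site_worked_example(self):
        yields = {"Tifton": 36.0, "Knoxville": 6.8, "Watkinsville": 11.0}
        weights = {"Tifton": 3.0, "Knoxville": 1.0, "Watkinsville": 1.0}
        # ((3*36 + 6.8 + 11)/5) * 1.4 * 0.5 = 17.612
        assert combine_and_scale(yields, weights) == pytest.approx(17.612)

    def test_single_site_applies_factors_only(self):
        assert combine_and_scale({"Tifton": 36.0}, {"Tifton": 3.0}) == pytest.approx(
            36.0 * 0.7
        )

    def test_unit_factors_give_weighted_mean(self):
        f = ScalingFactors(sward_factor=1.0, commercial_factor=1.0)
        out = combine_and_scale({"a": 10.0, "b": 20.0}, {"a": 1, "b": 3}, f)
        assert out == pytest.approx(17.5)

    def test_empty_sites_rejected(self):
        with pytest.raises(ValueError):
            combine_and_scale({}, {})

    def test_site_order_invariance(self):
        w = {"a": 1.0, "b": 2.0, "c": 3.0}
        y1 = {"a": 5.0, "b": 7.0, "c": 9.0}
        y2 = dict(reversed(list(y1.items())))
        assert combine_and_scale(y1, w) == combine_and_scale(y2, w)

    @given(scale=st.floats(0.1, 10.0))
    def test_linear_in_plant_mass(self, scale):
        sites = default_sites()
        rec = record_from_masses({"Tifton": [2, 3, 4], "Knoxville": [3, 4], "Watkinsville": [5]})
        scaled = record_from_masses(
            {"Tifton": [2 * scale, 3 * scale, 4 * scale],
             "Knoxville": [3 * scale, 4 * scale], "Watkinsville": [5 * scale]}
        )
        a = estimate_commercial_yield(rec, sites).commercial_yield
        b = estimate_commercial_yield(scaled, sites).commercial_yield
        assert b == pytest.approx(a * scale)


class TestFilters:
    def test_low_yield_reference_genotype_excluded_below_cutoff(self):
        # a uniform ~0.88 kg/plant genotype projects to ~4.9 Mg/ha
        rec = record_from_masses(
            {"Tifton": [0.88] * 3, "Knoxville": [0.88] * 2, "Watkinsville": [0.88]}
        )
        est = estimate_commercial_yield(rec, default_sites())
        assert est.commercial_yield == pytest.approx(4.9, abs=0.05)
        assert est.failure_reason is FailureReason.BELOW_CUTOFF
        assert not est.passed

    def test_mortality_trumps_everything(self):
        rec = record_from_masses(
            {"Tifton": [9, 9, 9], "Knoxville": [9, 9], "Watkinsville": [9]},
            dead={("Watkinsville", 1)},
        )
        est = estimate_commercial_yield(rec, default_sites())
        assert est.failure_reason is FailureReason.MORTALITY

    def test_replicate_cv_above_one_excluded(self):
        # Tifton CV (population SD / mean) of [0.01, 0.01, 5] is > 1
        rec = record_from_masses(
            {"Tifton": [0.01, 0.01, 5.0], "Knoxville": [3, 3], "Watkinsville": [3]}
        )
        est = estimate_commercial_yield(rec, default_sites())
        assert est.failure_reason is FailureReason.CV_EXCEEDED

    def test_cv_exactly_one_passes(self):
        # two replicates [0, 2m]: population CV == 1 exactly -> not excluded
        rec = record_from_masses(
            {"Tifton": [3.0, 3.0, 3.0], "Knoxville": [0.0, 6.0], "Watkinsville": [3.0]}
        )
        est = estimate_commercial_yield(rec, default_sites())
        assert est.failure_reason is not FailureReason.CV_EXCEEDED

    def test_yield_exactly_at_cutoff_passes(self):
        est = CommercialYieldEstimate("g", 7.5, {}, True, FailureReason.NONE)
        rec = record_from_masses({"Tifton": [1, 1, 1]})
        out = apply_filters(rec, est)
        assert out.passed

    def test_verdict_consistency_invariant(self):
        with pytest.raises(ValueError):
            CommercialYieldEstimate("g", 10.0, {}, True, FailureReason.MORTALITY)


def brute_force_verdict(rec, sites, factors=ScalingFactors()):
    """Independent naive reimplementation of the filter cascade."""
    if any(not o.survived for o in rec.observations):
        return "mortality"
    site_masses = {}
    for o in rec.observations:
        site_masses.setdefault(o.site, []).append(o.year3_dry_mass)
    for masses in site_masses.values():
        if len(masses) >= 2:
            mu = sum(masses) / len(masses)
            sd = (sum((m - mu) ** 2 for m in masses) / len(masses)) ** 0.5
            if mu == 0 or sd / mu > factors.cv_cutoff:
                return "cv_exceeded"
    dens = {s.name: s.planting_density for s in sites}
    wts = {s.name: s.site_weight for s in sites}
    num = den = 0.0
    for site, masses in site_masses.items():
        y = (sum(masses) / len(masses)) * dens[site] * 10.0
        num += wts[site] * y
        den += wts[site]
    commercial = num / den * factors.sward_factor * factors.commercial_factor
    return "below_cutoff" if commercial < factors.yield_cutoff else "none"


def test_filter_verdicts_match_brute_force_on_toy_cohort():
    cfg = default_config(n_genotypes=50, seed=13)
    records = generate_cohort(cfg)
    for rec in records:
        est = estimate_commercial_yield(rec, cfg.sites)
        assert est.failure_reason.value == brute_force_verdict(rec, cfg.sites)


def test_missing_site_weight_is_an_error():
    with pytest.raises(KeyError):
        combine_and_scale({"a": 1.0}, {"b": 2.0})
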