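import dataclasses

import numpy as np
import pytest

from varigrass.composition import close_mass_balance, fcmf, to_whole_biomass
from varigrass.synthetic_cohort import (
    BiomassParams,
    CohortConfig,
    ComponentParams,
    CompositionParams,
    ConfigError,
    SiteSpec,
    default_config,
    default_sites,
    generate_cohort,
    read_cohort,
    sample_composition,
    sample_plant_observations,
    write_cohort,
)
from varigrass.yield_scaling import estimate_commercial_yield


def test_fixed_seed_reproduces_cohort_exactly():
    a = generate_cohort(default_config(n_genotypes=40, seed=1))
    b = generate_cohort(default_config(n_genotypes=40, seed=1))
    assert a == b


def test_different_seeds_differ():
    a = generate_cohort(default_config(n_genotypes=10, seed=1))
    b = generate_cohort(default_config(n_genotypes=10, seed=2))
    assert a != b


def test_extending_cohort_preserves_earlier_genotypes():
    small = generate_cohort(default_config(n_genotypes=20, seed=5))
    large = generate_cohort(default_config(n_genotypes=40, seed=5))
    assert large[:20] == small


def test_total_mortality_kills_every_plant():
    cfg = default_config(n_genotypes=8, seed=3)
    cfg = dataclasses.replace(
        cfg, biomass=dataclasses.replace(cfg.biomass, mortality=1.0)
    )
    for rec in generate_cohort(cfg):
        assert all(not o.survived and o.year3_dry_mass == 0.0 for o in rec.observations)


def test_zero_mortality_all_survive():
    cfg = default_config(n_genotypes=8, seed=3)
    cfg = dataclasses.replace(
        cfg, biomass=dataclasses.replace(cfg.biomass, mortality=0.0)
    )
    for rec in generate_cohort(cfg):
        assert all(o.survived for o in rec.observations)


def test_zero_replicate_cv_gives_identical_masses_within_genotype():
    rng = np.random.default_rng(0)
    params = BiomassParams(replicate_cv=0.0, mortality=0.0)
    obs = sample_plant_observations(params, default_sites(), rng)
    masses = {o.year3_dry_mass for o in obs}
    assert len(masses) == 1


def test_replicate_counts_honoured():
    rng = np.random.default_rng(0)
    obs = sample_plant_observations(BiomassParams(), default_sites(), rng)
    counts = {}
    for o in obs:
        counts[o.site] = counts.get(o.site, 0) + 1
    assert counts == {"Tifton": 3, "Knoxville": 2, "Watkinsville": 1}


def test_zero_variance_composition_returns_locations():
    comps = {
        k: ComponentParams(loc=v.loc, scale=0.0, lower=v.lower, upper=v.upper)
        for k, v in CompositionParams().components.items()
    }
    raw = sample_composition(
        CompositionParams(components=comps), np.random.default_rng(0)
    )
    assert raw.lignin == 0.19
    assert raw.sg_ratio == 0.68


def test_infeasible_truncation_rejected():
    with pytest.raises(ConfigError, match="bounds"):
        ComponentParams(loc=0.2, scale=0.01, lower=0.3, upper=0.1)


def test_negative_scale_rejected():
    with pytest.raises(ConfigError):
        ComponentParams(loc=0.2, scale=-1.0, lower=0.1, upper=0.3)
    with pytest.raises(ConfigError):
        BiomassParams(log_sigma=float("nan"))


def test_infeasible_fcmf_window_raises():
    params = CompositionParams(fcmf_range=(0.9, 0.95), max_rejections=50)
    with pytest.raises(ConfigError, match="FCMF"):
        sample_composition(params, np.random.default_rng(0))


@pytest.fixture(scope="module")
def big_cohort():
    return generate_cohort(default_config(n_genotypes=10_000, seed=11))


class TestMarginalDistributions:
    """Sampled marginals must respect bounds and configured moments."""

    def test_lignin_always_in_printed_range(self, big_cohort):
        lig = np.array([r.raw_composition.lignin for r in big_cohort])
        assert lig.min() >= 0.15 and lig.max() <= 0.21

    def test_sg_ratio_always_in_printed_range(self, big_cohort):
        sg = np.array([r.raw_composition.sg_ratio for r in big_cohort])
        assert sg.min() >= 0.47 and sg.max() <= 0.91

    def test_ash_range(self, big_cohort):
        ash = np.array([r.raw_composition.ash for r in big_cohort])
        assert ash.min() >= 0.01 and ash.max() <= 0.05

    def test_lignin_moments_match_configuration(self, big_cohort):
        lig = np.array([r.raw_composition.lignin for r in big_cohort])
        assert abs(lig.mean() - 0.19) < 0.002
        assert abs(lig.std() - 0.01) < 0.002

    def test_closed_fcmf_always_inside_window(self, big_cohort):
        vals = [
            fcmf(close_mass_balance(to_whole_biomass(r.raw_composition)))
            for r in big_cohort[:2000]
        ]
        assert min(vals) >= 0.62 and max(vals) <= 0.67

    def test_composition_independent_of_commercial_yield(self, big_cohort):
        cfg = default_config()
        pairs = []
        for rec in big_cohort[:10_000]:
            est = estimate_commercial_yield(rec, cfg.sites)
            f = fcmf(close_mass_balance(to_whole_biomass(rec.raw_composition)))
            pairs.append((f, est.commercial_yield))
        arr = np.array(pairs)
        r = np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]
        assert abs(r) < 0.03

    def test_commercial_yield_span_matches_study(self, big_cohort):
        cfg = default_config()
        passed = []
        for rec in big_cohort:
            est = estimate_commercial_yield(rec, cfg.sites)
            if est.passed:
                passed.append(est.commercial_yield)
        passed = np.array(passed)
        # filtered cohort spans roughly the reported 7.5-39 Mg/ha window
        assert passed.min() >= 7.5
        assert 33.0 <= np.quantile(passed, 1 - 1 / 84) <= 45.0
        assert 0.36 <= passed.std() / passed.mean() <= 0.45


def test_csv_round_trip(tmp_path, small_cohort):
    _, records = small_cohort
    obs_p, comp_p = tmp_path / "obs.csv", tmp_path / "comp.csv"
    write_cohort(records, obs_p, comp_p)
    back = read_cohort(obs_p, comp_p)
    assert [r.genotype_id for r in back] == [r.genotype_id for r in records]
    for a, b in zip(back, records):
        assert a.raw_composition.glucose == pytest.approx(b.raw_composition.glucose)
        assert len(a.observations) == len(b.observations)


def test_yaml_config_round_trip(tmp_path):
    cfg = default_config(n_genotypes=17, seed=9)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = CohortConfig.from_yaml(path)
    assert back == cfg


def test_site_spec_validation():
    with pytest.raises(ConfigError):
        SiteSpec("x", planting_density=0.0, n_replicates=1, site_weight=1.0)
    with pytest.raises(ConfigError):
        SiteSpec("x", planting_density=1.0, n_replicates=0, site_weight=1.0)
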