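import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from varigrass.composition import (
    ClosedComposition,
    RawComposition,
    close_mass_balance,
    to_whole_biomass,
)
from varigrass.synthetic_cohort import default_config, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The study-condition cohort at the package default seed."""
    cfg = default_config()
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-genotype cohort for cheaper stage tests."""
    cfg = default_config(n_genotypes=60, seed=7)
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def example_raw():
    """Whole-biomass-basis composition used in worked examples."""
    return RawComposition(
        glucose=0.380,
        xylose=0.235,
        galactose=0.010,
        arabinose=0.030,
        lignin=0.1805,
        sg_ratio=0.68,
        ash=0.030,
    )


@pytest.fixture()
def example_closed(example_raw) -> ClosedComposition:
    return close_mass_balance(example_raw)
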