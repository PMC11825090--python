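"""Shared fixtures: small seeded synthetic cohorts and reference coefficients."""

import numpy as np
import pandas as pd
import pytest

from vetweight import DEFAULT_SPECIES, apply_exclusions, generate_population
from vetweight.growth_model import GrowthCoefficients


@pytest.fixture(scope="session")
def dog_cohort():
    """2,000 dogs over a two-year window, cleaned, with ground truth."""
    records, truth = generate_population(
        {"dog": DEFAULT_SPECIES["dog"]},
        2000,
        ("2022-01-01", "2023-12-31"),
        seed=42,
    )
    cleaned, log = apply_exclusions(records)
    return {"records": records, "cleaned": cleaned, "log": log, "truth": truth}


@pytest.fixture(scope="session")
def dog_pairs(dog_cohort):
    from vetweight import build_growth_pairs

    return build_growth_pairs(dog_cohort["cleaned"], max_age_months=60)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def reference_dog_coeffs():
    """Published fixed-effect coefficients of a dog juvenile-gain model.

    Rounded values as printed for a UK primary-care population; the cubic
    interval term was dropped there by backward selection.
    """
    return GrowthCoefficients(
        intercept=0.385,
        age=-0.053,
        age2=0.002,
        age3=-0.00002,
        interval=0.065,
        interval2=-0.001,
        interval3=0.0,
        age_x_interval=-0.002,
        included_terms={
            "age": True,
            "age2": True,
            "age3": True,
            "interval": True,
            "interval2": True,
            "interval3": False,
            "age_x_interval": True,
        },
        var_animal=0.0,
        var_resid=1.0,
        max_valid_age_months=14.0,
    )


def make_pairs(coeffs, n, seed, resid_sd=0.02, age_range=(0.5, 13.5),
               interval_range=(0.25, 3.0), n_per_animal=2):
    """Simulate growth pairs exactly from a coefficient vector."""
    from vetweight.growth_model import predict_gain

    r = np.random.default_rng(seed)
    n_animals = n // n_per_animal
    animal = np.repeat([f"a{i}" for i in range(n_animals)], n_per_animal)
    m = len(animal)
    age = r.uniform(*age_range, m)
    interval = r.uniform(*interval_range, m)
    gain = predict_gain(coeffs, age, interval, validate_age=False)
    gain = gain + r.normal(0.0, resid_sd, m)
    return pd.DataFrame(
        {
            "animal_id": animal,
            "age_months": age,
            "interval_months": interval,
            "prop_gain": gain,
            "weight_kg": 10.0,
        }
    )
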