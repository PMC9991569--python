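import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from nrfindex.intake_mar import aggregate_recalls, exclude_implausible_energy
from nrfindex.reference_values import ReferenceValueEntry, ReferenceValueTable, load_default_table
from nrfindex.synthetic_cohort import GeneratorConfig, generate_cohort, generate_food_table


@pytest.fixture(scope="session")
def dri():
    return load_default_table()


@pytest.fixture()
def tiny_table():
    """Hand-built reference table for lookup semantics tests."""
    return ReferenceValueTable(
        entries=[
            ReferenceValueEntry("calcium", "any", 18, 100, 800.0, "RNI", "mg"),
            ReferenceValueEntry("iron", "male", 18, 49, 12.0, "RNI", "mg"),
            ReferenceValueEntry("iron", "male", 50, 100, 10.0, "RNI", "mg"),
            ReferenceValueEntry("sat_fat", "any", 18, 100, 0.10, "AMDR_fraction_of_energy", "g"),
            ReferenceValueEntry("sodium", "any", 18, 100, 2000.0, "MRV", "mg"),
        ]
    )


@pytest.fixture(scope="session")
def small_bundle(dri):
    """A small but complete synthetic cohort shared across pipeline tests."""
    cfg = GeneratorConfig(seed=7, n_participants=200, n_foods=24)
    foods = generate_food_table(cfg, dri)
    return generate_cohort(cfg, foods, dri)


@pytest.fixture(scope="session")
def small_cohort(small_bundle, dri):
    """Aggregated, plausibility-screened intakes plus matching participants."""
    intakes = aggregate_recalls(small_bundle.recalls, small_bundle.food_table)
    retained, excluded = exclude_implausible_energy(intakes, small_bundle.participants)
    part = small_bundle.participants[
        small_bundle.participants["participant_id"].isin(retained.index)
    ].reset_index(drop=True)
    return retained, part, excluded
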