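"""Shared fixtures: packaged reference tables and a small synthetic cohort."""

from __future__ import annotations

import pytest

from vetamu import io as vio
from vetamu import synthetic
from vetamu.consultations import build_consultations
from vetamu.model import CohortFilter
from vetamu.consultations import apply_cohort_filter


@pytest.fixture(scope="session")
def drug_dict():
    return vio.load_drug_dictionary()


@pytest.fixture(scope="session")
def breed_table():
    return vio.load_breed_table()


@pytest.fixture(scope="session")
def lexicon():
    return vio.load_lexicon()


@pytest.fixture(scope="session")
def small_dataset():
    """A compact generated cohort (~4-5k consultations) with ground truth."""
    config = synthetic.demo_scenario(
        n_practices=4, patients_per_practice=(120, 200), seed=11
    )
    table, truth = synthetic.generate_invoices(config)
    return config, table, truth


@pytest.fixture(scope="session")
def small_cohort(small_dataset, drug_dict, breed_table, lexicon):
    """Consultations built from the small generated cohort, cohort-filtered."""
    _, table, truth = small_dataset
    data = build_consultations(table, drug_dict, breed_table, lexicon)
    data, _ = apply_cohort_filter(data, CohortFilter(min_patients_per_practice=1))
    return data, truth
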