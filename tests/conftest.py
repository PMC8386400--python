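"""Shared fixtures: small synthetic cohorts and their matched datasets."""

from __future__ import annotations

import datetime as dt

import pytest

from asertval.io import matched_frame
from asertval.matching import attach_lags, match_concurrent
from asertval.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """30-patient cohort under default study conditions (seeded)."""
    config = GeneratorConfig(n_patients=30, seed=1234)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def matched_small(small_cohort):
    patients, asserts, clinical, truth = small_cohort
    records, report = match_concurrent(asserts, clinical)
    records = attach_lags(records, asserts, report)
    return records, report, truth


@pytest.fixture(scope="session")
def matched_df_small(matched_small):
    records, _, _ = matched_small
    return matched_frame(records)


@pytest.fixture(scope="session")
def large_cohort():
    """200-patient cohort for the Monte-Carlo structure checks."""
    config = GeneratorConfig(n_patients=200, seed=2024)
    return generate_cohort(config)


def d(iso: str) -> dt.date:
    return dt.date.fromisoformat(iso)
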