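"""Shared fixtures: a small seeded synthetic cohort and its derived objects."""

from __future__ import annotations

from dataclasses import replace

import pytest

from coherent.cohort import build_strata
from coherent.engine import build_journeys
from coherent.simulate import default_params, generate_cohort


def scaled_params(n_hosp: int = 60, n_home: int = 25, n_died: int = 2):
    """Paper-calibrated rates at reduced cohort sizes (fast tests)."""
    p = default_params()
    p.hospitalized = {g: replace(gp, n=n_hosp) for g, gp in p.hospitalized.items()}
    p.ed_home = {g: replace(gp, n=n_home) for g, gp in p.ed_home.items()}
    p.n_died_in_ed = {g: n_died for g in p.n_died_in_ed}
    return p


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(scaled_params(), seed=123)


@pytest.fixture(scope="session")
def small_strata(small_cohort):
    return build_strata(small_cohort.episodes, small_cohort.vitals, 2018)


@pytest.fixture(scope="session")
def hosp_journeys(small_cohort, small_strata):
    sub = small_strata.select(arm="HOSPITALIZED")
    return build_journeys(sub, small_cohort.episodes, small_cohort.vitals, horizon=365)
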