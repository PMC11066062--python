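"""Shared fixtures: a tiny synthetic cohort and its normalized matrix."""

import pytest

from imnatac.normalization import (
    estimate_dispersions,
    size_factors_median_of_ratios,
    vst,
)
from imnatac.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_cohort(CohortConfig.tiny(), seed=1234)


@pytest.fixture(scope="session")
def tiny_normalized(tiny_cohort):
    sf = size_factors_median_of_ratios(tiny_cohort.counts)
    dm = estimate_dispersions(tiny_cohort.counts, sf)
    tm = vst(tiny_cohort.counts, sf, dm)
    return tiny_cohort, tm
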