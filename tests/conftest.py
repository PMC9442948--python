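import math

import pytest

from sirdesign import (
    EpidemicParams,
    PrecisionInputs,
    canonical_design,
    summarize_design,
)


@pytest.fixture(scope="session")
def pure_summary():
    """Idealised four-group pure design at h = 0.47, phi = 1."""
    design = canonical_design("pure", g_size=100, exact=True)
    return summarize_design(design, 1.0)


@pytest.fixture(scope="session")
def single_summary():
    """Idealised single-group design: 15% all-BB seeders, chi_cont = 0.8."""
    design = canonical_design("single", g_size=100, exact=True)
    return summarize_design(design, 1.0)


@pytest.fixture(scope="session")
def mixed_summary_limit():
    """Two-group mixed design in the zero-seeder limit, chi = +-1/sqrt(2)."""
    design = canonical_design("mixed", g_size=100, exact=True, n_seed=0.0)
    return summarize_design(design, 1.0, allow_empty_seeders=True)


@pytest.fixture(scope="session")
def unit_inputs():
    return PrecisionInputs(phi=1.0, k=1.0, a_g=1.0, a_f=1.0, a_r=1.0)


@pytest.fixture
def baseline_params():
    """Neutral epidemic: R0 = 5 in a group of 100, no SNP effects."""
    return EpidemicParams.from_r0(5.0, 100)
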