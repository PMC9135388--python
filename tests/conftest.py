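import pytest

from hcineq import (GeneratorConfig, apply_exclusions, default_catalog,
                    generate_cohort, score_frame)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_bundle():
    """A mid-size synthetic cohort with planted QC challenges."""
    cfg = GeneratorConfig(n_case=250, n_control=260, n_duplicates=6,
                          n_incomplete=8, n_unconfirmed=4, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def analysis_cohort(small_bundle):
    kept, ledger = apply_exclusions(small_bundle.frame)
    return kept, ledger


@pytest.fixture(scope="session")
def cohort(analysis_cohort):
    return analysis_cohort[0]


@pytest.fixture(scope="session")
def scores(cohort, catalog):
    return score_frame(cohort, catalog)
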