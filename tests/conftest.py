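import warnings

import pytest

from cafebudget.synthetic_data import (
    SyntheticConfig,
    calibrate,
    generate,
    table1_fixture,
    table1_targets,
)


@pytest.fixture(scope="session")
def fixture_table():
    """The deterministic watershed summary fixture (1985 and 2019 cells)."""
    return table1_fixture()


@pytest.fixture(scope="session")
def small_table():
    """A small synthetic cohort shared by read-only tests."""
    return generate(SyntheticConfig(n_counties=8, years=(2000, 2004), seed=11))


@pytest.fixture(scope="session")
def calibrated_cohort():
    """Default 197-county cohort calibrated to the watershed cells.

    Session-scoped: generation plus calibration is the expensive step shared
    by the qualitative-property tests.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = generate(SyntheticConfig(seed=1))
        return calibrate(table, table1_targets(with_recyclable=True))
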