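import numpy as np
import pandas as pd
import pytest

import extraopt as eo


@pytest.fixture(scope="session")
def factors():
    return eo.fixture_factors()


@pytest.fixture(scope="session")
def table1():
    """The packaged 29-run extraction experiment."""
    return eo.fixture_design()


@pytest.fixture(scope="session")
def table1_fit(table1):
    return eo.fit_quadratic(table1)


@pytest.fixture(scope="session")
def frozen_ann():
    return eo.fixture_ann()


@pytest.fixture(scope="session")
def table1_extra_columns():
    """The published per-run model predictions shipped alongside the fixture."""
    from importlib import resources
    with resources.as_file(
        resources.files("extraopt").joinpath("data", "table1.csv")
    ) as p:
        return pd.read_csv(p)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
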