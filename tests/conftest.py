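import numpy as np
import pytest

from n2osource.records import IncubationRecord, IsotopomerRecord, RateRecord
from n2osource.unmixing import EndmemberTable

ANALYTICAL_SIGMAS = {"d15n_bulk": 0.2, "d18o": 0.5, "sp": 1.0}


@pytest.fixture(scope="session")
def default_table() -> EndmemberTable:
    return EndmemberTable.default()


@pytest.fixture(scope="session")
def collapsed_table(default_table) -> EndmemberTable:
    return default_table.collapse()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_isotopomer(**kw) -> IsotopomerRecord:
    base = dict(
        station_id="S1",
        depth=50.0,
        layer="subsurface",
        c_n2o=8.0,
        d15n_bulk=5.0,
        d18o=40.0,
        d15n_alpha=15.0,
        d15n_beta=-5.0,
        sp=20.0,
    )
    base.update(kw)
    return IsotopomerRecord(**base)


def make_incubation(**kw) -> IncubationRecord:
    base = dict(
        station_id="S1",
        depth=50.0,
        substrate="ammonium",
        treatment="control",
        replicate=1,
        f_substrate=0.9,
        delta_t=24.0,
        c0_nox15=0.0,
        ct_nox15=1.8,
        dc45=10.0,
        dc46=2.0,
    )
    base.update(kw)
    return IncubationRecord(**base)


def make_rate(**kw) -> RateRecord:
    base = dict(
        station_id="S1",
        depth=50.0,
        substrate="ammonium",
        treatment="control",
        replicate=1,
        r_nitr=2.0,
        r_n2o=24.0,
        yield_n2o=0.0119,
    )
    base.update(kw)
    return RateRecord(**base)
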