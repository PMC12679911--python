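import numpy as np
import pandas as pd
import pytest

from herdvigor.herdbook import HerdBook
from herdvigor.simulate import SimParams, simulate_herd


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def sim():
    """A small but complete multi-year herd with ground truth."""
    params = SimParams(
        n_years=4,
        groups=((5, 100), (4, 80), (3, 50), (2, 40)),
        seed=42,
    )
    return simulate_herd(params)


@pytest.fixture(scope="session")
def sim_default():
    """Full-scale herd under the default (study-like) conditions."""
    return simulate_herd(SimParams(seed=7))


def tiny_herd_frames():
    """A hand-written 6-animal herd: sire, two dams, three calves."""
    animals = pd.DataFrame([
        # id, sex, birth, dam, true_sire, assigned, group, year, bw, ww, ret, disp
        ["S1", "M", "2012-04-01", None, None, None, None, None, 40.0, None, False, None],
        ["D1", "F", "2011-04-05", None, None, None, None, None, 35.0, None, False, None],
        ["D2", "F", "2012-04-07", None, None, None, None, None, 36.0, None, False, None],
        ["C1", "F", "2015-04-10", "D1", "S1", "S1", 1, 2014, 38.0, 210.0, True, None],
        ["C2", "M", "2015-04-20", "D2", "S1", "S1", 1, 2014, 39.0, 220.0, False, 2016],
        ["C3", "F", "2015-05-15", "D1", "S1", None, 1, 2014, 37.0, None, False, None],
    ], columns=["animal_id", "sex", "birth_date", "dam_id", "true_sire_id",
                "assigned_sire_id", "group", "year", "birth_weight",
                "weaning_weight", "retained", "disposal_year"])
    roster = pd.DataFrame([["S1", 1, 2014]], columns=["sire_id", "group", "year"])
    return animals, roster


@pytest.fixture()
def tiny_herd():
    animals, roster = tiny_herd_frames()
    return HerdBook(animals, roster)
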