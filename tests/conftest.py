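import numpy as np
import pytest

from cbescreen import DEFAULT_SPACE, DFSCurve, LifeTable, default_parameters
from cbescreen.params import MBCMortality


@pytest.fixture(scope="session")
def params():
    """Packaged default parameter set (session-wide, treated as read-only)."""
    return default_parameters()


@pytest.fixture()
def space():
    return DEFAULT_SPACE


def zero_mortality_life_table():
    return LifeTable(np.arange(0, 101), np.zeros(101))


def constant_life_table(q_annual):
    return LifeTable(np.arange(0, 101), np.full(101, q_annual))


def quiet_params(
    base,
    *,
    q_annual=0.0,
    recurrence=False,
    mbc_death=None,
    remission_to_mbc=None,
):
    """Variant of the defaults with hazards switched off or pinned.

    ``recurrence=False`` flattens the DFS curve (no events ever);
    ``mbc_death`` pins all five metastatic-year probabilities to one value.
    """
    p = base.copy()
    p.life_table = constant_life_table(q_annual) if q_annual else zero_mortality_life_table()
    if not recurrence:
        # cure everyone instantly: recurrence probability is exactly 0 at all t
        p.dfs = DFSCurve(
            family="weibull", shape=1.0, scale=1e9,
            cure_threshold=0.0, max_cure_rate=1.0, mbc_split=p.dfs.mbc_split,
        )
    if mbc_death is not None:
        p.mbc_mortality = MBCMortality(*(mbc_death,) * 5)
    if remission_to_mbc is not None:
        p.remission_to_mbc = remission_to_mbc
    else:
        p.remission_to_mbc = p.remission_to_mbc if recurrence else 0.0
    return p.validate()
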