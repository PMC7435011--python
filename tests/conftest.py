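import numpy as np
import pytest

from girkcascade import (
    CellContext,
    GatingParams,
    InitialConditionSpec,
    RateConstants,
    UnitConversion,
    attach_channel,
    build_wt_network,
    invert_basal_currents,
)

CHANNEL_DENSITY = 21.7  # channels/um^2, high-density expression group


@pytest.fixture(scope="session")
def rates():
    return RateConstants()


@pytest.fixture(scope="session")
def conv():
    return UnitConversion.from_channel_density(CHANNEL_DENSITY)


@pytest.fixture(scope="session")
def gating():
    return GatingParams.graded()


@pytest.fixture(scope="session")
def ctx():
    return CellContext(channel_density=CHANNEL_DENSITY)


@pytest.fixture(scope="session")
def wt_network(rates, conv):
    return build_wt_network(rates, conv)


@pytest.fixture(scope="session")
def full_network(wt_network, gating, conv):
    return attach_channel(wt_network, gating, conv)


@pytest.fixture(scope="session")
def hd_totals(gating, conv, rates):
    """Per-channel (Gbg, Galpha) totals of the high-density reference cell."""
    inv = invert_basal_currents(
        InitialConditionSpec(CHANNEL_DENSITY, 13.36, 17.2), gating, conv, rates
    )
    return inv.gbg_total, inv.ga_total


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
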