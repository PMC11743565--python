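import numpy as np
import pytest

from mfcbalance import ReactorConfig, VoltageTrace, default_species_table


@pytest.fixture(scope="session")
def species_table():
    return default_species_table()


@pytest.fixture
def acetate_config():
    return ReactorConfig(substrate="acetate", feed_cod_mg_per_l=150.0)


@pytest.fixture
def starch_config():
    return ReactorConfig(substrate="starch", feed_cod_mg_per_l=250.0)


@pytest.fixture
def constant_trace():
    """1.0 mA held for 10 h across 200 ohm, minute sampling."""
    times = np.arange(0, 601) / 60.0
    return VoltageTrace(times, np.full(601, 0.2), external_resistance_ohm=200.0)
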