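import numpy as np
import pytest

from entch4 import synthdata as sd
from entch4.formulas import load_equations
from entch4.sniffer import Background, GasTrace


@pytest.fixture(scope="session")
def equations():
    return load_equations()


@pytest.fixture
def rng():
    return np.random.default_rng(20210930)


@pytest.fixture
def flat_background():
    return Background(ch4=20.0, co2=600.0)


def make_trace(ch4, co2, source="AMS", flow=None):
    ch4 = np.asarray(ch4, dtype=float)
    return GasTrace(
        source=source,
        t=np.arange(len(ch4), dtype=float),
        ch4=ch4,
        co2=np.asarray(co2, dtype=float),
        flow=flow,
    )


@pytest.fixture
def quiet_trace_cfg():
    """Noise-free AMS trace config with no head-away gaps."""
    return sd.TraceConfig(noise_sd_co2=0.0, noise_sd_ch4=0.0, head_away_fraction=0.0)
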