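import numpy as np
import pytest

from nucfret.fret import CorrectionSet, FretPair
from nucfret.simulate import ExchangingPair, FretSpecies, SimConfig, simulate_bursts


@pytest.fixture(scope="session")
def pair():
    """Alexa488-Alexa594 pair with the donor-only lifetime used throughout."""
    return FretPair(R0=55.6, tau_D0=4.0)


@pytest.fixture(scope="session")
def exchange_pair():
    """MF* <-> HF exchange at the 150 mM / 20 pM rates and distances."""
    return ExchangingPair(
        FretSpecies("MFstar", 61.1, 2.0),
        FretSpecies("HF", 46.1, 2.0),
        k_ab=33.4e3,
        k_ba=13.2e3,
    )


@pytest.fixture(scope="session")
def corrections():
    return CorrectionSet(bg_green=0.35, bg_red=0.35)


@pytest.fixture(scope="session")
def static_stream():
    """A single mid-FRET species, no donor-only: shared across tests."""
    cfg = SimConfig(seed=123, donor_only_fraction=0.0)
    species = FretSpecies("MF", 61.1, 2.0, 1.0)
    return simulate_bursts([species], cfg, 600), cfg, species


@pytest.fixture(scope="session")
def mixture_stream(exchange_pair):
    """Four-component mixture at study-like fractions (ground truth known)."""
    cfg = SimConfig(seed=321, donor_only_fraction=0.10)
    mf = FretSpecies("MF", 61.1, 2.0, 0.40)
    lf = FretSpecies("LF", 85.8, 2.0, 0.15)
    stream = simulate_bursts([mf, lf], cfg, 1500, dynamic=exchange_pair,
                             dyn_fraction=0.35)
    return stream, cfg, (mf, lf)
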