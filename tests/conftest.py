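import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from xlscout.proteome import ProteinRecord
from xlscout.simulate import gen_proteome


@pytest.fixture(scope="session")
def toy_protein():
    return ProteinRecord("P1", "P1 toy", "MKPRLYKAR")


@pytest.fixture(scope="session")
def small_proteome():
    return gen_proteome(10, seed=11)


@pytest.fixture(scope="session")
def decoy_proteome():
    return gen_proteome(50, seed=12, prefix="DEC")


LHCI_PSI_SUBUNITS = [f"LHCA{i}" for i in range(1, 10)] + ["PSAD", "PSAF"]


@pytest.fixture(scope="session")
def gel_universe():
    """Subunit names with distinct carbon counts, as in a real complex."""
    carbons = {s: 900 + 13 * i for i, s in enumerate(LHCI_PSI_SUBUNITS)}
    return LHCI_PSI_SUBUNITS, carbons
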