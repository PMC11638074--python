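import pytest

from ubchain.chain_model import UbUnit, parse_architecture
from ubchain.mass_engine import moiety_mz, released_moiety_table
from ubchain.synthetic_data import default_branched_substrate

#: Chain notations as they appear in print (unicode superscripts included),
#: covering mono, homotypic, mixed and branched architectures with and
#: without unit modifications.
NOTATION_CORPUS = [
    "Ub",
    "^48^Ub_2",
    "^63^Ub_2",
    "^48^Ub_3",
    "^63^Ub_3",
    "^48^Ub_4",
    "^63^Ub_4",
    "(Ub)_2–^48,63^Ub",
    "(Ub)_2–^48,63^Ub–^48^Ub",
    "(Ub)_2–^48,63^Ub–^63^Ub",
    "(Ub^K48R, K63R^)_2–^48,63^Ub^1–72^",
    "(Ub)_2–^1,63^Ub",
    "[Ub]_2–^29,48^Ub",
    "(Ub)_2–^29,48^Ub",
    "Ub–^48^Ub–^63^Ub–^48^Ub",
    "^63^(^48^Ub_2)_2",
    "(Ub)(Ub–^48^Ub)–^48,63^Ub",
    "(Ub^K48R, K63R^)_2–^48,63^Ub–^48^Ub^1–72^",
]


@pytest.fixture(scope="session")
def branched_substrate():
    """Default mass-distinguishable branched Ub4 substrate."""
    return default_branched_substrate()


@pytest.fixture(scope="session")
def moiety_table(branched_substrate):
    return released_moiety_table(branched_substrate)


@pytest.fixture(scope="session")
def standard_mz():
    """Theoretical [M+H]+ of the uniformly 15N-labeled Ub standard."""
    return moiety_mz(UbUnit("std", isotope="15N"))
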