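import pytest

from venombank.codon_design import CodonTable
from venombank.peptide_io import generate_synthetic_library

#: Synthetic stand-in for the proprietary DsbC-His6 carrier: a DsbC-like
#: length and composition with an internal hexa-histidine stretch.  Used
#: only to exercise the sequence-carrier code path.
SYNTHETIC_CARRIER = (
    "MKKIWLALAGLVLAFSASAAQYEDGKQYTTLEKPVAGAPQVLEFFSFFCPHCYQFEEVL"
    "HISDNVKKKLPEGVKMTKYHVNFMGGDLGKDLTQAWAVAMALGVEDKVTVPLFEGVQKT"
    "QTIRSASDIRDVFINAGIKGEEYDAAWNSFVVKSLVAQQEKAAADVQLRGVPAMFVNGK"
    "YQLNPQGMDTSNMDVFVQQYADTVKYLSEKKHHHHHH"
)


@pytest.fixture(scope="session")
def codon_table():
    return CodonTable.default()


@pytest.fixture(scope="session")
def small_library():
    return generate_synthetic_library(24, seed=11)
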