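import pytest

from kturn.annotate import RNAStrand, hybridize_strands, scan_kturns

# The two FRET strands of the duplex construct (5'->3'): fluorescein on
# the bulged strand, Cy3 on the partner.
FLU_STRAND = "CCAGUCAGGGCCGAUGAAUGAGUUCAGG"
CY3_STRAND = "CCUGAACUCAUGAAGCCCUGACUGG"


@pytest.fixture(scope="session")
def fret_strands():
    return (RNAStrand("flu", FLU_STRAND, label="fluorescein"),
            RNAStrand("cy3", CY3_STRAND, label="Cy3"))


@pytest.fixture(scope="session")
def fret_duplex(fret_strands):
    return hybridize_strands(*fret_strands, max_bulge=3)


@pytest.fixture(scope="session")
def fret_kturn(fret_duplex):
    sites = scan_kturns(fret_duplex)
    assert len(sites) == 1
    return sites[0]
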