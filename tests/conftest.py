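import pytest

from ltpdigest.core import load_prup3_fixtures
from ltpdigest.mapping import IdentifiedPeptide, PeptideLocation


@pytest.fixture(scope="session")
def prup3():
    """(isoform, epitopes, topology) of the vendored mature Pru p 3 chain."""
    return load_prup3_fixtures()


@pytest.fixture(scope="session")
def isoform(prup3):
    return prup3[0]


@pytest.fixture(scope="session")
def epitopes(prup3):
    return {e.label: e for e in prup3[1]}


@pytest.fixture(scope="session")
def topology(prup3):
    return prup3[2]


# Intervals of the peptides that dominate the digests (N-terminal, central
# and C-terminal preferred proteolysis products, plus the non-reduced pair).
DOMINANT_INTERVALS = [
    (1, 26), (1, 29), (51, 61), (50, 79), (56, 64),
    (66, 91), (86, 91), (53, 72), (55, 72),
]


@pytest.fixture(scope="session")
def dominant_locations(isoform):
    locs = []
    for start, end in DOMINANT_INTERVALS:
        seq = isoform.slice(start, end)
        locs.append(
            PeptideLocation(
                accession=isoform.accession, start=start, end=end,
                peptide=IdentifiedPeptide(sequence=seq),
            )
        )
    return locs
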