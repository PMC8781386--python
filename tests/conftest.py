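import numpy as np
import pytest

from tandemshm import synth
from tandemshm.io_model import GermlineAllele, RepertoireRecord

#: standard genetic code, independent of the package's translation path
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE = {
    b1 + b2 + b3: _AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}


@pytest.fixture(scope="session")
def genetic_code():
    return GENETIC_CODE


@pytest.fixture(scope="session")
def toy_alleles():
    return synth.generate_toy_alleles(4, 300, seed=11)


@pytest.fixture(scope="session")
def allele_map(toy_alleles):
    return {a.name: a for a in toy_alleles}


def make_allele(sequence, name="A*01", frame_offset=0, regions=()):
    return GermlineAllele(
        name=name, sequence=sequence, frame_offset=frame_offset, regions=list(regions)
    )


def make_record(v_alignment, v_call="A*01", sequence_id="r1", **kwargs):
    return RepertoireRecord(
        sequence_id=sequence_id, v_call=v_call, v_alignment=v_alignment, **kwargs
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
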