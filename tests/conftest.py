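import pytest

from rfc1 import (
    AssayConfig,
    DiploidGenotype,
    core_motifs,
    default_locus,
    default_registry,
    parse_structure,
)


@pytest.fixture(scope="session")
def locus():
    return default_locus()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def motifs():
    return core_motifs()


@pytest.fixture(scope="session")
def assay_cfg():
    return AssayConfig()


def genotype(a1: str, a2: str, sample_id: str = "S") -> DiploidGenotype:
    return DiploidGenotype(
        parse_structure(a1), parse_structure(a2), sample_id=sample_id
    )


@pytest.fixture(scope="session")
def make_genotype():
    return genotype
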