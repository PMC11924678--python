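import pytest

from sarcophen.locus import annotate_pseudoexon, build_fixture_locus


@pytest.fixture(scope="session")
def alleles():
    return build_fixture_locus(1)


@pytest.fixture(scope="session")
def dexon55(alleles):
    return alleles["dExon55"]


@pytest.fixture(scope="session")
def pseudoexon_annotation(dexon55):
    return annotate_pseudoexon(dexon55.locus, dexon55.junctions)


@pytest.fixture(scope="session")
def flanking_exons(dexon55):
    return dexon55.locus.exon("exon54"), dexon55.locus.exon("exon56")
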