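import pytest

from rflpsim import load_assays, load_enzymes, load_primer_panel

PRIMERS = {
    "677F": "CTCGCCTTGAACAGGTGGAG",
    "677R": "CTGGATGGGAAAGATCCCGG",
    "894F": "GTCCCTGAGGAGGGCATGAG",
    "894R": "TCCAGCAGCATGTTGGACAC",
    "786F": "GCAGGTCAGCAGAGAGACTA",
    "786R": "GACACAGAACTACAAACCCC",
}


@pytest.fixture(scope="session")
def assays():
    return load_assays()


@pytest.fixture(scope="session")
def panel():
    return load_primer_panel()


@pytest.fixture(scope="session")
def enzymes():
    return load_enzymes()
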