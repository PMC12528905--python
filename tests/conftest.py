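import itertools

import pytest
from Bio.Seq import Seq

from scfvlib.cassette_design import default_library_design


@pytest.fixture(scope="session")
def design():
    return default_library_design()


def brute_force_expand(codes: str):
    """Independent enumeration of a degenerate codon's concrete codons."""
    iupac = {
        "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
        "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT",
        "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    return ["".join(t) for t in itertools.product(*(iupac[c] for c in codes))]


def brute_force_translate(codon: str, amber_to_gln: bool = False) -> str:
    """Translate one concrete codon via biopython's Seq machinery."""
    if amber_to_gln and codon == "TAG":
        return "Q"
    return str(Seq(codon).translate())


def brute_force_peptides(codon_specs, amber_to_gln: bool = False):
    """All distinct stop-free peptides of a cassette, by full enumeration."""
    peptides = set()
    for combo in itertools.product(*(brute_force_expand(c) for c in codon_specs)):
        pep = "".join(brute_force_translate(c, amber_to_gln) for c in combo)
        if "*" not in pep:
            peptides.add(pep)
    return peptides
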