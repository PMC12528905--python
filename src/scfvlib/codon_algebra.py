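"""Exact algebra of IUPAC degenerate codons.

Degenerate codons written in the 15-letter IUPAC nucleotide ambiguity
alphabet (e.g. NNK, DRC, RRY) describe equimolar mixtures of concrete
codons produced during oligo synthesis.  This module expands such codons,
translates them under the standard genetic code (optionally with amber
suppression, TAG read as Gln by suppressor hosts such as *E. coli* TG1),
and does exact combinatorial accounting of the DNA- and protein-level
diversity of cassettes built from them.

All diversity products use arbitrary-precision integers: a stretch of
NNK codons quickly exceeds the 64-bit range (32**13 > 2**63).

Assumption: bases within one ambiguity letter are mixed equimolar
(standard mixed-base synthesis); non-uniform mixes and trimer
phosphoramidite chemistry are out of scope.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import prod
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

from Bio.Data import CodonTable

__all__ = [
    "IUPAC_BASES",
    "STOP",
    "AMINO_ACIDS",
    "InvalidAlphabetError",
    "DegenerateCodon",
    "AADistribution",
    "expand_code",
    "expand_codon",
    "aa_distribution",
    "stop_probability",
    "cassette_dna_diversity",
    "cassette_protein_diversity",
    "genetic_code",
]

#: Standard IUPAC nucleotide ambiguity alphabet.
IUPAC_BASES: Mapping[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

STOP = "*"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Supported translation modes.  ``amber_suppressed`` reads TAG as Gln,
#: as in amber-suppressor display hosts; TAA/TGA remain stops.
GENETIC_CODE_MODES = ("standard", "amber_suppressed")


class InvalidAlphabetError(ValueError):
    """A symbol outside the IUPAC nucleotide ambiguity alphabet."""


def _build_code_tables() -> Dict[str, Dict[str, str]]:
    table1 = CodonTable.unambiguous_dna_by_id[1]
    standard = dict(table1.forward_table)
    for codon in table1.stop_codons:
        standard[codon] = STOP
    amber = dict(standard)
    amber["TAG"] = "Q"
    return {"standard": standard, "amber_suppressed": amber}


_CODE_TABLES = _build_code_tables()


def genetic_code(mode: str = "standard") -> Mapping[str, str]:
    """Codon -> residue map for *mode* (stops map to ``"*"``)."""
    try:
        return _CODE_TABLES[mode]
    except KeyError:
        raise ValueError(
            f"unknown genetic-code mode {mode!r}; expected one of {GENETIC_CODE_MODES}"
        ) from None


def expand_code(symbol: str) -> frozenset:
    """Expand one IUPAC ambiguity letter to its base set.

    >>> sorted(expand_code("N"))
    ['A', 'C', 'G', 'T']
    >>> expand_code("A") == frozenset("A")
    True
    """
    try:
        return IUPAC_BASES[symbol.upper()]
    except (KeyError, AttributeError):
        raise InvalidAlphabetError(
            f"invalid IUPAC nucleotide code: {symbol!r}"
        ) from None


@dataclass(frozen=True)
class DegenerateCodon:
    """One codon written in IUPAC ambiguity letters, e.g. ``NNK``.

    The codon denotes the equimolar mixture of every concrete codon in the
    Cartesian product of the three base sets.
    """

    codes: str

    def __post_init__(self) -> None:
        codes = self.codes.upper()
        if len(codes) != 3:
            raise ValueError(f"a codon has exactly 3 letters, got {self.codes!r}")
        for ch in codes:
            expand_code(ch)  # raises InvalidAlphabetError on bad symbols
        object.__setattr__(self, "codes", codes)

    @property
    def base_sets(self) -> Tuple[frozenset, frozenset, frozenset]:
        a, b, c = self.codes
        return (expand_code(a), expand_code(b), expand_code(c))

    @property
    def expansion_count(self) -> int:
        return prod(len(s) for s in self.base_sets)

    @property
    def is_fixed(self) -> bool:
        return self.expansion_count == 1

    def expand(self) -> List[str]:
        """All concrete codons, lexicographically sorted, duplicate-free."""
        sets = [sorted(s) for s in self.base_sets]
        return ["".join(t) for t in itertools.product(*sets)]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.codes


CodonLike = Union[str, DegenerateCodon]


def as_codon(codon: CodonLike) -> DegenerateCodon:
    return codon if isinstance(codon, DegenerateCodon) else DegenerateCodon(codon)


def expand_codon(codon: CodonLike) -> List[str]:
    """Enumerate the concrete codons of a degenerate codon (sorted)."""
    return as_codon(codon).expand()


@dataclass(frozen=True)
class AADistribution:
    """Residue probabilities induced by a degenerate codon.

    ``probs`` maps one-letter residues (plus ``"*"`` for stop) to their
    probability under equimolar expansion; entries with zero mass are
    omitted, and the retained masses sum to 1.
    """

    probs: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total!r}, not 1")
        if any(p < 0 for p in self.probs.values()):
            raise ValueError("negative probability")

    @property
    def stop_probability(self) -> float:
        return self.probs.get(STOP, 0.0)

    @property
    def support(self) -> frozenset:
        return frozenset(self.probs)

    @property
    def residue_support(self) -> frozenset:
        """Support excluding the stop symbol."""
        return frozenset(k for k in self.probs if k != STOP)

    def __getitem__(self, residue: str) -> float:
        return self.probs.get(residue, 0.0)

    def to_tsv(self, path) -> None:
        """Write a two-column (residue, probability) TSV."""
        with open(path, "w") as fh:
            fh.write("residue\tprobability\n")
            for res in sorted(self.probs):
                fh.write(f"{res}\t{self.probs[res]:.12g}\n")


def aa_distribution(codon: CodonLike, mode: str = "standard") -> AADistribution:
    """Translate a degenerate codon into its residue distribution.

    Each concrete codon in the expansion carries weight 1/expansion_count.
    Under the standard code NNK covers all 20 residues with a single stop
    (TAG) at mass 1/32; under amber suppression that mass moves to Gln.
    """
    dc = as_codon(codon)
    code = genetic_code(mode)
    weight = 1.0 / dc.expansion_count
    probs: Dict[str, float] = {}
    for concrete in dc.expand():
        res = code[concrete]
        probs[res] = probs.get(res, 0.0) + weight
    return AADistribution(probs)


def stop_probability(codon: CodonLike, mode: str = "standard") -> float:
    """Probability that a random realization of *codon* is a stop."""
    return aa_distribution(codon, mode).stop_probability


def cassette_dna_diversity(codons: Sequence[CodonLike]) -> int:
    """Exact number of distinct DNA realizations of an ordered cassette."""
    return prod(as_codon(c).expansion_count for c in codons)


def cassette_protein_diversity(
    codons: Sequence[CodonLike], mode: str = "standard"
) -> int:
    """Exact number of distinct stop-free peptides a cassette encodes.

    Positions are independent, so the count is the product over positions
    of the number of distinct non-stop residues reachable there.
    """
    return prod(
        len(aa_distribution(c, mode).residue_support) for c in codons
    )
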