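"""CDR3 mutagenesis-cassette construction and template-depletion checks.

Builds the VL and VH CDR3 cassettes of a semisynthetic scFv library on a
VH3/Vkappa1 framework:

* VL CDR3 spans Kabat 91-96.  Position 91 is usually Tyr in natural
  kappa light chains (~50%), so two cassette variants are built: variant A
  fixes Tyr91, variant B randomizes it.  Positions 92/93 get the
  restricted DRC/RRY codons, 94/96 get NNK, and the highly conserved
  Pro95 stays fixed.
* VH CDR3 loops of varying length sit between the structurally conserved
  Arg94 and Asp101 anchors (salt bridge).  Two sublibraries cover the
  length space: S (short, 5-22 randomized residues) and L (long, 9-28).

Template depletion relies on two unique restriction sites engineered into
the unmutated template: SacI (GAGCTC) inside VL CDR3 and NheI (GCTAGC)
inside VH CDR3.  Any plasmid retaining a site is cut; mutant cassettes
must therefore (almost) never regenerate the site, which
:func:`cassette_site_regeneration_risk` quantifies exactly.

The shipped template is synthetic: the construct used in the wet lab is
not public, so a fixed surrogate with the same architecture (framework
arms, parent CDR3s carrying the SacI/NheI sites) is generated here and
used throughout tests and simulations.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .codon_algebra import (
    STOP,
    CodonLike,
    DegenerateCodon,
    aa_distribution,
    as_codon,
    cassette_dna_diversity,
    cassette_protein_diversity,
    expand_code,
    genetic_code,
)

__all__ = [
    "RESTRICTION_SITES",
    "PositionSpec",
    "CDR3Cassette",
    "SublibraryDesign",
    "LibraryDesign",
    "DesignConfig",
    "InvalidArmError",
    "UnsupportedLengthError",
    "AnnotationRequiredError",
    "kabat_vh_labels",
    "build_vl_cassettes",
    "build_vh_cassettes",
    "build_library_design",
    "default_library_design",
    "check_template_sites",
    "cassette_site_regeneration_risk",
    "theoretical_library_stats",
    "theoretical_position_frequencies",
    "export_cassette_fasta",
]

#: Recognition sequences of the template-depletion enzymes (both are
#: palindromic, so one strand suffices for scanning).
RESTRICTION_SITES: Mapping[str, str] = {"SacI": "GAGCTC", "NheI": "GCTAGC"}

_DNA = set("ACGT")


class InvalidArmError(ValueError):
    """A framework arm contains non-ACGT characters."""


class UnsupportedLengthError(ValueError):
    """A VH loop length outside the supported Kabat labelling range."""


class AnnotationRequiredError(ValueError):
    """A template operation was requested without CDR3 interval annotations."""


@dataclass(frozen=True)
class PositionSpec:
    """One Kabat-labelled cassette position and its codon design."""

    kabat_label: str
    codon: DegenerateCodon
    fixed_aa: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "codon", as_codon(self.codon))
        if self.fixed_aa is not None:
            code = genetic_code("standard")
            translated = {code[c] for c in self.codon.expand()}
            if translated != {self.fixed_aa}:
                raise ValueError(
                    f"position {self.kabat_label}: codon {self.codon} translates to "
                    f"{sorted(translated)}, not fixed residue {self.fixed_aa!r}"
                )


def _check_arm(arm: str, what: str) -> str:
    arm = arm.upper()
    if set(arm) - _DNA:
        raise InvalidArmError(
            f"{what} must be unambiguous A/C/G/T, got {arm!r}"
        )
    return arm


@dataclass(frozen=True)
class CDR3Cassette:
    """An ordered run of designed codon positions with framework arms.

    ``region`` is ``"VH"`` or ``"VL"`` for library cassettes (anchor
    invariants are enforced), or ``None`` for ad-hoc cassettes used in
    probability calculations.
    """

    name: str
    positions: Tuple[PositionSpec, ...]
    upstream_arm: str = ""
    downstream_arm: str = ""
    region: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("cassette needs at least one position")
        object.__setattr__(self, "positions", tuple(self.positions))
        object.__setattr__(self, "upstream_arm", _check_arm(self.upstream_arm, "upstream arm"))
        object.__setattr__(self, "downstream_arm", _check_arm(self.downstream_arm, "downstream arm"))
        labels = self.kabat_labels
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate Kabat labels in cassette {self.name}")
        if self.region == "VH":
            first, last = self.positions[0], self.positions[-1]
            if first.fixed_aa != "R" or last.fixed_aa != "D":
                raise ValueError(
                    "VH cassettes are anchored by fixed Arg (Kabat 94) and Asp (Kabat 101)"
                )
        elif self.region == "VL":
            if labels[0] != "91" or labels[-1] != "96":
                raise ValueError("VL cassettes span Kabat 91-96")
            by_label = {p.kabat_label: p for p in self.positions}
            if by_label.get("95") is None or by_label["95"].fixed_aa != "P":
                raise ValueError("VL position 95 must be fixed Pro")

    @property
    def kabat_labels(self) -> List[str]:
        return [p.kabat_label for p in self.positions]

    @property
    def codons(self) -> List[DegenerateCodon]:
        return [p.codon for p in self.positions]

    @property
    def degenerate_core(self) -> str:
        """The cassette core as a plain IUPAC string."""
        return "".join(p.codon.codes for p in self.positions)

    @property
    def oligo(self) -> str:
        """Full degenerate oligo: upstream arm + core + downstream arm."""
        return self.upstream_arm + self.degenerate_core + self.downstream_arm

    @property
    def randomized_length(self) -> int:
        """Number of non-fixed (randomized) residues."""
        return sum(1 for p in self.positions if p.fixed_aa is None)

    def dna_diversity(self) -> int:
        return cassette_dna_diversity(self.codons)

    def protein_diversity(self, mode: str = "standard") -> int:
        return cassette_protein_diversity(self.codons, mode)

    def stop_free_fraction(self, mode: str = "standard") -> float:
        """Fraction of DNA realizations translating without a stop."""
        frac = 1.0
        for codon in self.codons:
            frac *= 1.0 - aa_distribution(codon, mode).stop_probability
        return frac


@dataclass(frozen=True)
class SublibraryDesign:
    """One VH length series: S (short) or L (long)."""

    name: str
    loop_lengths: Tuple[int, int]  # inclusive range of randomized residues
    cassettes: Tuple[CDR3Cassette, ...]

    def __post_init__(self) -> None:
        lo, hi = self.loop_lengths
        if len(self.cassettes) != hi - lo + 1:
            raise ValueError("one VH cassette per loop length is required")


#: Sublibrary length ranges (randomized VH CDR3 residues, anchors excluded).
SUBLIBRARY_RANGES: Mapping[str, Tuple[int, int]] = {"S": (5, 22), "L": (9, 28)}


@dataclass(frozen=True)
class DesignConfig:
    """Tunable knobs of the cassette design.

    Fixed-position codons default to common human codons; the VL variant-B
    codon at position 91 defaults to NNK.  ``anchor_flank`` is how many
    framework nucleotides flank each cassette core as complementary arms.
    """

    fixed_codons: Mapping[str, str] = field(
        default_factory=lambda: {"Y": "TAT", "P": "CCT", "R": "CGT", "D": "GAT"}
    )
    vl_variant_b_91: str = "NNK"
    anchor_flank: int = 12


def kabat_vh_labels(k: int) -> List[str]:
    """Kabat labels for ``k`` randomized VH CDR3 residues.

    Positions run 95..100, then take insertion letters 100a..100z, which
    supports loops up to 32 residues.
    """
    if not 1 <= k <= 32:
        raise UnsupportedLengthError(
            f"VH loop length {k} outside the supported Kabat labelling range 1-32"
        )
    labels = [str(n) for n in range(95, 95 + min(k, 6))]
    for i in range(k - 6):
        labels.append("100" + string.ascii_lowercase[i])
    return labels


def _fixed_position(label: str, aa: str, config: DesignConfig) -> PositionSpec:
    return PositionSpec(label, DegenerateCodon(config.fixed_codons[aa]), fixed_aa=aa)


def build_vl_cassettes(
    config: DesignConfig = DesignConfig(),
    upstream_arm: str = "",
    downstream_arm: str = "",
) -> Tuple[CDR3Cassette, CDR3Cassette]:
    """Build the two VL CDR3 cassette variants (Kabat 91-96).

    Variant A fixes Tyr at 91 (the dominant natural residue); variant B
    randomizes 91.  Mixed equimolar, the pair yields roughly 50% Tyr91
    plus the small Tyr mass of the variant-B codon.
    """
    def shared(first91: PositionSpec, name: str) -> CDR3Cassette:
        positions = (
            first91,
            PositionSpec("92", DegenerateCodon("DRC")),
            PositionSpec("93", DegenerateCodon("RRY")),
            PositionSpec("94", DegenerateCodon("NNK")),
            _fixed_position("95", "P", config),
            PositionSpec("96", DegenerateCodon("NNK")),
        )
        return CDR3Cassette(
            name=name,
            positions=positions,
            upstream_arm=upstream_arm,
            downstream_arm=downstream_arm,
            region="VL",
        )

    variant_a = shared(_fixed_position("91", "Y", config), "VL-A")
    variant_b = shared(
        PositionSpec("91", DegenerateCodon(config.vl_variant_b_91)), "VL-B"
    )
    return variant_a, variant_b


def build_vh_cassettes(
    sublibrary_name: str,
    loop_lengths: Optional[Tuple[int, int]] = None,
    config: DesignConfig = DesignConfig(),
    upstream_arm: str = "",
    downstream_arm: str = "",
) -> List[CDR3Cassette]:
    """Build one VH cassette per loop length of a sublibrary.

    Each cassette is ``Arg94 + k×NNK + Asp101`` with Kabat insertion
    labelling of the k randomized positions.
    """
    if loop_lengths is None:
        loop_lengths = SUBLIBRARY_RANGES[sublibrary_name]
    lo, hi = loop_lengths
    if lo < 1:
        raise UnsupportedLengthError(f"loop lengths start at 1, got {lo}")
    cassettes = []
    for k in range(lo, hi + 1):
        positions = (
            _fixed_position("94", "R", config),
            *(
                PositionSpec(label, DegenerateCodon("NNK"))
                for label in kabat_vh_labels(k)
            ),
            _fixed_position("101", "D", config),
        )
        cassettes.append(
            CDR3Cassette(
                name=f"VH-{sublibrary_name}-k{k}",
                positions=positions,
                upstream_arm=upstream_arm,
                downstream_arm=downstream_arm,
                region="VH",
            )
        )
    return cassettes


# ---------------------------------------------------------------------------
# Synthetic template
# ---------------------------------------------------------------------------

# Fixed synthetic scFv framework fragments (plausible VH3/Vkappa1-like
# codons; invented surrogates, not the wet-lab construct).  The parent
# CDR3s carry the depletion sites: SacI inside VL CDR3 and NheI inside
# VH CDR3, each unique template-wide.
_PAD5 = "ATGGCAGAAGTTCAGCTG"
_VL_FR_UP = "ACCATCAGCAGCCTGCAACCGGAAGATTTCGCAACCTACTACTGT"
_VL_PARENT_CDR3 = "TATAGCGAGCTCCCGACG"  # Y S E L P T, SacI at codons 93/94
_VL_FR_DOWN = "TTTGGCCAAGGCACCAAAGTTGAAATCAAA"
_LINKER = "GGTGGAGGCGGTTCAGGCGGAGGTGGCTCTGGCGGTGGCGGATCG"
_VH_FR_UP = "AGCCTGCGTGCCGAAGACACCGCCGTTTATTACTGCGCG"
_VH_PARENT_CDR3 = "CGTGCTAGCTGGGGTGAT"  # R A S W G D, NheI at codons 95/96
_VH_FR_DOWN = "TGGGGTCAAGGCACCCTGGTTACCGTTAGCAGC"
_PAD3 = "GCATCCACTAAAGGCCCA"


@dataclass(frozen=True)
class LibraryDesign:
    """The full library: VL variants, S+L sublibraries, and the template.

    ``vl_interval`` / ``vh_interval`` are 0-based half-open coordinates of
    the CDR3 regions on ``template`` (VL: Kabat 91-96; VH: Kabat 94-101
    including the Arg/Asp anchors).
    """

    vl_cassettes: Tuple[CDR3Cassette, CDR3Cassette]
    sublibraries: Tuple[SublibraryDesign, ...]
    template: str
    vl_interval: Tuple[int, int]
    vh_interval: Tuple[int, int]
    config: DesignConfig = DesignConfig()

    def sublibrary(self, name: str) -> SublibraryDesign:
        for sub in self.sublibraries:
            if sub.name == name:
                return sub
        raise KeyError(name)

    def template_region(self, region: str) -> str:
        s, e = self.vl_interval if region == "VL" else self.vh_interval
        return self.template[s:e]

    def flanks(self, region: str, length: Optional[int] = None) -> Tuple[str, str]:
        """Framework sequences flanking a CDR3 interval."""
        if length is None:
            length = self.config.anchor_flank
        s, e = self.vl_interval if region == "VL" else self.vh_interval
        return self.template[s - length : s], self.template[e : e + length]


def build_library_design(config: DesignConfig = DesignConfig()) -> LibraryDesign:
    """Assemble the default S+L library design on the synthetic template."""
    template = (
        _PAD5
        + _VL_FR_UP
        + _VL_PARENT_CDR3
        + _VL_FR_DOWN
        + _LINKER
        + _VH_FR_UP
        + _VH_PARENT_CDR3
        + _VH_FR_DOWN
        + _PAD3
    )
    vl_start = len(_PAD5) + len(_VL_FR_UP)
    vl_interval = (vl_start, vl_start + len(_VL_PARENT_CDR3))
    vh_start = (
        vl_interval[1] + len(_VL_FR_DOWN) + len(_LINKER) + len(_VH_FR_UP)
    )
    vh_interval = (vh_start, vh_start + len(_VH_PARENT_CDR3))

    flank = config.anchor_flank
    vl_up = template[vl_interval[0] - flank : vl_interval[0]]
    vl_down = template[vl_interval[1] : vl_interval[1] + flank]
    vh_up = template[vh_interval[0] - flank : vh_interval[0]]
    vh_down = template[vh_interval[1] : vh_interval[1] + flank]

    vl_cassettes = build_vl_cassettes(config, vl_up, vl_down)
    sublibraries = tuple(
        SublibraryDesign(
            name=name,
            loop_lengths=SUBLIBRARY_RANGES[name],
            cassettes=tuple(
                build_vh_cassettes(name, config=config, upstream_arm=vh_up, downstream_arm=vh_down)
            ),
        )
        for name in ("S", "L")
    )
    return LibraryDesign(
        vl_cassettes=vl_cassettes,
        sublibraries=sublibraries,
        template=template,
        vl_interval=vl_interval,
        vh_interval=vh_interval,
        config=config,
    )


def default_library_design() -> LibraryDesign:
    """The package's default design (cached construction is cheap enough)."""
    return build_library_design()


# ---------------------------------------------------------------------------
# Restriction-site checks
# ---------------------------------------------------------------------------

def _occurrences(seq: str, site: str) -> List[int]:
    hits, start = [], seq.find(site)
    while start != -1:
        hits.append(start)
        start = seq.find(site, start + 1)
    return hits


@dataclass(frozen=True)
class SiteCheck:
    enzyme: str
    site: str
    region: str
    in_region: bool
    unique: bool
    positions: Tuple[int, ...]

    @property
    def passed(self) -> bool:
        return self.in_region and self.unique


def check_template_sites(
    template: str,
    vl_interval: Optional[Tuple[int, int]] = None,
    vh_interval: Optional[Tuple[int, int]] = None,
) -> Dict[str, SiteCheck]:
    """Verify depletion-site placement on the template.

    SacI must occur inside the VL CDR3 interval and NheI inside the VH
    CDR3 interval, each exactly once template-wide.  Both sites are
    palindromic, so forward-strand scanning covers both strands.
    Accepts a :class:`LibraryDesign` in place of the three arguments.
    """
    if isinstance(template, LibraryDesign):
        design = template
        template, vl_interval, vh_interval = (
            design.template,
            design.vl_interval,
            design.vh_interval,
        )
    if vl_interval is None or vh_interval is None:
        raise AnnotationRequiredError(
            "template CDR3 interval annotations are required"
        )
    assignments = {"SacI": ("VL", vl_interval), "NheI": ("VH", vh_interval)}
    report = {}
    for enzyme, (region, (start, end)) in assignments.items():
        site = RESTRICTION_SITES[enzyme]
        hits = _occurrences(template.upper(), site)
        in_region = any(start <= h and h + len(site) <= end for h in hits)
        report[enzyme] = SiteCheck(
            enzyme=enzyme,
            site=site,
            region=region,
            in_region=in_region,
            unique=len(hits) == 1,
            positions=tuple(hits),
        )
    return report


# ---------------------------------------------------------------------------
# Site-regeneration probability
# ---------------------------------------------------------------------------

def _kmp_failure(pattern: str) -> List[int]:
    fail = [0] * len(pattern)
    k = 0
    for i in range(1, len(pattern)):
        while k and pattern[i] != pattern[k]:
            k = fail[k - 1]
        if pattern[i] == pattern[k]:
            k += 1
        fail[i] = k
    return fail


def _automaton(pattern: str) -> List[Dict[str, int]]:
    """KMP matching automaton: state = matched prefix length."""
    fail = _kmp_failure(pattern)
    m = len(pattern)
    delta: List[Dict[str, int]] = []
    for state in range(m):
        row = {}
        for base in "ACGT":
            k = state
            while k and pattern[k] != base:
                k = fail[k - 1]
            row[base] = k + 1 if pattern[k] == base else 0
        delta.append(row)
    return delta


def _position_distributions(
    cassette: CDR3Cassette, include_arm_context: bool, site_len: int
) -> List[Dict[str, float]]:
    dists: List[Dict[str, float]] = []
    if include_arm_context:
        for base in cassette.upstream_arm[-(site_len - 1):]:
            dists.append({base: 1.0})
    for codon in cassette.codons:
        for letter in codon.codes:
            bases = sorted(expand_code(letter))
            p = 1.0 / len(bases)
            dists.append({b: p for b in bases})
    if include_arm_context:
        for base in cassette.downstream_arm[: site_len - 1]:
            dists.append({base: 1.0})
    return dists


def cassette_site_regeneration_risk(
    cassette: CDR3Cassette,
    site: str,
    include_arm_context: bool = True,
) -> float:
    """Exact probability that a cassette realization contains *site*.

    Positions are independent (equimolar mixing within each ambiguity
    letter); windows overlapping the fixed arms by up to ``len(site)-1``
    nucleotides are included.  Because occurrence windows overlap, the
    probability is computed exactly by propagating a distribution over
    KMP-automaton states (match-prefix lengths) across positions, rather
    than by summing per-window probabilities.
    """
    site = site.upper()
    delta = _automaton(site)
    dists = _position_distributions(cassette, include_arm_context, len(site))
    state_probs = [1.0] + [0.0] * len(site)  # last slot = absorbed (matched)
    for dist in dists:
        nxt = [0.0] * (len(site) + 1)
        nxt[len(site)] = state_probs[len(site)]
        for state in range(len(site)):
            p_state = state_probs[state]
            if p_state == 0.0:
                continue
            for base, p_base in dist.items():
                nxt[delta[state][base]] += p_state * p_base
        state_probs = nxt
    return state_probs[len(site)]


# ---------------------------------------------------------------------------
# Theoretical diversity accounting
# ---------------------------------------------------------------------------

def _sci(n: int) -> str:
    return f"{float(n):.3g}" if n else "0"


def theoretical_library_stats(
    design: LibraryDesign, mode: str = "standard"
) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Per-cassette and total diversity accounting.

    Returns a table with one row per cassette (VL variants and every VH
    length of both sublibraries): exact DNA diversity, stop-free protein
    diversity, and stop-containing fraction; plus a totals dict with
    exact integers and scientific-notation renderings.  Totals sum DNA
    diversities over cassettes within each pool (equimolar pooling).
    """
    rows = []
    for cassette in design.vl_cassettes:
        rows.append(
            {
                "pool": "VL",
                "cassette": cassette.name,
                "loop_length": cassette.randomized_length,
                "dna_diversity": cassette.dna_diversity(),
                "protein_diversity": cassette.protein_diversity(mode),
                "stop_fraction": 1.0 - cassette.stop_free_fraction(mode),
            }
        )
    for sub in design.sublibraries:
        for cassette in sub.cassettes:
            rows.append(
                {
                    "pool": sub.name,
                    "cassette": cassette.name,
                    "loop_length": cassette.randomized_length,
                    "dna_diversity": cassette.dna_diversity(),
                    "protein_diversity": cassette.protein_diversity(mode),
                    "stop_fraction": 1.0 - cassette.stop_free_fraction(mode),
                }
            )
    table = pd.DataFrame(rows)
    totals: Dict[str, object] = {"mode": mode}
    for pool in ("VL", "S", "L"):
        sel = table[table["pool"] == pool]
        dna = int(sum(sel["dna_diversity"]))
        protein = int(sum(sel["protein_diversity"]))
        totals[pool] = {
            "n_cassettes": len(sel),
            "dna_diversity": dna,
            "dna_diversity_sci": _sci(dna),
            "protein_diversity": protein,
            "protein_diversity_sci": _sci(protein),
        }
    return table, totals


def theoretical_position_frequencies(
    cassette: CDR3Cassette, mode: str = "standard", drop_stop: bool = True
) -> pd.DataFrame:
    """Expected residue frequencies per Kabat position of a cassette.

    With ``drop_stop`` the stop mass is removed and each row renormalized
    (displayable clones only); rows sum to 1.
    """
    rows = {}
    for pos in cassette.positions:
        probs = dict(aa_distribution(pos.codon, mode).probs)
        if drop_stop:
            probs.pop(STOP, None)
            total = sum(probs.values())
            probs = {k: v / total for k, v in probs.items()}
        rows[pos.kabat_label] = probs
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    return table.reindex(sorted(table.columns), axis=1)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_cassette_fasta(design: LibraryDesign, fasta_path, manifest_path=None) -> None:
    """Write degenerate oligos as IUPAC FASTA plus an optional TSV manifest."""
    cassettes = list(design.vl_cassettes)
    for sub in design.sublibraries:
        cassettes.extend(sub.cassettes)
    with open(fasta_path, "w") as fh:
        for cassette in cassettes:
            fh.write(f">{cassette.name} region={cassette.region}\n{cassette.oligo}\n")
    if manifest_path is not None:
        rows = [
            {
                "name": c.name,
                "region": c.region,
                "loop_length": c.randomized_length,
                "kabat_labels": ",".join(c.kabat_labels),
                "core": c.degenerate_core,
                "dna_diversity": c.dna_diversity(),
            }
            for c in cassettes
        ]
        pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
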