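"""Seeded synthetic repertoires, ELISA plates, and panning titers.

Everything downstream of library construction (sequencing QC, screening
triage) is testable offline against data whose ground truth is known.
The repertoire generator realizes clones from the designed cassettes —
choosing a sublibrary, a VH loop length and a VL variant, drawing each
degenerate position uniformly from its expansion, and splicing the
realizations into the template framework — then optionally replaces a
clone with unmutated template (residual-template fraction) and applies
per-base substitution/indel errors.  ELISA and panning generators plant
binders and round-over-round enrichment with configurable noise.

Defaults mirror the characterized library: sublibrary mix S:L weighted
by the reported colony counts (6.93e9 : 1.57e10), lengths uniform within
each sublibrary range, zero template fraction and error rates unless a
scenario dictates otherwise.  A single PRNG stream drives each run, so
identical config + seed reproduces outputs byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cassette_design import CDR3Cassette, LibraryDesign, default_library_design
from .codon_algebra import genetic_code
from .screening_triage import ElisaPlate, PanningRound

__all__ = [
    "GeneratorConfig",
    "sample_clone",
    "generate_repertoire",
    "write_repertoire_fasta",
    "generate_elisa_fixture",
    "generate_panning_fixture",
]

#: Default sublibrary weights from the reported colony counts
#: (S 6.93e9, L 1.57e10).
DEFAULT_MIX: Mapping[str, float] = {
    "S": 6.93e9 / (6.93e9 + 1.57e10),
    "L": 1.57e10 / (6.93e9 + 1.57e10),
    "VL_only": 0.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the repertoire generator.

    ``sublibrary_mix`` weights the source of the VH loop (S, L, or
    ``VL_only`` for clones keeping the parental VH); ``length_weights``
    optionally skews VH loop lengths (uniform by default);
    ``template_fraction`` is the probability a clone is emitted as pure
    unmutated template; error rates are per base.
    """

    seed: int = 0
    n_clones: int = 190
    sublibrary_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIX)
    )
    length_weights: Optional[Mapping[int, float]] = None
    vl_variant_mix: Tuple[float, float] = (0.5, 0.5)
    template_fraction: float = 0.0
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    genetic_code_mode: str = "standard"

    def __post_init__(self) -> None:
        for rate in (self.template_fraction, self.substitution_rate, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        total = sum(self.sublibrary_mix.values())
        if total <= 0:
            raise ValueError("sublibrary_mix weights must sum to a positive value")
        object.__setattr__(
            self,
            "sublibrary_mix",
            {k: v / total for k, v in self.sublibrary_mix.items()},
        )


def _realize_cassette(cassette: CDR3Cassette, rng: np.random.Generator) -> str:
    parts = []
    for pos in cassette.positions:
        for letter_bases in pos.codon.base_sets:
            bases = sorted(letter_bases)
            parts.append(bases[rng.integers(len(bases))])
    return "".join(parts)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _apply_errors(
    seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator
) -> Tuple[str, int, int]:
    """Substitutions first, then indels (ins/del 50:50, uniform base)."""
    n_subs = n_indels = 0
    if sub_rate > 0:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        hits = np.flatnonzero(rng.random(arr.size) < sub_rate)
        for i in hits:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = choices[rng.integers(3)]
        n_subs = hits.size
        seq = arr.tobytes().decode()
    if indel_rate > 0:
        out = []
        for ch in seq:
            if rng.random() < indel_rate:
                n_indels += 1
                if rng.random() < 0.5:
                    continue  # deletion
                out.append(ch)
                out.append("ACGT"[rng.integers(4)])  # insertion after
            else:
                out.append(ch)
        seq = "".join(out)
    return seq, n_subs, int(n_indels)


def _splice(design: LibraryDesign, vl_nt: Optional[str], vh_nt: Optional[str]) -> str:
    t = design.template
    vl_s, vl_e = design.vl_interval
    vh_s, vh_e = design.vh_interval
    vl_part = vl_nt if vl_nt is not None else t[vl_s:vl_e]
    vh_part = vh_nt if vh_nt is not None else t[vh_s:vh_e]
    return t[:vl_s] + vl_part + t[vl_e:vh_s] + vh_part + t[vh_e:]


def sample_clone(
    design: LibraryDesign,
    config: GeneratorConfig,
    rng: np.random.Generator,
    clone_id: str = "clone",
) -> Tuple[str, Dict[str, object]]:
    """Draw one clone; returns (sequence, truth row)."""
    code = genetic_code(config.genetic_code_mode)
    truth: Dict[str, object] = {"id": clone_id}

    if rng.random() < config.template_fraction:
        seq = design.template
        truth.update(
            source="template",
            is_template=True,
            vl_nt=design.template_region("VL"),
            vh_nt=design.template_region("VH"),
            vh_loop_length=pd.NA,
            vl_peptide=pd.NA,
            vh_peptide=pd.NA,
            has_stop=False,
        )
    else:
        names = list(config.sublibrary_mix)
        weights = np.array([config.sublibrary_mix[n] for n in names])
        source = names[rng.choice(len(names), p=weights)]

        variant_idx = rng.choice(2, p=np.asarray(config.vl_variant_mix) / sum(config.vl_variant_mix))
        vl_cassette = design.vl_cassettes[variant_idx]
        vl_nt = _realize_cassette(vl_cassette, rng)

        if source == "VL_only":
            vh_nt = None
            vh_loop_len = pd.NA
            vh_pep = pd.NA
        else:
            sub = design.sublibrary(source)
            lo, hi = sub.loop_lengths
            lengths = list(range(lo, hi + 1))
            if config.length_weights:
                w = np.array([config.length_weights.get(k, 0.0) for k in lengths])
                w = w / w.sum()
            else:
                w = np.full(len(lengths), 1.0 / len(lengths))
            vh_loop_len = int(lengths[rng.choice(len(lengths), p=w)])
            cassette = sub.cassettes[vh_loop_len - lo]
            vh_nt = _realize_cassette(cassette, rng)
            vh_pep = "".join(code[vh_nt[i : i + 3]] for i in range(0, len(vh_nt), 3))

        vl_pep = "".join(code[vl_nt[i : i + 3]] for i in range(0, len(vl_nt), 3))
        seq = _splice(design, vl_nt, vh_nt)
        truth.update(
            source=source if source == "VL_only" else f"{source}:k={vh_loop_len}",
            is_template=False,
            vl_nt=vl_nt,
            vh_nt=vh_nt if vh_nt is not None else design.template_region("VH"),
            vh_loop_length=vh_loop_len,
            vl_peptide=vl_pep,
            vh_peptide=vh_pep,
            has_stop="*" in vl_pep or (vh_pep is not pd.NA and "*" in vh_pep),
        )

    seq, n_subs, n_indels = _apply_errors(
        seq, config.substitution_rate, config.indel_rate, rng
    )
    truth["n_substitutions"] = n_subs
    truth["n_indels"] = n_indels
    return seq, truth


def generate_repertoire(
    design: Optional[LibraryDesign] = None,
    config: GeneratorConfig = GeneratorConfig(),
) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Generate ``config.n_clones`` reads plus their truth table.

    Returns ([(id, sequence), ...], truth DataFrame); both are fully
    determined by the config (single PRNG stream seeded once).
    """
    if design is None:
        design = default_library_design()
    rng = np.random.default_rng(config.seed)
    width = max(5, len(str(max(config.n_clones, 1))))
    reads: List[Tuple[str, str]] = []
    truth_rows: List[Dict[str, object]] = []
    for i in range(config.n_clones):
        clone_id = f"clone{i:0{width}d}"
        seq, truth = sample_clone(design, config, rng, clone_id)
        reads.append((clone_id, seq))
        truth_rows.append(truth)
    columns = [
        "id", "source", "is_template", "vh_loop_length", "vl_nt", "vh_nt",
        "vl_peptide", "vh_peptide", "has_stop", "n_substitutions", "n_indels",
    ]
    truth = pd.DataFrame(truth_rows, columns=columns)
    return reads, truth


def write_repertoire_fasta(
    reads: Sequence[Tuple[str, str]],
    truth: pd.DataFrame,
    fasta_path,
    truth_path=None,
    seed: Optional[int] = None,
) -> None:
    """Write reads as FASTA (seed recorded in headers) and truth as TSV."""
    tag = f" seed={seed}" if seed is not None else ""
    with open(fasta_path, "w") as fh:
        for clone_id, seq in reads:
            fh.write(f">{clone_id}{tag}\n{seq}\n")
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Screening fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElisaSignalParams:
    """Lognormal low/high absorbance components (A450 units)."""

    low_median: float = 0.08
    low_sigma: float = 0.15
    high_median: float = 1.2
    high_sigma: float = 0.2


def generate_elisa_fixture(
    n_clones: int = 50,
    n_binders: int = 12,
    signal_params: ElisaSignalParams = ElisaSignalParams(),
    seed: int = 0,
    n_negative_controls: int = 3,
) -> Tuple[ElisaPlate, pd.DataFrame]:
    """A monoclonal ELISA plate with planted binders.

    Binder wells draw from the high lognormal component, non-binders and
    negative controls from the low one.  The truth table lists each
    well's role.
    """
    if n_binders > n_clones:
        raise ValueError("more binders than clones")
    rng = np.random.default_rng(seed)
    binder_ids = set(rng.choice(n_clones, size=n_binders, replace=False).tolist())
    wells: List[Tuple[str, float]] = []
    rows = []
    p = signal_params
    for i in range(n_clones):
        is_binder = i in binder_ids
        median, sigma = (p.high_median, p.high_sigma) if is_binder else (p.low_median, p.low_sigma)
        a450 = float(rng.lognormal(np.log(median), sigma))
        well_id = f"clone{i:03d}"
        wells.append((well_id, a450))
        rows.append({"id": well_id, "is_binder": is_binder, "a450": a450})
    controls = []
    for j in range(n_negative_controls):
        a450 = float(rng.lognormal(np.log(p.low_median), p.low_sigma))
        well_id = f"neg{j}"
        wells.append((well_id, a450))
        controls.append(well_id)
        rows.append({"id": well_id, "is_binder": False, "a450": a450})
    plate = ElisaPlate(wells=tuple(wells), negative_controls=tuple(controls))
    return plate, pd.DataFrame(rows)


def generate_panning_fixture(
    n_rounds: int = 3,
    enrichment_factor: float = 10.0,
    base_input_titer: float = 1e12,
    base_output_ratio: float = 1e-6,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> List[PanningRound]:
    """Panning rounds whose output/input ratio grows by a fixed factor.

    ``noise_sigma`` adds lognormal noise to each output titer (0 = exact
    geometric trajectory).
    """
    rng = np.random.default_rng(seed)
    rounds = []
    for i in range(1, n_rounds + 1):
        ratio = base_output_ratio * enrichment_factor ** (i - 1)
        output = base_input_titer * ratio
        if noise_sigma > 0:
            output *= float(rng.lognormal(0.0, noise_sigma))
        rounds.append(
            PanningRound(index=i, input_titer=base_input_titer, output_titer=output)
        )
    return rounds
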