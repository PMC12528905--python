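"""Mutagenesis-primer arm QC and equimolar pooling.

Kunkel mutagenesis primers carry a degenerate cassette core between two
framework-complementary arms.  Annealing behaviour — and hence residual
unmutated template — is governed by the arms, which are therefore held
to three rules: balanced GC between arms (|ΔGC| ≤ 5 percentage points),
GC content below 50% on each arm, and melting temperature near 45 °C.

Tm methods: the Wallace rule 2(A+T)+4(G+C) for arms up to 14 nt,
nearest-neighbor thermodynamics (Allawi & SantaLucia 1997 unified
parameters, via Bio.SeqUtils.MeltingTemp) for longer arms.  The method
used is recorded in every report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from .codon_algebra import IUPAC_BASES

__all__ = [
    "AVOGADRO",
    "Primer",
    "QCRules",
    "PrimerQCReport",
    "AmbiguousSequenceError",
    "MissingArmError",
    "gc_content",
    "melting_temp",
    "qc_primer",
    "equimolar_pool",
    "read_primer_tsv",
]

AVOGADRO = 6.02214076e23  # molecules per mole

_DNA = set("ACGT")


class AmbiguousSequenceError(ValueError):
    """Arm-level metrics need unambiguous A/C/G/T sequence."""


class MissingArmError(ValueError):
    """Primer QC requires both complementary arms."""


@dataclass(frozen=True)
class Primer:
    """A mutagenesis oligo: arms flanking a (possibly degenerate) core."""

    name: str
    sequence: str
    upstream_arm: str
    downstream_arm: str
    concentration_uM: Optional[float] = None
    mass_ug: Optional[float] = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        up = self.upstream_arm.upper()
        down = self.downstream_arm.upper()
        if set(seq) - set(IUPAC_BASES):
            raise ValueError(f"primer {self.name}: non-IUPAC characters in sequence")
        if up and not seq.startswith(up):
            raise ValueError(f"primer {self.name}: upstream arm is not a prefix")
        if down and not seq.endswith(down):
            raise ValueError(f"primer {self.name}: downstream arm is not a suffix")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "upstream_arm", up)
        object.__setattr__(self, "downstream_arm", down)

    @property
    def core(self) -> str:
        end = len(self.sequence) - len(self.downstream_arm)
        return self.sequence[len(self.upstream_arm) : end]


def gc_content(seq: str) -> float:
    """GC percentage of an unambiguous sequence: 100·(G+C)/length."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - _DNA:
        raise AmbiguousSequenceError(
            f"GC content is defined for unambiguous sequence only, got {seq!r}"
        )
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def melting_temp(seq: str, method: str = "auto") -> Tuple[float, str]:
    """Melting temperature in °C and the method actually used.

    ``method`` is ``"wallace"``, ``"nn"`` or ``"auto"`` (Wallace up to
    14 nt, nearest-neighbor beyond).  NN uses the Allawi & SantaLucia
    (1997) unified parameters at 50 mM Na+ and 25 nM per strand.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - _DNA:
        raise AmbiguousSequenceError(f"Tm needs unambiguous sequence, got {seq!r}")
    if method == "auto":
        method = "wallace" if len(seq) <= 14 else "nn"
    if method == "wallace":
        return float(_mt.Tm_Wallace(seq)), "wallace"
    if method == "nn":
        return float(_mt.Tm_NN(seq)), "nn"
    raise ValueError(f"unknown Tm method {method!r}")


@dataclass(frozen=True)
class QCRules:
    """Arm acceptance rules (defaults follow the optimized protocol)."""

    max_arm_gc: float = 50.0       # strict: arm GC must be < this
    max_delta_gc: float = 5.0      # inclusive: |ΔGC| ≤ this
    tm_target: float = 45.0        # °C
    tm_window: float = 3.0         # inclusive: |Tm − target| ≤ this
    tm_method: str = "auto"


#: Rule identifiers used in reports.
RULE_GC_BELOW = "GC<50"
RULE_DELTA_GC = "dGC<=5"
RULE_TM_WINDOW = "Tm~45"


@dataclass(frozen=True)
class PrimerQCReport:
    name: str
    gc_upstream: float
    gc_downstream: float
    delta_gc: float
    tm_upstream: float
    tm_downstream: float
    tm_method: str
    failures: Tuple[str, ...]
    rules: QCRules

    @property
    def passed(self) -> bool:
        return not self.failures


def qc_primer(primer: Primer, rules: QCRules = QCRules()) -> PrimerQCReport:
    """Evaluate a primer's arms against the composition rules.

    Rules apply to the arms only — the degenerate core has no defined GC
    content.  Boundary behaviour: |ΔGC| exactly at the limit passes
    ("≤ 5%"), arm GC exactly at 50% fails ("below 50%"), Tm exactly at
    the window edge passes.
    """
    if not primer.upstream_arm or not primer.downstream_arm:
        raise MissingArmError(f"primer {primer.name}: both arms are required")
    gc_up = gc_content(primer.upstream_arm)
    gc_down = gc_content(primer.downstream_arm)
    delta = abs(gc_up - gc_down)
    tm_up, method = melting_temp(primer.upstream_arm, rules.tm_method)
    tm_down, _ = melting_temp(primer.downstream_arm, rules.tm_method)

    failures: List[str] = []
    if not (gc_up < rules.max_arm_gc and gc_down < rules.max_arm_gc):
        failures.append(RULE_GC_BELOW)
    if delta > rules.max_delta_gc:
        failures.append(RULE_DELTA_GC)
    if (
        abs(tm_up - rules.tm_target) > rules.tm_window
        or abs(tm_down - rules.tm_target) > rules.tm_window
    ):
        failures.append(RULE_TM_WINDOW)
    return PrimerQCReport(
        name=primer.name,
        gc_upstream=gc_up,
        gc_downstream=gc_down,
        delta_gc=delta,
        tm_upstream=tm_up,
        tm_downstream=tm_down,
        tm_method=method,
        failures=tuple(failures),
        rules=rules,
    )


def qc_report_frame(reports: Sequence[PrimerQCReport]) -> pd.DataFrame:
    """Tabulate QC reports (one row per primer)."""
    return pd.DataFrame(
        {
            "name": r.name,
            "gc_upstream": r.gc_upstream,
            "gc_downstream": r.gc_downstream,
            "delta_gc": r.delta_gc,
            "tm_upstream": r.tm_upstream,
            "tm_downstream": r.tm_downstream,
            "tm_method": r.tm_method,
            "passed": r.passed,
            "failures": ";".join(r.failures),
        }
        for r in reports
    )


def equimolar_pool(
    primers: Sequence[Primer], pmol_each: float = 100.0
) -> pd.DataFrame:
    """Volumes delivering an equal molar amount of every primer.

    Uses n = c·v, so v_i = pmol_each / c_i; when all primers sit at the
    same concentration (e.g. all diluted to 100 µM) the volumes are
    equal.  Molecule counts come from N = c·N_A·v.
    """
    if not primers:
        raise ValueError("no primers to pool")
    rows = []
    for p in primers:
        if p.concentration_uM is None or p.concentration_uM <= 0:
            raise ValueError(
                f"primer {p.name}: positive concentration required for pooling"
            )
        volume_ul = pmol_each / p.concentration_uM  # pmol / (pmol/µL)
        moles = pmol_each * 1e-12
        rows.append(
            {
                "name": p.name,
                "concentration_uM": p.concentration_uM,
                "volume_uL": volume_ul,
                "amount_pmol": pmol_each,
                "molecules": moles * AVOGADRO,
            }
        )
    pool = pd.DataFrame(rows)
    pool.attrs["total_volume_uL"] = float(pool["volume_uL"].sum())
    return pool


def read_primer_tsv(path) -> List[Primer]:
    """Load primers from TSV: name, sequence, upstream_arm, downstream_arm,
    optional concentration_uM and mass_ug columns."""
    table = pd.read_csv(path, sep="\t")
    primers = []
    for row in table.itertuples(index=False):
        primers.append(
            Primer(
                name=str(row.name),
                sequence=row.sequence,
                upstream_arm=row.upstream_arm,
                downstream_arm=row.downstream_arm,
                concentration_uM=getattr(row, "concentration_uM", None),
                mass_ug=getattr(row, "mass_ug", None),
            )
        )
    return primers
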