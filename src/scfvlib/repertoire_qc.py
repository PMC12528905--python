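"""QC of sequenced library clones: CDR3 extraction, diversity statistics,
residual-template detection, reference comparison, and library sizing.

Each clone is a single Sanger-style read spanning the scFv.  CDR3s are
located by approximate matching of fixed framework anchors flanking the
designed intervals; extracted regions are translated and flagged
(frameshift, internal stop, residual template).  Aggregate statistics
mirror the standard diversity analyses of a new library: loop-length
histograms, per-position residue counts and Shannon entropies, sequence
logo matrices, and Jensen-Shannon divergence against a natural-repertoire
reference.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import jensenshannon

from .cassette_design import (
    RESTRICTION_SITES,
    LibraryDesign,
    kabat_vh_labels,
)
from .codon_algebra import STOP, genetic_code

__all__ = [
    "ExtractedRegion",
    "CloneRecord",
    "RepertoireSummary",
    "extract_cdr3",
    "analyze_clone",
    "analyze_reads",
    "detect_template",
    "summarize_repertoire",
    "compare_to_reference",
    "export_logo_matrix",
    "estimate_library_size",
    "read_clone_fasta",
]

FLAG_UNANCHORED = "unanchored"
FLAG_FRAMESHIFT = "frameshift"
FLAG_INTERNAL_STOP = "internal_stop"
FLAG_TEMPLATE = "template"

#: Enzyme site assigned to each region for template detection.
REGION_SITES = {"VL": RESTRICTION_SITES["SacI"], "VH": RESTRICTION_SITES["NheI"]}


@dataclass(frozen=True)
class ExtractedRegion:
    """One CDR3 region located on a read (0-based half-open)."""

    start: int
    end: int
    nucleotides: str
    peptide: Optional[str]  # None when out of frame

    @property
    def in_frame(self) -> bool:
        return self.peptide is not None


@dataclass
class CloneRecord:
    """A sequenced clone with its extracted CDR3s and QC flags."""

    id: str
    sequence: str
    vl_cdr3: Optional[ExtractedRegion] = None
    vh_cdr3: Optional[ExtractedRegion] = None
    flags: frozenset = frozenset()
    template_evidence: Tuple[str, ...] = ()

    def region(self, name: str) -> Optional[ExtractedRegion]:
        return self.vl_cdr3 if name == "VL" else self.vh_cdr3


def _approx_hits(seq: str, anchor: str, max_mismatch: int) -> List[int]:
    """Start positions of best approximate matches of *anchor* in *seq*.

    Returns all positions achieving the minimal Hamming distance, provided
    that distance is ≤ *max_mismatch*; empty list otherwise.
    """
    m = len(anchor)
    if len(seq) < m:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    windows = sliding_window_view(arr, m)
    pat = np.frombuffer(anchor.encode(), dtype=np.uint8)
    mismatches = (windows != pat).sum(axis=1)
    best = int(mismatches.min())
    if best > max_mismatch:
        return []
    return [int(i) for i in np.flatnonzero(mismatches == best)]


def _translate(nt: str, code: Mapping[str, str]) -> str:
    return "".join(code.get(nt[i : i + 3], "X") for i in range(0, len(nt), 3))


def extract_cdr3(
    sequence: str,
    anchors: Tuple[str, str],
    max_mismatch: int = 1,
    mode: str = "standard",
) -> Optional[ExtractedRegion]:
    """Locate a CDR3 between two framework anchors.

    Each anchor may mismatch at up to ``max_mismatch`` positions; the
    best-scoring placement is used, and a tie between equally good
    placements (or a missing anchor) yields ``None`` (unanchored).
    """
    upstream, downstream = (a.upper() for a in anchors)
    if min(len(upstream), len(downstream)) < 6:
        raise ValueError("anchors must be at least 6 nt")
    sequence = sequence.upper()
    up_hits = _approx_hits(sequence, upstream, max_mismatch)
    if len(up_hits) != 1:
        return None
    start = up_hits[0] + len(upstream)
    down_hits = _approx_hits(sequence[start:], downstream, max_mismatch)
    if len(down_hits) != 1:
        return None
    end = start + down_hits[0]
    nt = sequence[start:end]
    peptide = _translate(nt, genetic_code(mode)) if len(nt) % 3 == 0 and nt else None
    if not nt:
        return None
    return ExtractedRegion(start=start, end=end, nucleotides=nt, peptide=peptide)


def detect_template(
    clone: CloneRecord, design: LibraryDesign
) -> Tuple[bool, Tuple[str, ...]]:
    """Decide whether a clone is residual unmutated template.

    A region counts as template if its extracted nucleotides equal the
    template CDR3 exactly, or contain the depletion site assigned to
    that region (SacI for VL, NheI for VH) — such a plasmid would be cut
    during depletion regardless of the rest of its sequence.  The clone
    is template-positive if either region triggers.  Note that a mutant
    cassette realization regenerating a site by chance is (correctly)
    reported as template here, since it is indistinguishable from — and
    depleted like — the parent.
    """
    evidence: List[str] = []
    for region in ("VL", "VH"):
        extracted = clone.region(region)
        if extracted is None:
            continue
        if extracted.nucleotides == design.template_region(region):
            evidence.append(f"{region}:exact")
        elif REGION_SITES[region] in extracted.nucleotides:
            evidence.append(f"{region}:site:{REGION_SITES[region]}")
    return bool(evidence), tuple(evidence)


def analyze_clone(
    clone_id: str,
    sequence: str,
    design: LibraryDesign,
    max_mismatch: int = 1,
    mode: str = "standard",
) -> CloneRecord:
    """Extract both CDR3s from a read and set all QC flags."""
    record = CloneRecord(id=clone_id, sequence=sequence.upper())
    flags = set()
    for region in ("VL", "VH"):
        anchors = design.flanks(region)
        extracted = extract_cdr3(record.sequence, anchors, max_mismatch, mode)
        if region == "VL":
            record.vl_cdr3 = extracted
        else:
            record.vh_cdr3 = extracted
        if extracted is None:
            flags.add(FLAG_UNANCHORED)
        else:
            if not extracted.in_frame:
                flags.add(FLAG_FRAMESHIFT)
            elif STOP in extracted.peptide:
                flags.add(FLAG_INTERNAL_STOP)
    is_template, evidence = detect_template(record, design)
    if is_template:
        flags.add(FLAG_TEMPLATE)
    record.flags = frozenset(flags)
    record.template_evidence = evidence
    return record


def analyze_reads(
    reads: Iterable[Tuple[str, str]],
    design: LibraryDesign,
    max_mismatch: int = 1,
    mode: str = "standard",
) -> List[CloneRecord]:
    """Analyze an iterable of (id, sequence) pairs."""
    return [
        analyze_clone(cid, seq, design, max_mismatch, mode) for cid, seq in reads
    ]


def read_clone_fasta(path) -> List[Tuple[str, str]]:
    """Load (id, sequence) pairs from FASTA or FASTQ (by extension)."""
    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]


# ---------------------------------------------------------------------------
# Aggregate statistics
# ---------------------------------------------------------------------------

def _vh_loop_peptide(peptide: str) -> str:
    """Strip the Arg/Asp anchors from an in-frame VH CDR3 peptide."""
    return peptide[1:-1]


def _region_positions(region: str, peptide: str) -> List[str]:
    if region == "VL":
        return [str(n) for n in range(91, 97)]
    return kabat_vh_labels(len(peptide))


@dataclass
class RepertoireSummary:
    """Aggregate diversity statistics of an analyzed repertoire."""

    n_total: int
    n_usable: int
    template_count: int
    length_histogram: Dict[str, Counter]
    aa_counts: Dict[str, pd.DataFrame]  # Kabat position × residue counts
    entropy: Dict[str, pd.Series]       # bits per position
    flag_counts: Counter = field(default_factory=Counter)

    def frequencies(self, region: str) -> pd.DataFrame:
        counts = self.aa_counts[region]
        totals = counts.sum(axis=1)
        return counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)


def _entropy_bits(row: np.ndarray) -> float:
    total = row.sum()
    if total == 0:
        return 0.0
    p = row[row > 0] / total
    return float(-(p * np.log2(p)).sum()) + 0.0  # avoid -0.0


def summarize_repertoire(
    clones: Sequence[CloneRecord],
    design: LibraryDesign,
    mode: str = "standard",
    include_stop_clones: bool = False,
    stratify_vh_by_length: bool = False,
) -> RepertoireSummary:
    """Length and per-position residue statistics over usable clones.

    Usable means: both CDR3s extracted, in frame, not residual template
    (templates are tallied in ``template_count``, not in the diversity
    statistics) and — unless ``include_stop_clones`` — free of internal
    stops (stop-containing clones cannot display).  Loop lengths count
    randomized residues only
    (VH anchors excluded).  VH positions from loops of different lengths
    are pooled by Kabat label; ``stratify_vh_by_length`` adds per-length
    matrices under keys ``"VH:k"``.
    """
    residues = sorted(set(genetic_code(mode).values()) - {STOP}) + [STOP]
    length_hist: Dict[str, Counter] = {"VL": Counter(), "VH": Counter()}
    matrix_counts: Dict[str, Dict[str, Counter]] = {"VL": {}, "VH": {}}
    flag_counts: Counter = Counter()
    n_usable = 0
    template_count = 0

    for clone in clones:
        flag_counts.update(clone.flags)
        if FLAG_TEMPLATE in clone.flags:
            template_count += 1
        skip_flags = {FLAG_UNANCHORED, FLAG_FRAMESHIFT, FLAG_TEMPLATE}
        if not include_stop_clones:
            skip_flags.add(FLAG_INTERNAL_STOP)
        if clone.flags & skip_flags:
            continue
        if clone.vl_cdr3 is None or clone.vh_cdr3 is None:
            continue
        vh_loop = _vh_loop_peptide(clone.vh_cdr3.peptide)
        if not 1 <= len(vh_loop) <= 32:  # outside the Kabat labelling range
            continue
        n_usable += 1
        peptides = {"VL": clone.vl_cdr3.peptide, "VH": vh_loop}
        length_hist["VL"][len(peptides["VL"])] += 1
        length_hist["VH"][len(peptides["VH"])] += 1
        for region, peptide in peptides.items():
            labels = _region_positions(region, peptide)
            for label, residue in zip(labels, peptide):
                matrix_counts[region].setdefault(label, Counter())[residue] += 1
            if region == "VH" and stratify_vh_by_length:
                key = f"VH:{len(peptide)}"
                matrix_counts.setdefault(key, {})
                for label, residue in zip(labels, peptide):
                    matrix_counts[key].setdefault(label, Counter())[residue] += 1

    aa_counts: Dict[str, pd.DataFrame] = {}
    entropy: Dict[str, pd.Series] = {}
    for key, per_pos in matrix_counts.items():
        if not per_pos and key not in ("VL", "VH"):
            continue
        if key == "VL":
            index = [str(n) for n in range(91, 97)]
        elif key == "VH":
            max_len = max(length_hist["VH"]) if length_hist["VH"] else 0
            index = kabat_vh_labels(max_len) if max_len else []
        else:
            index = kabat_vh_labels(int(key.split(":")[1]))
        frame = pd.DataFrame(
            [[per_pos.get(lbl, Counter()).get(res, 0) for res in residues] for lbl in index],
            index=index,
            columns=residues,
        )
        aa_counts[key] = frame
        entropy[key] = pd.Series(
            [_entropy_bits(frame.loc[lbl].to_numpy(dtype=float)) for lbl in index],
            index=index,
        )

    return RepertoireSummary(
        n_total=len(clones),
        n_usable=n_usable,
        template_count=template_count,
        length_histogram=length_hist,
        aa_counts=aa_counts,
        entropy=entropy,
        flag_counts=flag_counts,
    )


def compare_to_reference(
    summary: RepertoireSummary, reference: pd.DataFrame, region: str = "VL"
) -> pd.DataFrame:
    """Jensen-Shannon divergence (base 2, in bits) per shared position.

    ``reference`` is a position × residue frequency table (rows sum
    to 1), e.g. a natural human CDR3 repertoire profile.  The result has
    one row per shared Kabat position plus a ``mean`` row.
    """
    observed = summary.frequencies(region)
    shared = [p for p in observed.index if p in reference.index]
    residues = sorted(set(observed.columns) | set(reference.columns))
    rows = []
    for pos in shared:
        p = observed.reindex(columns=residues, fill_value=0.0).loc[pos].to_numpy()
        q = reference.reindex(columns=residues, fill_value=0.0).loc[pos].to_numpy()
        jsd = float(jensenshannon(p, q, base=2) ** 2) if p.sum() and q.sum() else np.nan
        rows.append({"position": pos, "jsd_bits": jsd})
    table = pd.DataFrame(rows).set_index("position")
    table.loc["mean"] = table["jsd_bits"].mean()
    return table


def export_logo_matrix(
    summary: RepertoireSummary, region: str, path=None, drop_stop: bool = True
) -> pd.DataFrame:
    """Position-frequency matrix for sequence-logo tools (rows sum to 1).

    Written as TSV (positions as rows, residues as columns), the format
    consumed by WebLogo-style tools and logomaker.
    """
    freqs = summary.frequencies(region)
    if drop_stop and STOP in freqs.columns:
        freqs = freqs.drop(columns=STOP)
        totals = freqs.sum(axis=1)
        freqs = freqs.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    if path is not None:
        freqs.to_csv(path, sep="\t", index_label="position")
    return freqs


def estimate_library_size(
    colony_counts: Sequence[float],
    dilution_factors: Sequence[float],
    plated_fraction: float = 1.0,
) -> Tuple[float, float, np.ndarray]:
    """Library size from serial-dilution colony counts.

    Each replicate estimates ``count × dilution / plated_fraction``;
    returns (mean, SD, per-replicate estimates).  SD is the sample
    standard deviation (ddof=1) for ≥2 replicates, 0 otherwise.
    """
    counts = np.asarray(colony_counts, dtype=float)
    dilutions = np.asarray(dilution_factors, dtype=float)
    if dilutions.size == 1:
        dilutions = np.full_like(counts, dilutions[0])
    if counts.shape != dilutions.shape:
        raise ValueError("colony_counts and dilution_factors lengths differ")
    if not 0 < plated_fraction <= 1:
        raise ValueError("plated_fraction must be in (0, 1]")
    estimates = counts * dilutions / plated_fraction
    sd = float(estimates.std(ddof=1)) if estimates.size > 1 else 0.0
    return float(estimates.mean()), sd, estimates
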