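"""Panning enrichment statistics and ELISA hit calling.

After iterative affinity selection (panning), enrichment is tracked as
the output/input phage titer ratio per round; specific binders are then
called from monoclonal ELISA absorbances by a fold-over-negative-control
rule (a clone is a hit when its A450 is at least ``fold_threshold``
times the negative-control level; the threshold itself counts, per
"≥ 4-fold").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PanningRound",
    "ElisaPlate",
    "enrichment_trajectory",
    "call_hits",
    "rank_candidates",
    "read_panning_tsv",
    "read_plate_tsv",
]


@dataclass(frozen=True)
class PanningRound:
    """Input/output phage titers (pfu) of one selection round."""

    index: int
    input_titer: float
    output_titer: float

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("round index starts at 1")
        if self.input_titer <= 0 or self.output_titer <= 0:
            raise ValueError("titers must be positive")

    @property
    def ratio(self) -> float:
        return self.output_titer / self.input_titer


@dataclass(frozen=True)
class ElisaPlate:
    """Absorbance wells with at least one designated negative control."""

    wells: Tuple[Tuple[str, float], ...]
    negative_controls: Tuple[str, ...]

    def __post_init__(self) -> None:
        labels = {label for label, _ in self.wells}
        if not self.negative_controls:
            raise ValueError("at least one negative control is required")
        missing = set(self.negative_controls) - labels
        if missing:
            raise ValueError(f"negative controls not on plate: {sorted(missing)}")
        if any(a450 < 0 for _, a450 in self.wells):
            raise ValueError("absorbances must be non-negative")


def enrichment_trajectory(rounds: Sequence[PanningRound]) -> pd.DataFrame:
    """Per-round output/input ratios and round-over-round fold changes."""
    ordered = sorted(rounds, key=lambda r: r.index)
    rows = []
    prev_ratio = None
    for rnd in ordered:
        fold = rnd.ratio / prev_ratio if prev_ratio is not None else np.nan
        rows.append(
            {
                "round": rnd.index,
                "input_titer": rnd.input_titer,
                "output_titer": rnd.output_titer,
                "ratio": rnd.ratio,
                "fold_change": fold,
            }
        )
        prev_ratio = rnd.ratio
    return pd.DataFrame(rows)


def call_hits(
    plate: ElisaPlate,
    fold_threshold: float = 4.0,
    control_stat: str = "mean",
) -> Tuple[List[str], pd.DataFrame]:
    """Call ELISA hits by the fold-over-negative-control rule.

    A clone is a hit iff ``A450 ≥ fold_threshold × control_level``
    (equality included).  ``control_stat`` summarizes the negative wells
    as their ``"mean"`` (default) or ``"median"``.  Returns the hit ids
    and a per-clone report with fold values.
    """
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    controls = dict(plate.wells)
    neg_values = np.array([controls[label] for label in plate.negative_controls])
    if control_stat == "mean":
        level = float(neg_values.mean())
    elif control_stat == "median":
        level = float(np.median(neg_values))
    else:
        raise ValueError(f"unknown control_stat {control_stat!r}")
    if level <= 0:
        raise ValueError("negative-control level must be positive for fold calls")

    neg_set = set(plate.negative_controls)
    rows = []
    for label, a450 in plate.wells:
        if label in neg_set:
            continue
        fold = a450 / level
        rows.append(
            {"id": label, "a450": a450, "fold_over_control": fold,
             "is_hit": fold >= fold_threshold}
        )
    report = pd.DataFrame(rows)
    report.attrs["control_level"] = level
    report.attrs["fold_threshold"] = fold_threshold
    hits = report.loc[report["is_hit"], "id"].tolist()
    return hits, report


def rank_candidates(report: pd.DataFrame) -> List[Tuple[str, float]]:
    """Hits ordered by descending fold-over-control, ties by id.

    Accepts the report frame from :func:`call_hits`.
    """
    hits = report[report["is_hit"]]
    ordered = hits.sort_values(
        ["fold_over_control", "id"], ascending=[False, True]
    )
    return list(zip(ordered["id"], ordered["fold_over_control"]))


def read_panning_tsv(path) -> List[PanningRound]:
    """Load rounds from TSV with columns round, input_titer, output_titer."""
    table = pd.read_csv(path, sep="\t")
    return [
        PanningRound(int(getattr(r, "round")), float(r.input_titer), float(r.output_titer))
        for r in table.itertuples(index=False)
    ]


def read_plate_tsv(path) -> ElisaPlate:
    """Load a plate from TSV with columns id, a450, role (clone|negative)."""
    table = pd.read_csv(path, sep="\t")
    wells = tuple((str(r.id), float(r.a450)) for r in table.itertuples(index=False))
    controls = tuple(
        str(r.id) for r in table.itertuples(index=False) if str(r.role) == "negative"
    )
    return ElisaPlate(wells=wells, negative_controls=controls)
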