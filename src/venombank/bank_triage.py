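"""Concentration triage, plate layout and production statistics.

Purified peptides are quantified (A280 + peak area) and binned for the
screening bank: above 20 uM the quantification is trusted and the stock is
diluted to 10 uM; 5-20 uM peptides are banked as-is (together these form the
"10 uM bank"); 1-5 uM peptides go to the "1 uM bank"; below 1 uM the clone
counts as non-producing and is discarded.  Boundary semantics are half-open
(exactly 20 -> as-is, exactly 5 -> as-is, exactly 1 -> 1 uM bank) to make the
prose ranges disjoint; they are configurable via ``TriageThresholds``.

Stocks are 250 uL; each bank plate holds 80 peptides plus 16 control wells
(columns 1 and 12), and spawns five 50-uL replicate copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .peptide_io import DEFAULT_LENGTH_CLASSES, length_class

FINAL_VOLUME_UL = 250.0
TARGET_CONC_UM = 10.0
PEPTIDES_PER_PLATE = 80
CONTROL_WELLS_PER_PLATE = 16
PLATE_COPIES = 5
ALIQUOT_UL = 50.0

BINS = ("adjust_to_10", "bank10_asis", "bank1", "discard")


def round_half_away(x: float) -> int:
    """Round half away from zero (the rendering used in the reports)."""
    return int(floor(x + 0.5)) if x >= 0 else -int(floor(-x + 0.5))


def percent(part: float, total: float, decimals: int = 0) -> float:
    """Report-style percentage with round-half-away rendering."""
    if total == 0:
        return 0.0
    raw = 100.0 * part / total
    scale = 10 ** decimals
    return round_half_away(raw * scale) / scale


@dataclass(frozen=True)
class TriageThresholds:
    discard_below: float = 1.0
    bank1_below: float = 5.0
    asis_max: float = 20.0


@dataclass(frozen=True)
class TriageDecision:
    peptide_id: str
    conc_um: float
    bin: str
    stock_volume_ul: float
    water_ul: float
    final_conc_um: float
    final_volume_ul: float = FINAL_VOLUME_UL

    @property
    def bank(self) -> str | None:
        if self.bin in ("adjust_to_10", "bank10_asis"):
            return "bank10"
        if self.bin == "bank1":
            return "bank1"
        return None


def assign_bin(conc_um: float, peptide_id: str = "peptide",
               thresholds: TriageThresholds | None = None) -> TriageDecision:
    """Triage one peptide by concentration; dilution by C1*V1 = C2*V2."""
    if conc_um < 0:
        raise ValueError("concentration must be non-negative")
    t = thresholds or TriageThresholds()
    if conc_um > t.asis_max:
        stock = FINAL_VOLUME_UL * TARGET_CONC_UM / conc_um
        return TriageDecision(peptide_id, conc_um, "adjust_to_10",
                              stock, FINAL_VOLUME_UL - stock, TARGET_CONC_UM)
    if conc_um >= t.bank1_below:
        return TriageDecision(peptide_id, conc_um, "bank10_asis",
                              FINAL_VOLUME_UL, 0.0, conc_um)
    if conc_um >= t.discard_below:
        return TriageDecision(peptide_id, conc_um, "bank1",
                              FINAL_VOLUME_UL, 0.0, conc_um)
    return TriageDecision(peptide_id, conc_um, "discard", 0.0, 0.0, 0.0,
                          final_volume_ul=0.0)


ROWS = "ABCDEFGH"
CONTROL_COLUMNS = (1, 12)
_PEPTIDE_WELLS = [f"{row}{col}" for col in range(2, 12) for row in ROWS]
_CONTROL_WELLS = [f"{row}{col}" for col in CONTROL_COLUMNS for row in ROWS]


@dataclass(frozen=True)
class PlateLayout:
    plate_id: str
    bank: str
    wells: Mapping[str, str]  # well -> peptide_id | "CONTROL"
    copy_count: int = PLATE_COPIES
    aliquot_ul: float = ALIQUOT_UL

    @property
    def peptide_wells(self) -> list[str]:
        return [w for w, v in self.wells.items() if v != "CONTROL"]


def layout_plates(decisions: Sequence[TriageDecision]) -> list[PlateLayout]:
    """Fill bank plates (80 peptides + 16 controls) in input order.

    The 10 uM and 1 uM banks are laid out separately; the last plate of each
    bank may be partial.  Five 50-uL copies per 250-uL stock are feasible by
    construction (5 x 50 == 250).
    """
    assert PLATE_COPIES * ALIQUOT_UL <= FINAL_VOLUME_UL
    if any(d.bank is None for d in decisions):
        raise ValueError("discarded peptides cannot be plated")
    plates: list[PlateLayout] = []
    for bank in ("bank10", "bank1"):
        ids = [d.peptide_id for d in decisions if d.bank == bank]
        for p in range(0, len(ids), PEPTIDES_PER_PLATE):
            chunk = ids[p:p + PEPTIDES_PER_PLATE]
            wells = {w: "CONTROL" for w in _CONTROL_WELLS}
            wells.update(zip(_PEPTIDE_WELLS, chunk))
            plates.append(
                PlateLayout(
                    plate_id=f"{bank}-{p // PEPTIDES_PER_PLATE + 1:02d}",
                    bank=bank,
                    wells=wells,
                )
            )
    return plates


def bank_summary(decisions: Sequence[TriageDecision]) -> dict:
    """Counts and report percentages per triage bin and bank."""
    counts = {b: 0 for b in BINS}
    for d in decisions:
        counts[d.bin] += 1
    total = len(decisions)
    bank10 = counts["adjust_to_10"] + counts["bank10_asis"]
    bank1 = counts["bank1"]
    produced = bank10 + bank1
    return {
        "total": total,
        "counts": counts,
        "produced": produced,
        "bank10": bank10,
        "bank1": bank1,
        "above_20": counts["adjust_to_10"],
        "percent": {b: percent(counts[b], total) for b in BINS},
        "bank10_percent_of_produced": percent(bank10, produced),
        "bank1_percent_of_produced": percent(bank1, produced),
        "above_20_percent_of_bank10": percent(counts["adjust_to_10"], bank10),
    }


@dataclass(frozen=True)
class ProductionRecord:
    """Peptide metadata plus production outcome, for the report breakdowns."""

    peptide_id: str
    taxon: str
    length: int
    n_bridges_max: int
    odd_cysteines: bool
    pattern: str
    nterm: str
    produced: bool
    conc_um: float = 0.0

    def __post_init__(self) -> None:
        if self.produced and self.conc_um and self.conc_um < 1.0:
            raise ValueError("produced peptides must have conc >= 1 uM")


GROUP_KEYS = ("taxon", "length_class", "n_bridges", "odd_even_cys",
              "nterm", "pattern")


def production_report(records: Sequence[ProductionRecord], group_by: str,
                      length_classes: Sequence[tuple[int, int]] =
                      DEFAULT_LENGTH_CLASSES) -> pd.DataFrame:
    """Success-rate table per group: (group, n, n_produced, success %).

    Success percentages are rendered to the nearest integer; groups are
    ordered by group size descending.
    """
    if not records:
        raise ValueError("no production records")
    if group_by not in GROUP_KEYS:
        raise ValueError(f"unknown group_by key {group_by!r}; "
                         f"choose from {GROUP_KEYS}")

    def key(r: ProductionRecord):
        if group_by == "taxon":
            return r.taxon
        if group_by == "length_class":
            return length_class(r.length, length_classes)
        if group_by == "n_bridges":
            return r.n_bridges_max
        if group_by == "odd_even_cys":
            return "odd" if r.odd_cysteines else "even"
        if group_by == "nterm":
            return r.nterm
        return r.pattern

    df = pd.DataFrame(
        {"group": [key(r) for r in records],
         "produced": [r.produced for r in records]}
    )
    out = (
        df.groupby("group", sort=False)
        .agg(n=("produced", "size"), n_produced=("produced", "sum"))
        .reset_index()
    )
    out["success_pct"] = [
        round_half_away(100.0 * p / n) for p, n in zip(out.n_produced, out.n)
    ]
    return out.sort_values("n", ascending=False, kind="stable",
                           ignore_index=True)
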