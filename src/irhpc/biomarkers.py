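"""Blood and IHC biomarkers: dNLR and PD-L1 TPS rules.

dNLR = neutrophils / (leukocytes - neutrophils), dichotomised at a
strict > 3. PD-L1 cases are evaluable only with at least 100 viable
tumour cells on the slide; the tumour proportion score is banded at the
1% and 50% cutoffs (both inclusive-lower), and the association between
eosinophils in both tumour compartments and TPS positivity is tested by
Pearson chi-square without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

from irhpc.cohort_model import BloodCount, Pdl1Record
from irhpc.stats import Chi2Result, pearson_chi2

DNLR_THRESHOLD = 3.0
MIN_VIABLE_CELLS = 100

TPS_NEGATIVE = "negative"
TPS_POSITIVE_LOW = "positive_low"
TPS_HIGH = "high"


@dataclass(frozen=True)
class DnlrResult:
    value: float
    high: bool                     # strictly greater than the threshold
    threshold: float = DNLR_THRESHOLD


def dnlr(counts: BloodCount, threshold: float = DNLR_THRESHOLD) -> DnlrResult:
    """Derived neutrophil-to-lymphocyte ratio with its > threshold flag."""
    problems = counts.validate()
    if problems:
        raise ValueError("invalid blood counts: " + "; ".join(map(str, problems)))
    value = counts.neutrophils / (counts.leukocytes - counts.neutrophils)
    return DnlrResult(value=value, high=value > threshold, threshold=threshold)


@dataclass(frozen=True)
class Exclusion:
    case_id: str
    reason: str


def filter_pdl1_evaluable(records: list[Pdl1Record], min_cells: int = MIN_VIABLE_CELLS
                          ) -> tuple[list[Pdl1Record], list[Exclusion]]:
    """Keep cases with at least ``min_cells`` viable tumour cells
    (inclusive boundary) and log each exclusion with its reason."""
    kept, log = [], []
    for rec in records:
        if rec.viable_tumour_cells >= min_cells:
            kept.append(rec)
        else:
            log.append(Exclusion(rec.case_id,
                                 f"insufficient tumour cells "
                                 f"({rec.viable_tumour_cells} < {min_cells})"))
    return kept, log


def tps_category(tps: float) -> str:
    """Band a tumour proportion score: [0,1) negative, [1,50) positive
    at the low cutoff, [50,100] high."""
    if not (0 <= tps <= 100):
        raise ValueError(f"TPS must lie in [0,100], got {tps!r}")
    if tps < 1:
        return TPS_NEGATIVE
    if tps < 50:
        return TPS_POSITIVE_LOW
    return TPS_HIGH


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Eosinophil compartment pattern (rows) x TPS at a cutoff (columns).

    Row order: eosinophils in both compartments, then not; column order:
    TPS at/above the cutoff, then below.
    """

    cells: tuple[tuple[int, int], tuple[int, int]]
    tps_cutoff: float
    test: Chi2Result

    @property
    def total(self) -> int:
        return sum(sum(row) for row in self.cells)


def eosinophil_pdl1_table(records: list[Pdl1Record], tps_cutoff: float = 50
                          ) -> ContingencyTable2x2:
    """Cross-tabulate eosinophil pattern against TPS >= cutoff.

    ``records`` must already be filtered for evaluability. The attached
    test is Pearson chi-square without continuity correction, flagged
    degenerate when a margin is empty.
    """
    if tps_cutoff not in (1, 50):
        raise ValueError("TPS cutoff must be 1 or 50")
    if not records:
        raise ValueError("no evaluable PD-L1 records")
    cells = [[0, 0], [0, 0]]
    for rec in records:
        i = 0 if rec.eosinophils_both_compartments else 1
        j = 0 if rec.tps >= tps_cutoff else 1
        cells[i][j] += 1
    test = pearson_chi2(cells)
    return ContingencyTable2x2(cells=tuple(tuple(r) for r in cells),
                               tps_cutoff=tps_cutoff, test=test)
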