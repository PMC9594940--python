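"""The pretreatment irHPC score and its >=2-point predicted-response rule.

The score is additive over four biopsy features: TIL grade plus
eosinophil grade plus one point for dense plasma cells, minus the
neutrophil grade (neutrophils are the negative feature, contributing
minus their ordinal grade). The attainable range is therefore [-3, 7].
A case whose score reaches the cutoff (default 2 points) is predicted
to respond (cPR/MPR) to neoadjuvant anti-PD-1 treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

from irhpc.cohort_model import FeatureGrades, Violation

DEFAULT_CUTOFF = 2
SCORE_MIN, SCORE_MAX = -3, 7

RESPONDER = "responder"
NON_RESPONDER = "non_responder"


@dataclass(frozen=True)
class IrhpcScore:
    value: int
    predicted_responder: bool
    cutoff: int = DEFAULT_CUTOFF


def irhpc_score(grades: FeatureGrades, cutoff: int = DEFAULT_CUTOFF) -> IrhpcScore:
    """Score one set of biopsy feature grades.

    value = til + eosinophils - neutrophils + (1 if dense plasma cells
    present else 0); predicted_responder iff value >= cutoff.
    """
    problems = grades.validate()
    if problems:
        raise ValueError("invalid feature grades: " + "; ".join(map(str, problems)))
    value = (grades.til + grades.eosinophils - grades.neutrophils
             + (1 if grades.dense_plasma_cells else 0))
    return IrhpcScore(value=value, predicted_responder=value >= cutoff, cutoff=cutoff)


def classify_prediction(score: int, cutoff: int = DEFAULT_CUTOFF) -> str:
    """Map a score to the predicted class: responder iff score >= cutoff."""
    if not (SCORE_MIN <= score <= SCORE_MAX):
        raise ValueError(f"score {score} outside attainable range [{SCORE_MIN}, {SCORE_MAX}]")
    return RESPONDER if score >= cutoff else NON_RESPONDER


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    n_at_or_above_cutoff: int
    percent_at_or_above: float | None  # None when the group is empty
    undefined: bool = False


def score_group_summary(scores: dict[str, int], responses: dict[str, str],
                        cutoff: int = DEFAULT_CUTOFF) -> dict[str, GroupSummary]:
    """Cross-tabulate reference scores against the actual response class.

    ``responses`` maps each case to one of cPR/MPR/pPR/nPR; cases are
    pooled into the responder (cPR/MPR) and non-responder (pPR/nPR)
    groups and counted at the cutoff. Percentages are rounded to one
    decimal; an empty group is flagged undefined rather than reported
    as 0%.
    """
    missing = sorted(set(responses) - set(scores)) + sorted(set(scores) - set(responses))
    if missing:
        raise ValueError(f"cases lacking a score or a response class: {missing}")
    groups: dict[str, list[int]] = {"cPR/MPR": [], "pPR/nPR": []}
    for case, resp in responses.items():
        if resp in ("cPR", "MPR"):
            groups["cPR/MPR"].append(scores[case])
        elif resp in ("pPR", "nPR"):
            groups["pPR/nPR"].append(scores[case])
        else:
            raise ValueError(f"case {case}: unknown response class {resp!r}")
    out = {}
    for name, vals in groups.items():
        n = len(vals)
        k = sum(1 for v in vals if v >= cutoff)
        pct = round(100.0 * k / n, 1) if n else None
        out[name] = GroupSummary(group=name, n=n, n_at_or_above_cutoff=k,
                                 percent_at_or_above=pct, undefined=(n == 0))
    return out
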