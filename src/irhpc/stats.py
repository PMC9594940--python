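"""Agreement statistics and nonparametric tests.

Overall per cent agreement (OPA) treats every unordered pair of raters
within a case as one comparison and reports the concordant fraction
with a 95% confidence interval (Wilson score by default). Chance-
corrected multi-rater agreement uses Fleiss' kappa with the standard
interpretation bands: <= 0.40 poor to fair, 0.41-0.60 moderate,
0.61-0.80 substantial, 0.81-1.00 almost perfect.

The nonparametric tests (Wilcoxon signed-rank, Kruskal-Wallis, Pearson
chi-square without continuity correction) are thin, defaulted wrappers
over scipy so every caller in the package applies the same conventions:
zero differences dropped, exact signed-rank null for small samples,
two-sided p-values throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss
from statsmodels.stats.proportion import proportion_confint

KAPPA_BANDS = [
    (0.40, "poor to fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
]


@dataclass(frozen=True)
class AgreementResult:
    n_pairs: int
    n_concordant: int
    opa: float                     # percent
    ci_low: float                  # percent
    ci_high: float                 # percent
    kappa: float | None = None
    kappa_label: str | None = None


def _as_ratings(ratings) -> np.ndarray:
    arr = np.asarray(ratings, dtype=float)
    if arr.ndim != 2:
        raise ValueError("ratings must be a 2-D cases x raters matrix")
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 raters")
    return arr


def opa(ratings, ci_method: str = "wilson") -> AgreementResult:
    """Overall per cent agreement over all within-case rater pairs.

    ``ratings`` is a cases x raters matrix of categorical codes with NaN
    marking a missing rating; a pair contributes only when both ratings
    are present. The CI treats pairs as independent (an approximation,
    since pairs within a case share raters).
    """
    arr = _as_ratings(ratings)
    n_pairs = n_conc = 0
    for row in arr:
        present = row[~np.isnan(row)]
        for a, b in itertools.combinations(present, 2):
            n_pairs += 1
            n_conc += a == b
    if n_pairs == 0:
        raise ValueError("no rater pairs with both ratings present")
    return _opa_result(n_conc, n_pairs, ci_method)


def opa_from_counts(n_concordant: int, n_cases: int, n_raters: int,
                    ci_method: str = "wilson") -> AgreementResult:
    """OPA from summary counts: n_pairs = n_cases * C(n_raters, 2)."""
    n_pairs = n_cases * math.comb(n_raters, 2)
    if not (0 <= n_concordant <= n_pairs):
        raise ValueError(f"impossible counts: {n_concordant} concordant of {n_pairs} pairs")
    if n_pairs == 0:
        raise ValueError("no pairs")
    return _opa_result(n_concordant, n_pairs, ci_method)


def _opa_result(n_conc: int, n_pairs: int, ci_method: str) -> AgreementResult:
    method = {"wilson": "wilson", "clopper-pearson": "beta"}.get(ci_method)
    if method is None:
        raise ValueError(f"unknown CI method {ci_method!r}")
    lo, hi = proportion_confint(n_conc, n_pairs, alpha=0.05, method=method)
    return AgreementResult(n_pairs=n_pairs, n_concordant=int(n_conc),
                           opa=100.0 * n_conc / n_pairs,
                           ci_low=100.0 * lo, ci_high=100.0 * hi)


def interpret_kappa(kappa: float) -> str:
    """Label a kappa value with its interpretation band.

    Kappa is rounded to two decimals first, so values falling in the
    printed band gaps (e.g. 0.405) resolve to the nearer band.
    """
    k = round(kappa, 2)
    for upper, label in KAPPA_BANDS:
        if k <= upper:
            return label
    return KAPPA_BANDS[-1][1]


def fleiss_kappa(ratings) -> tuple[float, str]:
    """Fleiss' kappa for a cases x raters matrix of categorical ratings.

    Cases must have the same number of non-missing ratings; rows with a
    deviating count are dropped (Fleiss' formulation assumes a constant
    number of ratings per subject). Returns (kappa, band label); raises
    when chance agreement is 1 (a single category used throughout).
    """
    arr = _as_ratings(ratings)
    counts_per_row = (~np.isnan(arr)).sum(axis=1)
    n_typical = int(np.max(counts_per_row))
    keep = counts_per_row == n_typical
    if not keep.all():
        import warnings
        warnings.warn(f"dropping {int((~keep).sum())} case(s) with fewer than "
                      f"{n_typical} ratings", stacklevel=2)
    arr = arr[keep]
    if arr.shape[0] == 0 or n_typical < 2:
        raise ValueError("no cases with >= 2 ratings")
    cats = np.unique(arr[~np.isnan(arr)])
    table = np.zeros((arr.shape[0], len(cats)), dtype=int)
    for j, c in enumerate(cats):
        table[:, j] = np.nansum(arr == c, axis=1)
    if len(cats) < 2:
        raise ValueError("kappa undefined: a single category used throughout")
    kappa = float(_sm_fleiss(table, method="fleiss"))
    return kappa, interpret_kappa(kappa)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_nonzero: int
    n_zero_dropped: int


def wilcoxon_signed_rank(x, y=None) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    With two arrays, tests the differences x - y. Zero differences are
    dropped (classic Wilcoxon). The exact null distribution is used for
    up to 25 non-zero untied pairs, a tie-corrected normal approximation
    otherwise.
    """
    d = np.asarray(x, dtype=float) - (0 if y is None else np.asarray(y, dtype=float))
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero; test degenerate")
    ties = len(np.unique(np.abs(nz))) < nz.size
    method = "exact" if (nz.size <= 25 and not ties) else "approx"
    res = sps.wilcoxon(nz, zero_method="wilcox", method=method,
                       correction=False, alternative="two-sided")
    return WilcoxonResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                          n_nonzero=int(nz.size), n_zero_dropped=int(d.size - nz.size))


@dataclass(frozen=True)
class KruskalResult:
    statistic: float
    p_value: float
    df: int


def kruskal_wallis(*groups) -> KruskalResult:
    """Kruskal-Wallis rank test across >= 2 groups (tie-corrected H,
    chi-square approximation with k - 1 degrees of freedom)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if sum(1 for g in groups if g.size) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        # scipy raises when all values are identical across groups
        flat = np.concatenate(groups)
        if np.all(flat == flat[0]):
            return KruskalResult(statistic=0.0, p_value=1.0, df=len(groups) - 1)
    h, p = sps.kruskal(*groups)
    return KruskalResult(statistic=float(h), p_value=float(p), df=len(groups) - 1)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    df: int
    degenerate: bool = False


def pearson_chi2(table) -> Chi2Result:
    """Pearson chi-square on a 2x2 table, without continuity correction.

    A zero row or column margin makes independence untestable; the
    result is then flagged degenerate with statistic 0.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if arr.sum() <= 0 or (arr < 0).any():
        raise ValueError("table cells must be non-negative with a positive total")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return Chi2Result(statistic=0.0, p_value=1.0, df=1, degenerate=True)
    chi2, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    return Chi2Result(statistic=float(chi2), p_value=float(p), df=int(dof))
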