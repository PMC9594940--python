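# Methods note

## Scope and data model

The package evaluates neoadjuvant anti-PD-1 cohorts given *recorded*
pathology: ordinal biopsy feature grades per rater, tumour-bed
component areas per rater, blood counts, PD-L1 slide records and
right-censored follow-up. It deliberately does not interpret images or
define what histology constitutes a 1+ versus 2+ grade — grades and
areas are inputs. Tables are plain CSV (UTF-8, header row, "." decimal
mark), one row per (case, rater) for the patients table, joined on
`case_id`; per-case fields repeat on each rater row. Missing values
are empty cells and are never imputed; each operation states how it
treats missingness (means skip missing raters with a warning,
agreement pairs require both ratings, Fleiss' κ drops rows with a
deviating rating count).

## The pretreatment score

`score = til + eosinophils − neutrophils + 1{dense plasma cells}` over
grades 0–3. The neutrophil contribution is minus the ordinal grade —
the mirrored-magnitude reading is the only one consistent with the
documented score range of the non-responder group reaching −2 and with
the symmetric grade scale. The cutoff is a parameter defaulting to 2
and the rule is `≥` (a score of exactly 2 predicts response). The
score is monotone in each feature by construction; the test suite
checks this exhaustively over all 4×4×4×2 = 128 grade combinations.

Where a cohort carries no designated reference scorer, the pipeline
uses the per-case **median of rater scores** as the consensus score
for the score-versus-response cross-tabulation and for score-based
survival grouping (integral for an odd rater count). Fixture-level
analyses may instead supply reference scores directly to
`score_group_summary`.

## %RVT and response classes

Both formulas operate on per-case area totals:
`%RVT = 100·RVT/(RVT+necrosis+regression)` and
`%RVT-without-necrosis = 100·RVT/(RVT+regression)`. Dropping necrosis
only shrinks the denominator, so the without-necrosis percent weakly
dominates, with equality exactly when necrosis is absent (property
tested). Classes are half-open continuous intervals cPR = {0},
MPR = (0, 10], pPR = (10, 90], nPR = (90, 100]: inclusive upper bounds
are the only convention under which a case at exactly 10% is MPR while
non-integer percents remain classifiable. No rounding happens before
classification; percents are displayed to one decimal. The
with-necrosis formula is the default and the variant is an explicit
flag, since the immune-related response criteria treat the full
tumour bed as the baseline denominator. A tumour bed consisting of
necrosis only makes the without-necrosis percent undefined; this is a
named error, not a silent zero.

## Agreement statistics

OPA counts every unordered rater pair within a case (both ratings
present) and reports concordant/total with a 95% CI. The CI method is
the Wilson score interval by default — well behaved at extreme
proportions — with Clopper–Pearson selectable; either way the pairs
are treated as independent, which overstates the effective sample
size slightly because pairs within a case share raters. This
approximation is documented rather than corrected, matching how the
45-pair denominator is conventionally used.

Fleiss' κ uses the standard formulation (per-case agreement averaged,
chance agreement from pooled category proportions) via statsmodels,
on a counts table the package builds after dropping cases whose
number of non-missing ratings deviates from the modal count. Band
labels are assigned after rounding κ to two decimals, so values
falling in the printed band gaps (0.401–0.409 etc.) resolve to the
nearer band. κ is undefined (raised) when a single category is used
throughout.

## Nonparametric tests

Wilcoxon signed-rank drops zero differences (classic Wilcoxon), uses
the exact null for ≤ 25 untied non-zero pairs and a tie-corrected
normal approximation otherwise; all p-values two-sided. With 17
all-positive non-zero differences the exact two-sided p is
2·(1/2)¹⁷ ≈ 1.5×10⁻⁵. Kruskal–Wallis uses the tie-corrected H with a
χ² approximation on k−1 degrees of freedom; identical-valued groups
short-circuit to H = 0, p = 1. The eosinophil × TPS association uses
Pearson's χ² **without** continuity correction: on the 108-case
contingency tables this choice reproduces both published p-values
(≈ 0.003 at the 50% cutoff, ≈ 0.343 at 1%), whereas the Yates-corrected
statistic does not (≈ 0.008).

## Survival

Kaplan–Meier estimation is delegated to lifelines behind a thin
`KmCurve` container. Deaths flagged unrelated to treatment are
*removed* from the analysis set (not censored), reproducing the
29-of-31 analysis convention. `rate_at` evaluates S(t)
right-continuously — a query at an event time returns the post-event
value — and flags queries beyond the last observed time as
extrapolation. Median follow-up is the simple median with a min–max
range (the published figure is a range, not a CI); reverse-KM is not
the default. DFS events are encoded by the input flags (relapse or
treatment-related death), never inferred.

## The synthetic-data generator

`simulate_cohort` draws, per patient: latent ordinal grades from
per-feature categorical distributions; a true score; MPR achievement
from a logistic link in the true score (intercept −1.6, slope 1.1,
giving ≈ 48% responders at the default grade distributions); a latent
%RVT — responders split into a cPR point mass (probability 0.4,
mirroring 6 cPR among 15 responders) and uniform (0, 10], while
non-responders are uniform (10, 100]; a tumour bed of 100 area units
decomposed so that the necrosis share of the non-viable remainder has
mean 0.10 and is exactly zero for 35% of cases; per-rater observed
grades through a symmetric ±1 slip model (slip probability 0.25,
clipped at the 0/3 boundaries; binary plasma flips with probability
0.10) and per-rater areas with lognormal noise (σ = 0.10); blood
counts with the neutrophil fraction increasing in the neutrophil grade
and calibrated so roughly a third of patients exceed dNLR 3;
exponential DFS/OS times with group-specific hazards and
administrative censoring at 45 months; and an independent 109-case
PD-L1 series with one insufficient-cell case in expectation, 45/108
eosinophil-both prevalence, and a TPS-high odds ratio of 5.4 for the
eosinophil-both group (the value implied by the published 12/45 vs
4/63 split). Slip and flip models are the simplest ordinal/binary
noise structures; the field reports only that rater variability
existed, so nothing finer is identifiable.

What a green test establishes: the estimators recover the generator's
stated quantities (closed-form pairwise agreement (1−q)²+q²,
exponential S(t), the sign of the score→response link) at the stated
Monte-Carlo tolerances. What it does not establish: anything about
real histology — the generator has no spatial structure, no
correlation between features beyond the score link, no per-slide
heterogeneity, and rater errors independent across features and cases.

## Numerical conventions

Percentages are reported to one decimal, κ to two; classification
always precedes rounding. Seeds use `numpy.random.default_rng`
(integer-state, platform-stable); a fixed seed gives byte-identical
cohort files. Degenerate inputs are surfaced as flags or typed errors
(all-zero paired differences, single-category κ, zero-margin χ²,
empty tumour bed), never as NaN propagation.

## Known limitations

The published group-wise DFS/OS rates, κ = 0.54 and the 17-of-31
paired %RVT comparison depend on per-patient values that were never
deposited; the package reproduces the estimators and validates them
against oracles and closed forms, not those specific numbers. The OPA
confidence interval's independence approximation is described above.
The pipeline's median-of-raters consensus score is a stand-in for a
designated reference scorer and can differ from one where rater noise
is asymmetric.
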