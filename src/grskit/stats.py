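"""Case/control statistics for GRS cohorts.

Risk stratification at fixed GRS cutpoints, stratified odds ratios with Wald
confidence intervals against the average-risk reference, the Cochran-Armitage
proportion trend test, the Wilcoxon rank-sum comparison of case vs control
scores, mean-GRS summaries, and multi-cancer high/low-risk tallies.

Conventions: strata are low (GRS < 0.5), average (0.5 <= GRS <= 1.5, the
reference) and high (GRS > 1.5) — boundary values fall in "average" because
the defining inequalities for low and high are strict. Stratum p-values are
Pearson chi-square without continuity correction (Fisher's exact test
available by flag); zero cells get no Haldane-Anscombe correction by default
so a stratum with no cases reports OR 0 with an undefined upper bound. No
multiple-testing adjustment is applied across cancers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError
from .grs import GRSVector

CATEGORIES = ("low", "average", "high")
REFERENCE = "average"

#: Cancers analysed in a single sex only; others apply to everyone.
SEX_RESTRICTED: dict[str, str] = {
    "breast": "female",
    "ovarian": "female",
    "prostate": "male",
}


@dataclass(frozen=True)
class RiskCategories:
    """Per-subject risk stratum plus the cutpoints that defined it."""

    subject_ids: tuple[str, ...]
    categories: tuple[str, ...]
    low_cut: float
    high_cut: float

    def __post_init__(self) -> None:
        if len(self.subject_ids) != len(self.categories):
            raise AnalysisError("subject_ids and categories length mismatch")
        bad = set(self.categories) - set(CATEGORIES)
        if bad:
            raise AnalysisError(f"unknown categories {bad}")

    def counts(self) -> dict[str, int]:
        return {c: self.categories.count(c) for c in CATEGORIES}

    def __len__(self) -> int:
        return len(self.subject_ids)


def categorize_risk(
    grs: GRSVector, low_cut: float = 0.5, high_cut: float = 1.5
) -> RiskCategories:
    """Assign each subject to low / average / high risk by GRS.

    ``GRS < low_cut`` is low, ``GRS > high_cut`` is high, everything else —
    including scores exactly at either cutpoint — is average.
    """
    if not low_cut < high_cut:
        raise AnalysisError(f"low_cut {low_cut} must be below high_cut {high_cut}")
    values = grs.grs
    cats = np.where(values < low_cut, "low", np.where(values > high_cut, "high", "average"))
    return RiskCategories(grs.subject_ids, tuple(cats.tolist()), low_cut, high_cut)


@dataclass(frozen=True)
class OddsRatioResult:
    oddsratio: float
    ci_low: float
    ci_high: float
    p_value: float


def odds_ratio_ci(
    a_case: int,
    a_ctrl: int,
    ref_case: int,
    ref_ctrl: int,
    alpha: float = 0.05,
    fisher: bool = False,
    haldane: bool = False,
) -> OddsRatioResult:
    """Odds ratio of a stratum against the reference, with Wald CI.

    OR is the cross-product ``(a_case * ref_ctrl) / (a_ctrl * ref_case)``;
    the CI is ``exp(log OR +/- z * sqrt(sum of reciprocal cells))``. With an
    empty case cell the OR is 0 and the upper bound undefined (NaN); with an
    empty control cell the OR is infinite and the lower bound undefined —
    mirroring how such strata are conventionally printed. ``haldane`` adds
    0.5 to every cell when any is zero. The p-value is a 1-df Pearson
    chi-square on the 2x2 without continuity correction, or Fisher's exact
    test when ``fisher``.
    """
    cells = (a_case, a_ctrl, ref_case, ref_ctrl)
    if any(c < 0 for c in cells):
        raise AnalysisError(f"counts must be non-negative, got {cells}")
    if ref_case == 0 or ref_ctrl == 0:
        raise AnalysisError("reference stratum must have cases and controls")

    table = np.array([[a_case, a_ctrl], [ref_case, ref_ctrl]], dtype=float)
    if fisher:
        p = float(sps.fisher_exact(table)[1])
    else:
        p = float(sps.chi2_contingency(table, correction=False)[1])

    if haldane and 0 in cells:
        a_case, a_ctrl, ref_case, ref_ctrl = (c + 0.5 for c in cells)

    z = sps.norm.ppf(1 - alpha / 2)
    if a_case == 0:
        return OddsRatioResult(0.0, 0.0, math.nan, p)
    if a_ctrl == 0:
        return OddsRatioResult(math.inf, math.nan, math.inf, p)
    log_or = math.log(a_case * ref_ctrl) - math.log(a_ctrl * ref_case)
    se = math.sqrt(1 / a_case + 1 / a_ctrl + 1 / ref_case + 1 / ref_ctrl)
    return OddsRatioResult(
        math.exp(log_or), math.exp(log_or - z * se), math.exp(log_or + z * se), p
    )


def trend_test(
    case_counts: Sequence[int],
    total_counts: Sequence[int],
    scores: Sequence[float] = (0.0, 1.0, 2.0),
) -> tuple[float, float]:
    """Cochran-Armitage chi-square test for trend in proportions.

    Tests a linear trend in the case proportion across ordered strata with
    the given scores (equally spaced by default), identical to R's
    ``prop.trend.test``. Returns the signed z statistic and two-sided p.
    Strata with zero total are dropped; a degenerate table (all cases or no
    cases) returns ``(nan, nan)`` with a warning.
    """
    x = np.asarray(case_counts, dtype=float)
    n = np.asarray(total_counts, dtype=float)
    s = np.asarray(scores, dtype=float)
    if not (x.size == n.size == s.size):
        raise AnalysisError("case_counts, total_counts and scores length mismatch")
    if (x > n).any() or (x < 0).any() or (n < 0).any():
        raise AnalysisError("counts must satisfy 0 <= cases <= total per stratum")
    keep = n > 0
    x, n, s = x[keep], n[keep], s[keep]
    if keep.sum() < 2:
        raise AnalysisError("trend test needs at least 2 strata with subjects")
    total = n.sum()
    p_bar = x.sum() / total
    if p_bar in (0.0, 1.0):
        warnings.warn("trend test degenerate: all subjects in one arm", stacklevel=2)
        return math.nan, math.nan
    numerator = float((s * (x - n * p_bar)).sum())
    variance = p_bar * (1 - p_bar) * float((n * s**2).sum() - (n * s).sum() ** 2 / total)
    z = numerator / math.sqrt(variance)
    return z, float(2 * sps.norm.sf(abs(z)))


@dataclass(frozen=True)
class StratumRow:
    category: str
    cases: int
    controls: int
    oddsratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class RiskTable:
    """3x2 case/control table over risk strata with per-stratum ORs and trend."""

    strata: tuple[StratumRow, ...]
    trend_z: float
    trend_p: float
    reference: str = REFERENCE

    def stratum(self, category: str) -> StratumRow:
        for row in self.strata:
            if row.category == category:
                return row
        raise AnalysisError(f"no stratum {category!r}")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame([vars(r) for r in self.strata])
        frame["trend_p"] = self.trend_p
        return frame


def risk_table_from_counts(
    case_counts: Mapping[str, int],
    control_counts: Mapping[str, int],
    alpha: float = 0.05,
    fisher: bool = False,
    haldane: bool = False,
) -> RiskTable:
    """Build the stratified OR table directly from low/average/high counts.

    The average stratum is the reference (OR fixed at 1); low and high are
    each compared to it with :func:`odds_ratio_ci`, and the trend test runs
    over the three strata ordered low -> average -> high.
    """
    for counts, arm in ((case_counts, "case"), (control_counts, "control")):
        missing = set(CATEGORIES) - set(counts)
        if missing:
            raise AnalysisError(f"{arm} counts missing strata {sorted(missing)}")
    ref_case, ref_ctrl = case_counts[REFERENCE], control_counts[REFERENCE]
    if ref_case == 0 or ref_ctrl == 0:
        raise AnalysisError(
            "reference (average-risk) stratum is empty in one arm; OR undefined"
        )
    rows = []
    for cat in CATEGORIES:
        if cat == REFERENCE:
            rows.append(
                StratumRow(cat, ref_case, ref_ctrl, 1.0, math.nan, math.nan, math.nan)
            )
        else:
            res = odds_ratio_ci(
                case_counts[cat], control_counts[cat], ref_case, ref_ctrl,
                alpha=alpha, fisher=fisher, haldane=haldane,
            )
            rows.append(
                StratumRow(
                    cat, case_counts[cat], control_counts[cat],
                    res.oddsratio, res.ci_low, res.ci_high, res.p_value,
                )
            )
    cases = [case_counts[c] for c in CATEGORIES]
    totals = [case_counts[c] + control_counts[c] for c in CATEGORIES]
    z, p = trend_test(cases, totals)
    return RiskTable(tuple(rows), z, p)


def build_risk_table(
    case_cats: RiskCategories,
    control_cats: RiskCategories,
    alpha: float = 0.05,
    fisher: bool = False,
    haldane: bool = False,
) -> RiskTable:
    """Tabulate case and control risk categories into a stratified OR table."""
    overlap = set(case_cats.subject_ids) & set(control_cats.subject_ids)
    if overlap:
        raise AnalysisError(
            f"{len(overlap)} subject(s) appear in both arms, e.g. {sorted(overlap)[:3]}"
        )
    return risk_table_from_counts(
        case_cats.counts(), control_cats.counts(),
        alpha=alpha, fisher=fisher, haldane=haldane,
    )


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses full enumeration of rank assignments when the pooled sample has at
    most 12 observations and no ties; otherwise the normal approximation
    with tie and continuity corrections. Returns (U statistic of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise AnalysisError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    exact = pooled.size <= 12 and np.unique(pooled).size == pooled.size
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GRSSummary:
    group: str
    n: int
    mean: float
    ci_low: float
    ci_high: float


def mean_grs_summary(
    grs: GRSVector | Sequence[float], group: str, alpha: float = 0.05
) -> GRSSummary:
    """Arithmetic mean GRS with a normal-approximation confidence interval."""
    values = grs.grs if isinstance(grs, GRSVector) else np.asarray(grs, dtype=float)
    n = values.size
    if n < 2:
        raise AnalysisError("mean summary needs at least 2 subjects")
    mean = float(values.mean())
    half = float(sps.norm.ppf(1 - alpha / 2) * values.std(ddof=1) / math.sqrt(n))
    return GRSSummary(group, n, mean, mean - half, mean + half)


@dataclass(frozen=True)
class MultiCancerTally:
    """Proportions of subjects in extreme strata for at least one cancer."""

    n: dict[str, int]
    high_any: dict[str, float]
    low_any: dict[str, float]
    extreme_any: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.n,
                "high_risk_any": self.high_any,
                "low_risk_any": self.low_any,
                "high_or_low_any": self.extreme_any,
            }
        ).rename_axis("group")


def tally_multi_cancer(
    categories_by_cancer: Mapping[str, RiskCategories],
    sex: Mapping[str, str],
) -> MultiCancerTally:
    """Fraction of subjects at high (and low) risk for >= 1 cancer type.

    Each subject is tallied over their *applicable* cancers: sex-restricted
    cancers (breast and ovarian for females, prostate for males) only count
    for subjects of that sex; a subject of unknown sex is excluded from the
    restricted cancers with a warning but still counted for the rest.
    Proportions are reported overall and within each sex.
    """
    subjects: dict[str, dict[str, bool]] = {}
    unknown_seen = False
    for cancer, cats in categories_by_cancer.items():
        required = SEX_RESTRICTED.get(cancer.lower())
        for sid, cat in zip(cats.subject_ids, cats.categories):
            subject_sex = sex.get(sid, "unknown")
            if required is not None and subject_sex != required:
                if subject_sex == "unknown":
                    unknown_seen = True
                continue
            flags = subjects.setdefault(sid, {"high": False, "low": False})
            if cat in ("high", "low"):
                flags[cat] = True
    if unknown_seen:
        warnings.warn(
            "subjects of unknown sex excluded from sex-restricted cancers",
            stacklevel=2,
        )
    if not subjects:
        raise AnalysisError("no subjects to tally")

    groups = {
        "overall": list(subjects),
        "male": [s for s in subjects if sex.get(s) == "male"],
        "female": [s for s in subjects if sex.get(s) == "female"],
    }
    n, high_any, low_any, extreme_any = {}, {}, {}, {}
    for label, members in groups.items():
        n[label] = len(members)
        if not members:
            high_any[label] = low_any[label] = extreme_any[label] = math.nan
            continue
        hi = sum(subjects[s]["high"] for s in members)
        lo = sum(subjects[s]["low"] for s in members)
        both = sum(subjects[s]["high"] or subjects[s]["low"] for s in members)
        high_any[label] = hi / len(members)
        low_any[label] = lo / len(members)
        extreme_any[label] = both / len(members)
    return MultiCancerTally(n, high_any, low_any, extreme_any)
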