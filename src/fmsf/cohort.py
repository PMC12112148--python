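"""Cohort construction, exclusion rules and case--control statistics.

The study design compares women with patchy alopecia areata (AA) and
alopecia universalis (AU) against healthy controls.  Subjects showing
evident mitochondrial dysfunction — a negative ischemic response
(IRmax < 0) — are excluded before analysis, because severe systemic disease
masks the vascular effects of interest.

Two-group comparisons follow a normality-gated procedure: Shapiro--Wilk on
each group, Student's t-test (Welch by default) when both pass at the chosen
alpha, Mann--Whitney U otherwise.  Correlations use Pearson when both
marginals pass the gate, Spearman otherwise.  No multiple-testing correction
is applied (seven parameters, unadjusted p-values).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import PARAMETER_NAMES, FMSFParameters

logger = logging.getLogger(__name__)

__all__ = [
    "GROUP_LABELS",
    "COMORBIDITY_FLAGS",
    "SubjectRecord",
    "ExclusionRules",
    "GroupComparison",
    "CorrelationResult",
    "apply_exclusions",
    "choose_test",
    "compare_groups",
    "correlate",
    "summarize_groups",
    "compare_cohort",
    "pooled_mean",
]

GROUP_LABELS = ("AA", "AU", "control")
COMORBIDITY_FLAGS = ("smoking", "depression", "hashimoto", "hypertension",
                     "hypercholesterolemia", "diabetes")


@dataclass
class SubjectRecord:
    """One study participant: metadata plus derived FMSF parameters."""

    subject_id: str
    group: str
    sex: str = "F"
    age: float = math.nan
    bmi: float = math.nan
    sbp: float = math.nan
    dbp: float = math.nan
    flags: dict[str, bool] = field(default_factory=dict)
    parameters: FMSFParameters | None = None
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.group!r}; "
                             f"expected one of {GROUP_LABELS}")
        if not (math.isnan(self.age) or self.age > 0):
            raise ValueError("age must be > 0")


@dataclass(frozen=True)
class ExclusionRules:
    """Subject-exclusion policy, applied in field order.

    ``negative_ir`` removes subjects with IRmax < 0 (mitochondrial
    dysfunction); ``restrict_sex`` keeps only the given sex when set;
    ``exclude_flags`` removes subjects with any listed comorbidity flag set.
    """

    negative_ir: bool = True
    restrict_sex: str | None = None
    exclude_flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of one two-group comparison."""

    parameter: str
    test: str                      # "t_test" or "mann_whitney"
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")

    @property
    def significant(self) -> bool:
        """True at the conventional p < 0.05 threshold."""
        return self.p_value < 0.05


@dataclass(frozen=True)
class CorrelationResult:
    """Outcome of one correlation analysis; nan coefficient marks missing."""

    method: str                    # "pearson" or "spearman"
    coefficient: float
    p_value: float
    n: int


def apply_exclusions(subjects: Sequence[SubjectRecord],
                     rules: ExclusionRules = ExclusionRules(),
                     ) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Split a cohort into retained subjects and an exclusion log.

    Every excluded record is marked with the first matching reason; the two
    returned lists always partition the input.  An empty retained cohort
    yields a warning, not an error.
    """
    retained: list[SubjectRecord] = []
    excluded: list[SubjectRecord] = []
    for s in subjects:
        reason = ""
        if rules.negative_ir:
            ir = s.parameters.IRmax if s.parameters is not None else math.nan
            if math.isnan(ir):
                reason = "unmeasurable ischemic response"
            elif ir < 0:
                reason = f"negative ischemic response (IRmax = {ir:.1f})"
        if not reason and rules.restrict_sex is not None \
                and s.sex != rules.restrict_sex:
            reason = f"sex restricted to {rules.restrict_sex}"
        if not reason:
            for flag in rules.exclude_flags:
                if s.flags.get(flag, False):
                    reason = f"comorbidity: {flag}"
                    break
        if reason:
            s.excluded = True
            s.exclusion_reason = reason
            excluded.append(s)
            logger.info("excluded %s (%s): %s", s.subject_id, s.group, reason)
        else:
            retained.append(s)
    if not retained:
        warnings.warn("all subjects excluded; cohort is empty", stacklevel=2)
    counts = pd.Series([s.group for s in retained]).value_counts().to_dict()
    logger.info("retained %d subjects: %s", len(retained), counts)
    return retained, excluded


def _clean(values: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    return arr[~np.isnan(arr)]


def choose_test(group_a: Iterable[float], group_b: Iterable[float],
                alpha: float = 0.05) -> str:
    """Select the two-group test via the Shapiro--Wilk normality gate.

    Returns ``"t_test"`` when both groups are consistent with normality
    (Shapiro--Wilk p >= alpha in each), ``"mann_whitney"`` otherwise.
    """
    a, b = _clean(group_a), _clean(group_b)
    if a.size < 3 or b.size < 3:
        raise ValueError("insufficient data for normality gate (n < 3)")
    p_a = stats.shapiro(a).pvalue
    p_b = stats.shapiro(b).pvalue
    return "t_test" if (p_a >= alpha and p_b >= alpha) else "mann_whitney"


def compare_groups(group_a: Iterable[float], group_b: Iterable[float],
                   test: str, parameter: str = "",
                   equal_var: bool = False) -> GroupComparison:
    """Run the selected two-sided two-group test.

    ``t_test`` uses the Welch unequal-variance statistic by default
    (``equal_var=True`` switches to the classical pooled form); Mann--Whitney
    uses exact enumeration for small tie-free samples (n <= 8 per side) and
    the tie- and continuity-corrected normal approximation otherwise.  Two
    degenerate groups with equal means yield p = 1 by convention.
    """
    a, b = _clean(group_a), _clean(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    summary = dict(
        n_a=int(a.size), n_b=int(b.size),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)) if a.size > 1 else math.nan,
        sd_b=float(b.std(ddof=1)) if b.size > 1 else math.nan,
    )
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        warnings.warn("zero variance in both groups with equal means; "
                      "p = 1 by convention", stacklevel=2)
        return GroupComparison(parameter=parameter, test=test,
                               statistic=0.0, p_value=1.0, **summary)
    if test == "t_test":
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    elif test == "mann_whitney":
        small = a.size <= 8 and b.size <= 8
        ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (small and not ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(parameter=parameter, test=test,
                           statistic=float(res.statistic),
                           p_value=float(res.pvalue), **summary)


def correlate(x: Iterable[float], y: Iterable[float],
              alpha: float = 0.05) -> CorrelationResult:
    """Normality-gated correlation: Pearson if both marginals pass
    Shapiro--Wilk at ``alpha``, Spearman otherwise.

    A constant input vector makes the coefficient undefined; a missing-value
    result is returned with a warning.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must be paired")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if xa.size < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        warnings.warn("constant input; correlation undefined", stacklevel=2)
        return CorrelationResult(method="undefined", coefficient=math.nan,
                                 p_value=math.nan, n=int(xa.size))
    normal = (stats.shapiro(xa).pvalue >= alpha
              and stats.shapiro(ya).pvalue >= alpha)
    if normal:
        res = stats.pearsonr(xa, ya)
        method = "pearson"
    else:
        res = stats.spearmanr(xa, ya)
        method = "spearman"
    return CorrelationResult(method=method, coefficient=float(res.statistic),
                             p_value=float(res.pvalue), n=int(xa.size))


def pooled_mean(means: Sequence[float], ns: Sequence[int]) -> float:
    """n-weighted mean of subgroup means (equals the mean of the pooled raw
    values whenever the subgroup means came from those values)."""
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    if ns.sum() == 0:
        raise ValueError("empty pooling")
    return float((means * ns).sum() / ns.sum())


def _group_values(subjects: Sequence[SubjectRecord], group: str,
                  parameter: str) -> np.ndarray:
    vals = [getattr(s.parameters, parameter) for s in subjects
            if s.group == group and s.parameters is not None]
    return np.asarray(vals, dtype=float)


def summarize_groups(subjects: Sequence[SubjectRecord],
                     parameters: Sequence[str] = PARAMETER_NAMES,
                     ) -> pd.DataFrame:
    """Per-group and pooled summary table: n, mean and sample SD.

    Rows are parameters; columns are a MultiIndex of
    (AA | AU | AA+AU | control) x (n | mean | sd).  The pooled AA+AU column
    is computed from the raw values, which coincides with the n-weighted mean
    of the subgroup means.  A single-subject group reports SD as missing; an
    empty group's columns are omitted with a warning.
    """
    columns: dict[str, list[str] | None] = {
        "AA": ["AA"], "AU": ["AU"], "AA+AU": ["AA", "AU"],
        "control": ["control"],
    }
    blocks: dict[str, pd.DataFrame] = {}
    for col, members in columns.items():
        rows = {}
        n_any = 0
        for p in parameters:
            vals = np.concatenate([_group_values(subjects, g, p)
                                   for g in members])
            vals = vals[~np.isnan(vals)]
            n = int(vals.size)
            n_any = max(n_any, n)
            rows[p] = {
                "n": n,
                "mean": float(vals.mean()) if n else math.nan,
                "sd": float(vals.std(ddof=1)) if n > 1 else math.nan,
            }
        if n_any == 0:
            warnings.warn(f"group column {col!r} is empty; omitted",
                          stacklevel=2)
            continue
        blocks[col] = pd.DataFrame.from_dict(rows, orient="index")
    if not blocks:
        return pd.DataFrame()
    out = pd.concat(blocks, axis=1)
    out.index.name = "parameter"
    return out


#: Parameters compared on the log scale, where they are approximately normal.
LOG_SCALE = {"FM": "logFM", "NEURO": "logNEURO", "HS": "logHS"}


def compare_cohort(subjects: Sequence[SubjectRecord],
                   parameters: Sequence[str] = ("FM", "NEURO", "NOI", "RHR",
                                                "IRmax", "HRmax", "HS"),
                   case_groups: Sequence[str] = ("AA", "AU"),
                   control_group: str = "control",
                   alpha: float = 0.05) -> list[GroupComparison]:
    """Gate-then-test every parameter: pooled cases versus controls.

    Right-skewed magnitude parameters (FM, NEURO, HS) are gated and tested on
    their log10 scale — the scale on which the comparison is actually made —
    while the reported group means and SDs stay on the natural scale of the
    analysis column.
    """
    results = []
    for p in parameters:
        scale = LOG_SCALE.get(p, p)
        cases = np.concatenate([_group_values(subjects, g, scale)
                                for g in case_groups])
        controls = _group_values(subjects, control_group, scale)
        cases, controls = cases[~np.isnan(cases)], controls[~np.isnan(controls)]
        test = choose_test(cases, controls, alpha=alpha)
        label = p if scale == p else f"{p} (log10 scale)"
        results.append(compare_groups(cases, controls, test, parameter=label))
    return results
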