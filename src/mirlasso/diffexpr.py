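"""Two-group assignment from clinical endpoints and differential-expression filtering.

The filter is a sequential screen: a pooled-variance (Student's) two-sample
t-test keeps features with P below the threshold, then a fold-change gate
keeps those with FC strictly above ``upper_fc`` or strictly below
``lower_fc`` (defaults 1.5 and 0.667).  No multiple-testing correction is
applied — the screen is deliberately nonstringent, its job is to reduce the
feature set entering network estimation, not to control an error rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)

RULES = ("survival_1yr", "er_status", "stage_I_II_vs_III_IV", "explicit")

#: one year, in days; survival at exactly this value counts as high-risk
SURVIVAL_CUTOFF_DAYS = 365


class GroupingError(ValueError):
    """Raised when a grouping rule cannot produce two nonempty groups."""


@dataclass
class GroupAssignment:
    """Two disjoint sample groups derived from a clinical endpoint rule.

    ``group_a`` is the high-risk / ER-negative / stage III-IV side of each
    rule; it is the fold-change numerator downstream.  Samples whose endpoint
    was absent are listed in ``excluded``.
    """

    group_a: list[str]
    group_b: list[str]
    rule_name: str
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rule_name not in RULES:
            raise GroupingError(f"unknown rule {self.rule_name!r}; expected one of {RULES}")
        if not self.group_a or not self.group_b:
            raise GroupingError(f"rule {self.rule_name!r} produced an empty group")
        overlap = set(self.group_a) & set(self.group_b)
        if overlap:
            raise GroupingError(f"samples in both groups: {sorted(overlap)}")


def assign_groups(clinical: ClinicalTable, rule: str) -> GroupAssignment:
    """Split samples into two groups according to a clinical endpoint rule.

    Rules
    -----
    ``survival_1yr``
        group A (high-risk) = survival_days <= 365, group B (low-risk) > 365.
        Recorded survival days are used as-is; censoring is not modelled.
    ``er_status``
        group A = ER-negative, group B = ER-positive.
    ``stage_I_II_vs_III_IV``
        group A (high-risk) = stages III/IV, group B (low-risk) = I/II.

    Samples with an absent endpoint are excluded and reported on the
    returned assignment.
    """
    df = clinical.data
    if rule == "survival_1yr":
        endpoint = df["survival_days"]
        present = endpoint.notna()
        a = list(df.index[present & (endpoint <= SURVIVAL_CUTOFF_DAYS)])
        b = list(df.index[present & (endpoint > SURVIVAL_CUTOFF_DAYS)])
        logger.warning(
            "survival_1yr uses recorded survival_days as-is; censoring is ignored"
        )
    elif rule == "er_status":
        endpoint = df["er_status"]
        present = endpoint.notna()
        a = list(df.index[present & (endpoint == "negative")])
        b = list(df.index[present & (endpoint == "positive")])
    elif rule == "stage_I_II_vs_III_IV":
        endpoint = df["stage"]
        present = endpoint.notna()
        a = list(df.index[present & endpoint.isin(["III", "IV"])])
        b = list(df.index[present & endpoint.isin(["I", "II"])])
    else:
        raise GroupingError(f"unknown rule {rule!r}; expected one of {RULES}")
    excluded = list(df.index[~present])
    if excluded:
        logger.info("rule %s: %d samples excluded (absent endpoint)", rule, len(excluded))
    return GroupAssignment(group_a=a, group_b=b, rule_name=rule, excluded=excluded)


def t_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided pooled-variance (Student's) two-sample t-test P value.

    Both vectors need at least two observations.  If the pooled variance is
    zero the test is degenerate: P = 1 when the group means are equal (no
    evidence of difference), P = 0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError(f"each group needs >= 2 observations, got {x.size} and {y.size}")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        return 1.0 if x.mean() == y.mean() else 0.0
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.pvalue)


def fold_change(x: np.ndarray, y: np.ndarray) -> float:
    """Ratio of group means, mean(x)/mean(y); NaN when mean(y) is zero.

    Inputs must be nonnegative (expression-like); negative values raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("fold_change needs nonempty groups")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("fold_change requires nonnegative expression values")
    my = y.mean()
    if my == 0.0:
        return float("nan")
    return float(x.mean() / my)


@dataclass
class DifferentialResult:
    """Per-feature outcome of the t-test + fold-change screen."""

    feature_id: str
    p_value: float
    fold_change: float  # NaN when undefined (zero denominator group mean)
    passes: bool
    error: str | None = None


def select_differential(
    expr: ExpressionMatrix,
    groups: GroupAssignment,
    p_threshold: float = 0.05,
    upper_fc: float = 1.5,
    lower_fc: float = 0.667,
    log2_transform: bool = False,
) -> list[DifferentialResult]:
    """Run the sequential DE screen over every feature of ``expr``.

    A feature passes iff P < ``p_threshold`` and its fold change is strictly
    above ``upper_fc`` or strictly below ``lower_fc``.  Fold changes are
    group A mean over group B mean; an undefined fold change (zero group B
    mean) fails.  Per-feature computation errors are recorded on the result
    rather than aborting the run.  ``log2_transform`` applies log2(x+1)
    before testing (off by default).
    """
    missing = [s for s in groups.group_a + groups.group_b if s not in expr.values.index]
    if missing:
        raise ValueError(f"group samples absent from expression matrix: {missing}")
    xa = expr.values.loc[groups.group_a].to_numpy(dtype=float)
    xb = expr.values.loc[groups.group_b].to_numpy(dtype=float)
    if log2_transform:
        if (xa < 0).any() or (xb < 0).any():
            raise ValueError("log2 transform requires nonnegative values")
        xa = np.log2(xa + 1.0)
        xb = np.log2(xb + 1.0)

    results: list[DifferentialResult] = []
    for j, fid in enumerate(expr.feature_ids):
        err = None
        p = np.nan
        fc = np.nan
        try:
            p = t_test(xa[:, j], xb[:, j])
            fc = fold_change(xa[:, j], xb[:, j])
        except ValueError as exc:
            err = str(exc)
        passes = (
            err is None
            and p < p_threshold
            and np.isfinite(fc)
            and (fc > upper_fc or fc < lower_fc)
        )
        results.append(DifferentialResult(fid, float(p), float(fc), bool(passes), err))
    return results


def results_to_frame(
    results: list[DifferentialResult], expr: ExpressionMatrix | None = None
) -> pd.DataFrame:
    """Tabulate DE results; adds the feature class column when ``expr`` given."""
    df = pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "p_value": [r.p_value for r in results],
            "fold_change": [r.fold_change for r in results],
            "passes": [r.passes for r in results],
        }
    )
    if expr is not None:
        df.insert(1, "class", [expr.feature_class[r.feature_id] for r in results])
    return df


def passing_features(results: list[DifferentialResult]) -> list[str]:
    return [r.feature_id for r in results if r.passes]
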