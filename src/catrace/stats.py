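"""Group comparisons and quartile stratification.

Two-group metrics use the unpaired two-tailed t test; multi-group designs
use one-way ANOVA with Sidak-adjusted pairwise post hocs (or Tukey), or
two-way ANOVA for factorial designs. Values are summarized as mean +/- SEM.
The stratification rule splits a value vector at its quartiles into low/high
groups and removes 1.5xIQR outliers from each group afterwards.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError

__all__ = [
    "GroupComparison",
    "QuantileStrata",
    "compare_two_groups",
    "compare_multi_groups",
    "sidak_adjust",
    "stratify_quartiles",
]

ALPHA = 0.05


@dataclass
class GroupComparison:
    metric: str
    group_labels: list[str]
    n: list[int]
    means: list[float]
    sems: list[float]
    test: str
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None = field(default=None, repr=False)

    def summary_string(self) -> str:
        """Figure-legend style: group means +/- SEM and the P value."""
        parts = [
            f"{lbl}: {m:.3g} ± {s:.3g} (n={n})"
            for lbl, m, s, n in zip(self.group_labels, self.means, self.sems, self.n)
        ]
        return "; ".join(parts) + f"; {self.test}, P = {self.p_value:.3g}"

    def to_dict(self) -> dict:
        d = {
            "metric": self.metric, "group_labels": self.group_labels, "n": self.n,
            "means": self.means, "sems": self.sems, "test": self.test,
            "statistic": self.statistic, "p_value": self.p_value,
        }
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return d


def _clean(values: Sequence[float], label: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    if arr.size < min_n:
        raise StatsError(f"group '{label}' has n={arr.size} < {min_n} finite values")
    return arr


def _sem(a: np.ndarray) -> float:
    return float(a.std(ddof=1) / np.sqrt(a.size))


def compare_two_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    metric: str = "",
    labels: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Unpaired two-tailed t test with mean +/- SEM per group."""
    a = _clean(values_a, labels[0])
    b = _clean(values_b, labels[1])
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise StatsError("zero variance in both groups: t test undefined")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        metric=metric, group_labels=list(labels), n=[a.size, b.size],
        means=[float(a.mean()), float(b.mean())], sems=[_sem(a), _sem(b)],
        test="unpaired two-tailed t test", statistic=float(t), p_value=float(p),
    )


def sidak_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Sidak correction for m comparisons: p_adj = 1 - (1 - p)^m."""
    if m < 1:
        raise StatsError(f"number of comparisons must be >= 1, got {m}")
    return 1.0 - (1.0 - np.asarray(p)) ** m if np.ndim(p) else float(1.0 - (1.0 - p) ** m)


def _pairwise_sidak(groups: dict[str, np.ndarray],
                    contrasts: list[tuple[str, str]]) -> pd.DataFrame:
    m = len(contrasts)
    rows = []
    for la, lb in contrasts:
        t, p = sps.ttest_ind(groups[la], groups[lb], equal_var=True)
        rows.append({"group_a": la, "group_b": lb, "t": float(t),
                     "p_raw": float(p), "p_adj": sidak_adjust(float(p), m),
                     "method": "sidak"})
    return pd.DataFrame(rows)


def _pairwise_tukey(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    labels = list(groups)
    res = sps.tukey_hsd(*[groups[x] for x in labels])
    rows = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "t": float(res.statistic[i, j]),
                     "p_raw": float(res.pvalue[i, j]),
                     "p_adj": float(res.pvalue[i, j]),
                     "method": "tukey"})
    return pd.DataFrame(rows)


def compare_multi_groups(
    groups: dict[str, Sequence[float]],
    design: str = "one-way",
    posthoc: str = "sidak",
    metric: str = "",
    contrasts: list[tuple[str, str]] | None = None,
    factors: pd.DataFrame | None = None,
) -> GroupComparison:
    """ANOVA omnibus test with adjusted pairwise post hocs.

    ``design='one-way'``: ``groups`` maps label -> values; posthoc is
    'sidak' (pairwise t tests, Sidak-adjusted over the pre-specified
    ``contrasts``, default all pairs) or 'tukey'.

    ``design='two-way'``: ``factors`` must be a tidy frame with columns
    ``value``, ``factor_a``, ``factor_b``; all factorial cells must be
    present. The omnibus row reports the interaction F test; post hocs run
    across the factorial cells.
    """
    if design == "one-way":
        if len(groups) < 3:
            raise StatsError(f"one-way ANOVA needs >= 3 groups, got {len(groups)}")
        arrs = {k: _clean(v, k) for k, v in groups.items()}
        if all(a.var(ddof=1) == 0 for a in arrs.values()):
            raise StatsError("zero within-group variance in every group: ANOVA undefined")
        f, p = sps.f_oneway(*arrs.values())
        if posthoc == "sidak":
            pairs = contrasts or list(itertools.combinations(arrs, 2))
            table = _pairwise_sidak(arrs, pairs)
        elif posthoc == "tukey":
            table = _pairwise_tukey(arrs)
        else:
            raise StatsError(f"unknown posthoc '{posthoc}'")
        return GroupComparison(
            metric=metric, group_labels=list(arrs), n=[a.size for a in arrs.values()],
            means=[float(a.mean()) for a in arrs.values()],
            sems=[_sem(a) for a in arrs.values()],
            test=f"one-way ANOVA + {posthoc} post hoc",
            statistic=float(f), p_value=float(p), posthoc=table,
        )
    if design == "two-way":
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        if factors is None:
            raise StatsError("two-way design requires the tidy `factors` frame")
        req = {"value", "factor_a", "factor_b"}
        if not req.issubset(factors.columns):
            raise StatsError(f"factors frame must have columns {sorted(req)}")
        cells = factors.groupby(["factor_a", "factor_b"]).size()
        n_a = factors["factor_a"].nunique()
        n_b = factors["factor_b"].nunique()
        if len(cells) != n_a * n_b:
            raise StatsError("two-way ANOVA requires every factorial cell to be present")
        model = smf.ols("value ~ C(factor_a) * C(factor_b)", data=factors).fit()
        table = sm.stats.anova_lm(model, typ=2)
        inter = table.loc["C(factor_a):C(factor_b)"]
        cell_groups = {
            f"{a}|{b}": _clean(sub["value"], f"{a}|{b}")
            for (a, b), sub in factors.groupby(["factor_a", "factor_b"])
        }
        if posthoc == "tukey":
            ph = _pairwise_tukey(cell_groups)
        elif posthoc == "sidak":
            pairs = contrasts or list(itertools.combinations(cell_groups, 2))
            ph = _pairwise_sidak(cell_groups, pairs)
        else:
            raise StatsError(f"unknown posthoc '{posthoc}'")
        return GroupComparison(
            metric=metric, group_labels=list(cell_groups),
            n=[a.size for a in cell_groups.values()],
            means=[float(a.mean()) for a in cell_groups.values()],
            sems=[_sem(a) for a in cell_groups.values()],
            test=f"two-way ANOVA (interaction) + {posthoc} post hoc",
            statistic=float(inter["F"]), p_value=float(inter["PR(>F)"]), posthoc=ph,
        )
    raise StatsError(f"unknown design '{design}'")


@dataclass
class QuantileStrata:
    low_ids: list[Hashable]
    high_ids: list[Hashable]
    excluded_outlier_ids: list[Hashable]
    q1: float
    q3: float
    iqr: float
    quantile_method: str = "linear"


def stratify_quartiles(
    values: Sequence[float],
    ids: Sequence[Hashable] | None = None,
    quantile_method: str = "linear",
) -> QuantileStrata:
    """Split values into bottom-/top-quartile groups, then drop 1.5xIQR outliers.

    Q1/Q3 and the IQR come from the full vector (``quantile_method`` is the
    numpy interpolation; 'linear' is the common type-7 default). Ids with
    value <= Q1 form the low group, >= Q3 the high group; within each group,
    values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] are moved to
    ``excluded_outlier_ids``.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 8:
        raise StatsError(f"stratification needs >= 8 values, got {vals.size}")
    if not np.all(np.isfinite(vals)):
        raise StatsError("non-finite values cannot be stratified")
    if np.ptp(vals) == 0:
        raise StatsError("all values identical: quartiles are degenerate")
    if ids is None:
        ids = list(range(vals.size))
    ids = list(ids)
    if len(ids) != vals.size:
        raise StatsError("ids and values must have equal length")
    q1, q3 = np.quantile(vals, [0.25, 0.75], method=quantile_method)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    low, high, excluded = [], [], []
    for i, v in zip(ids, vals):
        if v <= q1:
            (excluded if (v < lo_fence or v > hi_fence) else low).append(i)
        elif v >= q3:
            (excluded if (v < lo_fence or v > hi_fence) else high).append(i)
    return QuantileStrata(low_ids=low, high_ids=high, excluded_outlier_ids=excluded,
                          q1=float(q1), q3=float(q3), iqr=float(iqr),
                          quantile_method=quantile_method)
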