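"""Cohort-level influence analysis and the statistical test-selection logic.

``loo_influence`` quantifies per-sample influence on a cohort statistic by
recomputing it with each sample left out in turn. Two statistics are exposed:
the plain cohort mean frequency (``mode="mean"``) and the High-minus-Low
group mean difference (``mode="group_difference"``, the default). In mean
mode the average of the n leave-one-out means equals the full-cohort mean
exactly (an algebraic identity).

``compare_two_groups`` applies the standard selection logic: Shapiro-Wilk
normality per group and Levene's test for equal variances; a two-sample
t-test when both pass, otherwise Mann-Whitney U. ``compare_multi_groups``
runs a Kruskal-Wallis omnibus test with BH-adjusted pairwise rank tests, and
``fisher_exact_2x2`` the exact test for 2x2 count tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio

from .cooccurrence import adjust_bh

__all__ = [
    "CohortTable",
    "LooResult",
    "GroupComparison",
    "MultiGroupComparison",
    "loo_influence",
    "rank_influence",
    "compare_two_groups",
    "compare_multi_groups",
    "fisher_exact_2x2",
]


@dataclass
class CohortTable:
    """Per-sample group membership (High/Low) and a frequency in [0, 1]."""

    sample_ids: np.ndarray
    groups: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.groups = np.asarray(self.groups, dtype=str)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        n = len(self.sample_ids)
        if len(self.groups) != n or len(self.frequencies) != n:
            raise ValueError("sample_ids, groups and frequencies must align")
        if len(np.unique(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if not set(np.unique(self.groups)) <= {"High", "Low"}:
            raise ValueError("groups must be 'High' or 'Low'")
        if ((self.frequencies < 0) | (self.frequencies > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "group": self.groups,
                "frequency": self.frequencies,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortTable":
        return cls(
            sample_ids=df["sample_id"].to_numpy(str),
            groups=df["group"].to_numpy(str),
            frequencies=df["frequency"].to_numpy(float),
        )


@dataclass
class LooResult:
    """Leave-one-out recomputation of a cohort statistic."""

    sample_ids: np.ndarray
    statistics: np.ndarray  # statistic with the sample left out
    deviations: np.ndarray  # loo statistic - full statistic (signed)
    full_statistic: float
    mode: str

    @property
    def abs_deviations(self) -> np.ndarray:
        return np.abs(self.deviations)

    def __len__(self) -> int:
        return len(self.sample_ids)


def _cohort_statistic(groups: np.ndarray, freqs: np.ndarray, mode: str) -> float:
    if mode == "mean":
        return float(freqs.mean())
    if mode == "group_difference":
        high, low = freqs[groups == "High"], freqs[groups == "Low"]
        if len(high) == 0 or len(low) == 0:
            raise ValueError("both groups must be nonempty")
        return float(high.mean() - low.mean())
    raise ValueError(f"unknown mode {mode!r}")


def loo_influence(cohort: CohortTable, mode: str = "group_difference") -> LooResult:
    """Recompute the cohort statistic once per left-out sample.

    ``mode="mean"``: statistic is the mean frequency. ``mode=
    "group_difference"``: High-group mean minus Low-group mean (each group
    needs >= 2 samples so no removal empties a group). Deviations are
    recorded signed (leave-one-out minus full) and as absolute values.
    """
    n = len(cohort)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    if mode == "group_difference":
        for g in ("High", "Low"):
            if np.sum(cohort.groups == g) < 2:
                raise ValueError(
                    f"group {g!r} needs >= 2 samples so no removal empties it"
                )
    full = _cohort_statistic(cohort.groups, cohort.frequencies, mode)
    stats_ = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        stats_[i] = _cohort_statistic(
            cohort.groups[keep], cohort.frequencies[keep], mode
        )
    return LooResult(
        sample_ids=cohort.sample_ids.copy(),
        statistics=stats_,
        deviations=stats_ - full,
        full_statistic=full,
        mode=mode,
    )


def rank_influence(loo: LooResult) -> pd.DataFrame:
    """Samples ordered by absolute deviation (descending), ties by sample id."""
    df = pd.DataFrame(
        {
            "sample_id": loo.sample_ids,
            "loo_statistic": loo.statistics,
            "deviation": loo.deviations,
            "abs_deviation": loo.abs_deviations,
        }
    )
    return df.sort_values(
        ["abs_deviation", "sample_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


@dataclass
class GroupComparison:
    """Two-group comparison with the assumption checks that selected the test."""

    test: str  # "t-test" or "mann-whitney"
    statistic: float
    pvalue: float
    shapiro_p: tuple
    levene_p: float | None


def _normality_p(x: np.ndarray) -> float:
    # A constant group has no normal fit; treat as a rejection.
    if np.ptp(x) == 0:
        return 0.0
    return float(stats.shapiro(x).pvalue)


def compare_two_groups(
    values, groups, alpha_assumptions: float = 0.05
) -> GroupComparison:
    """t-test when both groups pass normality and variance checks, else Mann-Whitney U.

    Shapiro-Wilk per group and Levene's test (mean-centred) across groups at
    ``alpha_assumptions``. A group with fewer than 3 samples cannot support
    the normality check: the comparison falls back to Mann-Whitney with a
    warning. Two identical groups report p = 1 on the rank-test path
    (all-ties convention).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=str)
    names = np.unique(groups)
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(names)}")
    x, y = values[groups == names[0]], values[groups == names[1]]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")

    if np.ptp(values) == 0:  # all observations tied across both groups
        return GroupComparison(
            test="mann-whitney",
            statistic=float(len(x) * len(y) / 2.0),
            pvalue=1.0,
            shapiro_p=(np.nan, np.nan),
            levene_p=None,
        )

    if min(len(x), len(y)) < 3:
        warnings.warn(
            "a group has fewer than 3 samples; falling back to Mann-Whitney",
            stacklevel=2,
        )
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        return GroupComparison(
            test="mann-whitney",
            statistic=float(res.statistic),
            pvalue=float(res.pvalue),
            shapiro_p=(np.nan, np.nan),
            levene_p=None,
        )

    sw = (_normality_p(x), _normality_p(y))
    lev = float(stats.levene(x, y, center="mean").pvalue)
    normal = sw[0] > alpha_assumptions and sw[1] > alpha_assumptions
    homoscedastic = lev > alpha_assumptions
    if normal and homoscedastic:
        res = stats.ttest_ind(x, y, equal_var=True)
        test = "t-test"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        test = "mann-whitney"
    return GroupComparison(
        test=test,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        shapiro_p=sw,
        levene_p=lev,
    )


@dataclass
class MultiGroupComparison:
    """Kruskal-Wallis omnibus result with BH-adjusted pairwise rank tests."""

    statistic: float
    pvalue: float
    pairwise: pd.DataFrame  # columns: group1, group2, statistic, pvalue, qvalue


def compare_multi_groups(values, groups) -> MultiGroupComparison:
    """Kruskal-Wallis across >= 3 groups plus BH-adjusted pairwise Mann-Whitney."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=str)
    names = sorted(np.unique(groups))
    if len(names) < 3:
        raise ValueError("need at least 3 groups")
    samples = [values[groups == g] for g in names]
    if np.ptp(values) == 0:
        omnibus_stat, omnibus_p = 0.0, 1.0
    else:
        res = stats.kruskal(*samples)
        omnibus_stat, omnibus_p = float(res.statistic), float(res.pvalue)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            xi, xj = samples[i], samples[j]
            if np.ptp(np.concatenate([xi, xj])) == 0:
                stat, p = float(len(xi) * len(xj) / 2.0), 1.0
            else:
                r = stats.mannwhitneyu(xi, xj, alternative="two-sided")
                stat, p = float(r.statistic), float(r.pvalue)
            rows.append((names[i], names[j], stat, p))
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "statistic", "pvalue"])
    pairwise["qvalue"] = adjust_bh(pairwise["pvalue"].to_numpy())
    return MultiGroupComparison(
        statistic=omnibus_stat, pvalue=omnibus_p, pairwise=pairwise
    )


def fisher_exact_2x2(table) -> tuple:
    """Two-sided Fisher exact p and conditional-MLE odds ratio for a 2x2 table."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)) or (table < 0).any():
            raise ValueError("counts must be nonnegative integers")
        table = np.round(table).astype(int)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    orr = odds_ratio(table, kind="conditional").statistic
    return float(orr), float(p)
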