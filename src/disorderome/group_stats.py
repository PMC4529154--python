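"""Nonparametric comparison of disorder content across organism groups.

The decision flow mirrors common practice for small, unequal groups of
proteome-level percentages:

1. Brown-Forsythe Levene test (median-centred) for homogeneity of
   variances across all groups.
2. If variances are homogeneous (p >= alpha): Kruskal-Wallis across all
   groups.  No rejection ends the analysis; a rejection triggers the
   pairwise stage.
3. If the overall Levene test rejects, the pairwise stage is entered
   directly.  For every unordered pair of groups a pairwise Levene test
   is run first; only pairs whose variance-homogeneity null is accepted
   receive a two-sample Wilcoxon rank test, marked ``*`` for p < 0.05
   and ``**`` for p < 0.005.

The "Wilcoxon" comparison defaults to the two-sample rank-sum
(Mann-Whitney U) test since the groups are unpaired and of unequal size;
a paired signed-rank variant is available when pairing is explicit and
group sizes match.  No multiple-testing correction is applied by default
(an optional Holm adjustment is available), and the flow contains no
internal randomness: identical input yields identical branches and marks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

ALPHA = 0.05
STRONG_ALPHA = 0.005

BRANCH_KW_OVERALL = "kw_overall"
BRANCH_PAIRWISE_AFTER_LEVENE_FAIL = "pairwise_after_levene_fail"
BRANCH_PAIRWISE_AFTER_KW_REJECT = "pairwise_after_kw_reject"


class DegenerateDataError(ValueError):
    """Raised when a test is undefined on the input (e.g. zero spread everywhere)."""


def _validate_groups(groups: Mapping[str, Sequence[float]], min_groups: int = 2) -> dict[str, np.ndarray]:
    if len(groups) < min_groups:
        raise ValueError(f"need >= {min_groups} groups, got {len(groups)}")
    out = {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError(
                f"group {label!r} has {arr.size} value(s); groups of fewer than two "
                "samples must be removed before testing (see organisms.group_by)"
            )
        out[label] = arr
    return out


def levene_bf(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Brown-Forsythe Levene test (median-centred) for equal variances."""
    arrays = list(_validate_groups(groups).values())
    if all(np.ptp(a) == 0 for a in arrays):
        raise DegenerateDataError("all groups have zero spread; variance test undefined")
    statistic, p = stats.levene(*arrays, center="median")
    if np.isnan(statistic) or np.isnan(p):
        raise DegenerateDataError("Levene statistic undefined on this input")
    return float(statistic), float(p)


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H test with tie correction (chi-square p-value)."""
    arrays = list(_validate_groups(groups).values())
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            statistic, p = stats.kruskal(*arrays)
    except ValueError:
        statistic, p = np.nan, np.nan
    if np.isnan(statistic) or np.isnan(p):
        # every observation identical: trivially no evidence against
        # identical distributions
        return 0.0, 1.0
    return float(statistic), float(p)


def _rank_test(x: np.ndarray, y: np.ndarray, paired: bool) -> float:
    if paired:
        if x.size != y.size:
            raise ValueError("paired comparison requires equal group sizes")
        diffs = x - y
        if np.all(diffs == 0):
            return 1.0
        return float(stats.wilcoxon(x, y).pvalue)
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.pvalue)


def pairwise_wilcoxon(
    groups: Mapping[str, Sequence[float]],
    paired: bool = False,
) -> list[tuple[tuple[str, str], float]]:
    """Two-sample Wilcoxon rank test p-value for every unordered pair.

    Uses the exact null distribution for small tie-free samples and the
    normal approximation with tie correction otherwise (scipy's policy).
    """
    arrays = _validate_groups(groups)
    out = []
    for g1, g2 in combinations(sorted(arrays), 2):
        out.append(((g1, g2), _rank_test(arrays[g1], arrays[g2], paired)))
    return out


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (optional; the default flow applies none)."""
    order = np.argsort(pvalues)
    m = len(pvalues)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


@dataclass(frozen=True)
class PairResult:
    group1: str
    group2: str
    levene_p: float
    wilcoxon_p: float | None
    mark: str

    def __post_init__(self) -> None:
        if self.mark not in ("", "*", "**"):
            raise ValueError(f"invalid mark {self.mark!r}")


@dataclass
class GroupComparisonResult:
    """Outcome of the full decision flow for one grouping and metric."""

    grouping_key: str
    metric: str
    alpha: float
    overall_levene: tuple[float, float]
    branch: str
    overall_kw: tuple[float, float] | None = None
    pairwise: list[PairResult] = field(default_factory=list)
    group_medians: dict[str, float] = field(default_factory=dict)

    @property
    def marks(self) -> dict[tuple[str, str], str]:
        return {(p.group1, p.group2): p.mark for p in self.pairwise if p.mark}


def _mark(p: float, alpha: float) -> str:
    if p < STRONG_ALPHA:
        return "**"
    if p < alpha:
        return "*"
    return ""


def decision_flow(
    groups: Mapping[str, Sequence[float]],
    alpha: float = ALPHA,
    grouping_key: str = "habitat",
    metric: str = "long30",
    paired: bool = False,
) -> GroupComparisonResult:
    """Run the Levene -> Kruskal-Wallis -> pairwise Wilcoxon decision flow.

    ``groups`` maps a group label to the raw disorder metric of each of
    its organisms (groups must already be filtered to size >= 2).  Group
    medians are reported as the summary location of each group.
    """
    arrays = _validate_groups(groups)
    medians = {label: float(np.median(a)) for label, a in arrays.items()}
    lev_stat, lev_p = levene_bf(arrays)
    result = GroupComparisonResult(
        grouping_key=grouping_key,
        metric=metric,
        alpha=alpha,
        overall_levene=(lev_stat, lev_p),
        branch=BRANCH_KW_OVERALL,
        group_medians=medians,
    )

    if lev_p >= alpha:
        kw = kruskal_wallis(arrays)
        result.overall_kw = kw
        if kw[1] >= alpha:
            return result
        result.branch = BRANCH_PAIRWISE_AFTER_KW_REJECT
    else:
        result.branch = BRANCH_PAIRWISE_AFTER_LEVENE_FAIL

    for g1, g2 in combinations(sorted(arrays), 2):
        pair = {g1: arrays[g1], g2: arrays[g2]}
        try:
            _, pair_lev_p = levene_bf(pair)
        except DegenerateDataError:
            # no spread in either group: variances trivially equal
            pair_lev_p = 1.0
        if pair_lev_p >= alpha:
            wp = _rank_test(arrays[g1], arrays[g2], paired)
            result.pairwise.append(PairResult(g1, g2, pair_lev_p, wp, _mark(wp, alpha)))
        else:
            result.pairwise.append(PairResult(g1, g2, pair_lev_p, None, ""))
    return result


def result_to_rows(result: GroupComparisonResult) -> list[dict[str, object]]:
    """Flatten a comparison result into TSV-ready rows (one per pair)."""
    rows: list[dict[str, object]] = []
    for pair in result.pairwise:
        rows.append(
            {
                "grouping_key": result.grouping_key,
                "metric": result.metric,
                "pair": f"{pair.group1}|{pair.group2}",
                "branch": result.branch,
                "levene_p": pair.levene_p,
                "wilcoxon_p": pair.wilcoxon_p,
                "mark": pair.mark,
            }
        )
    if not rows:
        kw_p = result.overall_kw[1] if result.overall_kw else None
        rows.append(
            {
                "grouping_key": result.grouping_key,
                "metric": result.metric,
                "pair": "(overall)",
                "branch": result.branch,
                "levene_p": result.overall_levene[1],
                "wilcoxon_p": kw_p,
                "mark": "",
            }
        )
    return rows
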