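"""Group-comparison statistics for morphometry and color features.

Two-group comparisons use the Mann-Whitney U test (exact enumeration for
small tie-free samples, normal approximation with tie correction otherwise);
multi-group comparisons use one-way ANOVA with Tukey's honest significant
difference for pairwise follow-up. All alternatives are two-sided. An optional
Holm adjustment is available for multi-feature panels.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "ZeroVarianceError",
    "mann_whitney_u",
    "anova_oneway",
    "tukey_hsd",
    "holm_adjust",
]


class ZeroVarianceError(ValueError):
    """All observations identical: the test statistic is undefined."""


@dataclass
class GroupComparison:
    """Result of one statistical comparison between groups."""

    test: str
    statistic: float
    p_value: float
    groups: tuple = ()
    significant: bool | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def mann_whitney_u(a, b, alternative: str = "two-sided") -> GroupComparison:
    """Mann-Whitney U test with midrank tie handling.

    Uses the exact null distribution when the combined sample size is at most
    12 and there are no ties, and the tie-corrected normal approximation (with
    continuity correction) otherwise. The statistic reported is U of the first
    sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return GroupComparison(
        test="mann_whitney_u", statistic=float(res.statistic), p_value=float(res.pvalue)
    )


def anova_oneway(groups: list) -> GroupComparison:
    """One-way ANOVA F test across two or more groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least two values")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ZeroVarianceError("all observations identical; F undefined")
    res = sps.f_oneway(*groups)
    return GroupComparison(
        test="anova_oneway", statistic=float(res.statistic), p_value=float(res.pvalue)
    )


def tukey_hsd(groups: list, alpha: float = 0.05, labels: list | None = None) -> list[GroupComparison]:
    """Tukey HSD pairwise comparisons (studentized-range adjusted p-values).

    Returns g*(g-1)/2 comparisons; ``significant`` marks adjusted p < alpha.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least two values")
    if np.ptp(np.concatenate(groups)) == 0:
        raise ZeroVarianceError("all observations identical; HSD undefined")
    if labels is None:
        labels = list(range(len(groups)))
    res = sps.tukey_hsd(*groups)
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p = float(res.pvalue[i, j])
            out.append(
                GroupComparison(
                    test="tukey_hsd",
                    statistic=float(res.statistic[i, j]),
                    p_value=min(max(p, 0.0), 1.0),
                    groups=(labels[i], labels[j]),
                    significant=p < alpha,
                )
            )
    return out


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()
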