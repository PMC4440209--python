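"""Across-intensity group comparisons: one-way ANOVA with SNK post hoc.

Each measured variable is compared across the four effort intensities by
classical one-way ANOVA; when groups differ, the Student-Newman-Keuls
(SNK) stepwise procedure on the ordered group means identifies which
pairs differ, using studentized-range critical values whose span (number
of means covered) shrinks from the outside in. Group annotations follow
the sports-science table convention: a group is marked "a" when it
differs from group 1, "b" from group 2, "c" from group 3, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "anova_oneway", "snk_posthoc", "compare_variable"]


@dataclass(frozen=True)
class GroupComparison:
    """ANOVA + post-hoc summary for one variable across intensity groups."""

    variable: str
    F_statistic: float
    p_value: float
    different_pairs: frozenset[tuple[int, int]]  # 0-based group indices, i < j
    posthoc_letters: tuple[str, ...]  # one annotation string per group

    def differs(self, i: int, j: int) -> bool:
        a, b = sorted((i, j))
        return (a, b) in self.different_pairs


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA: F = (SSB/(k-1)) / (SSW/(N-k)).

    Returns ``(F, p)`` against the F(k-1, N-k) reference distribution.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.ndim != 1 or a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0.0:
        if ssb == 0.0:
            raise ValueError(
                "degenerate ANOVA: zero within-group variance and equal means"
            )
        return float("inf"), 0.0
    f_stat = (ssb / (k - 1)) / (ssw / (n_total - k))
    p = float(sps.f.sf(f_stat, k - 1, n_total - k))
    return float(f_stat), p


def _harmonic_mean_n(sizes: Sequence[int]) -> float:
    sizes = np.asarray(sizes, dtype=float)
    return len(sizes) / (1.0 / sizes).sum()


def snk_posthoc(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> tuple[frozenset[tuple[int, int]], tuple[str, ...]]:
    """Student-Newman-Keuls stepwise comparison of group means.

    Group means are ordered; the widest span is tested first with the
    studentized-range critical value q(alpha, span, df_within). A span
    found non-significant seals every pair inside it; a significant span
    declares its extreme pair different and opens its two sub-spans.
    Unbalanced designs use the harmonic mean group size.

    Returns the symmetric set of different pairs (as sorted 0-based index
    tuples) and per-group annotation letters ("a" = differs from group 1,
    "b" = from group 2, ...).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df_within = n_total - k
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_within
    n_h = _harmonic_mean_n([a.size for a in arrays])

    means = np.array([a.mean() for a in arrays])
    order = np.argsort(means, kind="stable")  # ascending; ties broken by index
    sorted_means = means[order]
    se = np.sqrt(msw / n_h)

    different: set[tuple[int, int]] = set()
    if se == 0.0:
        # No within-group variance: any mean difference is a difference.
        for i in range(k):
            for j in range(i + 1, k):
                if means[i] != means[j]:
                    different.add((i, j))
    else:
        tested: dict[tuple[int, int], bool] = {}

        def test_span(lo: int, hi: int) -> None:
            span = hi - lo + 1
            if span < 2:
                return
            if (lo, hi) in tested:
                return
            q_obs = (sorted_means[hi] - sorted_means[lo]) / se
            q_crit = sps.studentized_range.ppf(1 - alpha, span, df_within)
            significant = bool(q_obs > q_crit)
            tested[(lo, hi)] = significant
            if significant:
                pair = tuple(sorted((int(order[lo]), int(order[hi]))))
                different.add(pair)
                test_span(lo, hi - 1)
                test_span(lo + 1, hi)

        test_span(0, k - 1)

    letters = tuple(
        "".join(
            chr(ord("a") + j)
            for j in range(k)
            if j != i and tuple(sorted((i, j))) in different
        )
        for i in range(k)
    )
    return frozenset(different), letters


def compare_variable(
    variable: str, groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> GroupComparison:
    """ANOVA plus SNK for one variable; post hoc only runs after rejection."""
    f_stat, p = anova_oneway(groups)
    if p < alpha:
        pairs, letters = snk_posthoc(groups, alpha)
    else:
        pairs, letters = frozenset(), tuple("" for _ in groups)
    return GroupComparison(variable, f_stat, p, pairs, letters)


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tabular view of per-variable comparisons (one row per variable)."""
    rows = []
    for c in comparisons:
        row = {"variable": c.variable, "F": c.F_statistic, "p": c.p_value}
        for i, letters in enumerate(c.posthoc_letters):
            row[f"group{i + 1}_letters"] = letters
        rows.append(row)
    return pd.DataFrame(rows)
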