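"""Group comparisons: one-way ANOVA plus Tukey HSD letter display.

Used to compare stomatal size and lg(R_gc/nge) across taxonomic groups
(pteridophytes / gymnosperms / angiosperms, or the angiosperm subgroups).
The post-hoc procedure is Tukey's honestly-significant-difference test;
groups sharing a letter are not significantly different at the chosen
alpha.  Letters come from the standard insert-and-absorb display
algorithm applied to the pairwise significance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["AnovaResult", "one_way_anova", "posthoc_letters"]


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_means: Dict[str, float]
    group_n: Dict[str, int]
    posthoc_letters: Optional[Dict[str, str]] = None
    posthoc_method: str = "tukey_hsd"


def _split_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = list(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    by_group: Dict[str, list] = {}
    for v, g in zip(values, groups):
        by_group.setdefault(str(g), []).append(float(v))
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    for g, vals in by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    return {g: np.array(v) for g, v in by_group.items()}


def one_way_anova(values, groups, posthoc: bool = True, alpha: float = 0.05) -> AnovaResult:
    """Classical one-way ANOVA across labeled groups.

    F = (SSB/df_between) / (SSW/df_within) with the p-value from the F
    distribution; optionally attaches Tukey HSD grouping letters.
    """
    by_group = _split_groups(values, groups)
    if all(np.ptp(v) == 0 for v in by_group.values()):
        raise ValueError("degenerate data: zero within-group variance everywhere")
    f_stat, p_value = stats.f_oneway(*by_group.values())
    n_total = sum(len(v) for v in by_group.values())
    result = AnovaResult(
        f_stat=float(f_stat),
        df_between=len(by_group) - 1,
        df_within=n_total - len(by_group),
        p_value=float(p_value),
        group_means={g: float(np.mean(v)) for g, v in by_group.items()},
        group_n={g: len(v) for g, v in by_group.items()},
        posthoc_letters=posthoc_letters(values, groups, alpha) if posthoc else None,
    )
    return result


def tukey_pairwise(values, groups, alpha: float = 0.05):
    """Tukey HSD pairwise comparisons; returns ({(g1, g2): p}, {(g1, g2): reject})."""
    by_group = _split_groups(values, groups)
    res = pairwise_tukeyhsd(
        np.asarray(values, dtype=float),
        np.asarray([str(g) for g in groups]),
        alpha=alpha,
    )
    pvals, reject = {}, {}
    table = res.summary().data[1:]
    for row, p, rej in zip(table, res.pvalues, res.reject):
        key = (str(row[0]), str(row[1]))
        pvals[key] = float(p)
        reject[key] = bool(rej)
    # sanity: every unordered pair covered
    assert len(pvals) == len(by_group) * (len(by_group) - 1) // 2
    return pvals, reject


def posthoc_letters(values, groups, alpha: float = 0.05) -> Dict[str, str]:
    """Compact letter display from Tukey HSD pairwise tests.

    Groups are ordered by descending mean; letters are assigned with the
    insert-and-absorb algorithm so that two groups share a letter iff
    their pairwise difference is not significant at ``alpha``.
    """
    by_group = _split_groups(values, groups)
    _, reject = tukey_pairwise(values, groups, alpha)

    def significant(g1, g2):
        return reject.get((g1, g2), reject.get((g2, g1), False))

    ordered = sorted(by_group, key=lambda g: -np.mean(by_group[g]))
    # insert-and-absorb: columns are candidate letters (sets of groups)
    columns = [set(ordered)]
    for i, g1 in enumerate(ordered):
        for g2 in ordered[i + 1 :]:
            if not significant(g1, g2):
                continue
            for col in [c for c in columns if g1 in c and g2 in c]:
                columns.remove(col)
                columns.append(col - {g1})
                columns.append(col - {g2})
            # absorb columns that became subsets of others
            columns = [
                c
                for c in columns
                if c and not any(c < other for other in columns if other is not c)
            ]
    # deduplicate while keeping a stable order (by best-ranked member)
    uniq = []
    for col in sorted(columns, key=lambda c: min(ordered.index(g) for g in c)):
        if col not in uniq:
            uniq.append(col)
    letters = {g: "" for g in ordered}
    for letter_idx, col in enumerate(uniq):
        letter = chr(ord("a") + letter_idx)
        for g in ordered:
            if g in col:
                letters[g] += letter
    return letters
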