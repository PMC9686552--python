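"""Two-sample comparisons of milk-composition traits from summary statistics
(mean +/- SD, n) or raw values, with significance marks.

Both the pooled-variance Student variant (default) and the Welch variant are
provided.  The "+/-" values in source tables are treated as standard
deviations (configurable upstream by converting SEM -> SD before calling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class StatsError(ValueError):
    pass


@dataclass
class GroupSummary:
    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise StatsError(f"{self.label}: sd must be >= 0")
        if self.n < 2:
            raise StatsError(f"{self.label}: n must be >= 2")


@dataclass
class ComparisonRow:
    trait: str
    group_a: GroupSummary
    group_b: GroupSummary
    t: float
    df: float
    p_value: float
    mark: str  # "**" (p<0.01), "*" (p<0.05), ""
    degenerate: bool = False


def summarize(label: str, values) -> GroupSummary:
    values = np.asarray(values, dtype=float)
    return GroupSummary(label, float(values.mean()), float(values.std(ddof=1)),
                        int(values.size))


def t_from_summary(a: GroupSummary, b: GroupSummary, variant: str = "student"):
    """Two-sided two-sample t-test from summary statistics.

    Returns ``(t, df, p, degenerate)``.  When both SDs are zero: equal means
    give (0, df, 1); unequal means give p = 0 with the degenerate flag.
    """
    va, vb = a.sd ** 2, b.sd ** 2
    if va == 0.0 and vb == 0.0:
        df = float(a.n + b.n - 2)
        if a.mean == b.mean:
            return 0.0, df, 1.0, False
        return float("inf") if a.mean > b.mean else float("-inf"), df, 0.0, True
    if variant == "student":
        df = float(a.n + b.n - 2)
        pooled = ((a.n - 1) * va + (b.n - 1) * vb) / df
        se = np.sqrt(pooled * (1.0 / a.n + 1.0 / b.n))
    elif variant == "welch":
        term_a, term_b = va / a.n, vb / b.n
        se = np.sqrt(term_a + term_b)
        df = (term_a + term_b) ** 2 / (
            term_a ** 2 / (a.n - 1) + term_b ** 2 / (b.n - 1)
        )
    else:
        raise StatsError(f"unknown variant {variant!r}")
    t = (a.mean - b.mean) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), float(df), p, False


def significance_mark(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_table(traits: dict[str, tuple[GroupSummary, GroupSummary]],
                  variant: str = "student") -> list[ComparisonRow]:
    """One comparison row per trait, in input order."""
    rows = []
    for trait, groups in traits.items():
        if len(groups) != 2 or groups[0] is None or groups[1] is None:
            raise StatsError(f"trait {trait!r}: need exactly two group summaries")
        a, b = groups
        t, df, p, degenerate = t_from_summary(a, b, variant)
        rows.append(ComparisonRow(trait, a, b, t, df, p, significance_mark(p),
                                  degenerate))
    return rows


def table_rows(rows: list[ComparisonRow]) -> list[dict]:
    return [{"trait": r.trait,
             "group_a": r.group_a.label, "mean_a": r.group_a.mean,
             "sd_a": r.group_a.sd, "n_a": r.group_a.n,
             "group_b": r.group_b.label, "mean_b": r.group_b.mean,
             "sd_b": r.group_b.sd, "n_b": r.group_b.n,
             "t": r.t, "df": r.df, "p_value": r.p_value, "mark": r.mark}
            for r in rows]
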