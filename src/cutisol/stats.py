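"""Association tests: contingency chi-square and one-/two-way ANOVA.

The chi-square test is the plain Pearson statistic without continuity
correction.  The two-way ANOVA uses Type III sums of squares with
sum-to-zero contrasts on unbalanced data (the SAS PROC GLM default
behaviour), via statsmodels.  Degenerate inputs follow explicit
contracts: a zero within-group mean square with a positive between-group
mean square is reported as an infinite F with a p -> 0 sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

#: Smallest positive p-value reported for degenerate (F = inf) cases; keeps
#: the p in (0, 1] contract while signalling p -> 0.
P_SENTINEL = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class ContingencyTable:
    rows: tuple[str, ...]
    cols: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (len(self.rows), len(self.cols)):
            raise ValueError("counts shape does not match labels")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ContingencyTable":
        return cls(
            rows=tuple(str(i) for i in df.index),
            cols=tuple(str(c) for c in df.columns),
            counts=tuple(tuple(int(v) for v in row) for row in df.values),
        )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    @property
    def grand_total(self) -> float:
        return float(self.array.sum())

    @property
    def expected(self) -> np.ndarray:
        arr = self.array
        total = arr.sum()
        return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / total


@dataclass(frozen=True)
class AssociationResult:
    kind: str  # chi_square | anova_oneway | anova_twoway_interaction
    statistic: float
    df: tuple[int, ...]
    p_value: float
    effect: pd.DataFrame | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        assert self.statistic >= 0
        assert 0 < self.p_value <= 1


def expected_count(table: ContingencyTable, row: int, col: int) -> float:
    """rowTotal x colTotal / grandTotal for one cell."""
    if table.grand_total == 0:
        raise ValueError("all-zero contingency table")
    return float(table.expected[row, col])


def chi_square(table: ContingencyTable) -> AssociationResult:
    """Pearson chi-square on an r x c table, no continuity correction.

    Requires at least a 2 x 2 table with a positive grand total.  A warning
    is attached when any expected count is below 5.
    """
    arr = table.array
    if arr.sum() == 0:
        raise ValueError("all-zero contingency table")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("chi-square needs at least 2 rows and 2 columns")
    stat, p, dof, expected = scipy.stats.chi2_contingency(arr, correction=False)
    warning = None
    if (expected < 5).any():
        n_low = int((expected < 5).sum())
        warning = f"{n_low} cell(s) with expected count < 5"
    return AssociationResult(
        kind="chi_square",
        statistic=float(stat),
        df=(int(dof),),
        p_value=max(float(p), P_SENTINEL),
        effect=pd.DataFrame(expected, index=table.rows, columns=table.cols),
        warning=warning,
    )


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> AssociationResult:
    """One-way ANOVA F = MS_between / MS_within.

    With all within-group variance zero and distinct group means the F is
    infinite; the result then carries ``statistic = inf`` and the p -> 0
    sentinel.  Identical data in every group give F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    values = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(len(v) == 0 for v in values):
        raise ValueError("every group needs at least one value")
    n_total = sum(len(v) for v in values)
    k = len(values)
    df_between, df_within = k - 1, n_total - k
    if df_within <= 0:
        raise ValueError("residual df = 0 for the group term")
    grand = np.concatenate(values).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    if ss_within == 0:
        if ss_between == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = float("inf"), P_SENTINEL
    else:
        stat = (ss_between / df_between) / (ss_within / df_within)
        p = float(scipy.stats.f.sf(stat, df_between, df_within))
        p = max(p, P_SENTINEL)
    effect = pd.DataFrame(
        {
            "sum_sq": [ss_between, ss_within],
            "df": [df_between, df_within],
        },
        index=["between", "within"],
    )
    return AssociationResult(
        kind="anova_oneway",
        statistic=float(stat),
        df=(df_between, df_within),
        p_value=float(p),
        effect=effect,
    )


def anova_twoway(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    interaction: bool = True,
) -> dict[str, AssociationResult]:
    """Two-way crossed ANOVA with Type III sums of squares.

    Sum-to-zero contrasts make the Type III decomposition meaningful on
    unbalanced data.  Returns one result per model term (main effects and,
    if requested, the interaction).  A term without residual degrees of
    freedom is an error naming the term.
    """
    df = pd.DataFrame(
        {
            "y": pd.to_numeric(data[response]),
            "a": data[factor_a].astype(str),
            "b": data[factor_b].astype(str),
        }
    ).dropna()
    op = "*" if interaction else "+"
    model = ols(f"y ~ C(a, Sum) {op} C(b, Sum)", data=df).fit()
    if model.df_resid <= 0:
        raise ValueError(
            f"residual df = 0 for the model {factor_a} {op} {factor_b}"
        )
    table = anova_lm(model, typ=3)
    name_map = {
        "C(a, Sum)": factor_a,
        "C(b, Sum)": factor_b,
        "C(a, Sum):C(b, Sum)": f"{factor_a}:{factor_b}",
    }
    results: dict[str, AssociationResult] = {}
    df_resid = int(table.loc["Residual", "df"])
    ss_resid = float(table.loc["Residual", "sum_sq"])
    for term, label in name_map.items():
        if term not in table.index:
            continue
        row = table.loc[term]
        stat, p = float(row["F"]), float(row["PR(>F)"])
        if not np.isfinite(stat):
            # zero residual SS with a non-zero term SS
            stat, p = float("inf"), P_SENTINEL
        if np.isnan(p):
            if ss_resid == 0 and float(row["sum_sq"]) > 0:
                stat, p = float("inf"), P_SENTINEL
            else:
                stat, p = 0.0, 1.0
        kind = (
            "anova_twoway_interaction" if ":" in label else "anova_twoway"
        )
        results[label] = AssociationResult(
            kind=kind,
            statistic=stat,
            df=(int(row["df"]), df_resid),
            p_value=max(min(p, 1.0), P_SENTINEL),
            effect=table.drop(columns=[], errors="ignore"),
        )
    return results
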