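"""Genotype-comparison statistics: one-way ANOVA, Tukey HSD, letter display.

Phenotype measurements (starch content, amylose, granule metrics, ...)
are compared across genotypes with a classical one-way ANOVA followed
by Tukey's honestly-significant-difference post hoc test; unbalanced
designs use the Tukey–Kramer correction.  Groups are summarised by a
compact letter display: any two groups sharing a letter are not
significantly different at the chosen alpha.

Letters are assigned with the insert-and-absorb algorithm, ordering
groups by descending mean so the highest-mean group carries "a".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

__all__ = ["GroupComparison", "anova_tukey", "compact_letters"]


@dataclass(frozen=True)
class GroupComparison:
    """ANOVA + Tukey results for a set of labelled replicate groups."""

    groups: tuple[str, ...]
    n: pd.Series
    means: pd.Series
    sem: pd.Series
    f_statistic: float
    p_value: float
    pairwise_p: pd.DataFrame
    alpha: float

    def letters(self, alpha: float | None = None) -> dict[str, str]:
        """Compact letter display at ``alpha`` (defaults to the fit alpha)."""
        return compact_letters(
            self.pairwise_p, self.means, alpha=self.alpha if alpha is None else alpha
        )

    def summary(self) -> pd.DataFrame:
        letters = self.letters()
        return pd.DataFrame(
            {
                "n": self.n,
                "mean": self.means,
                "sem": self.sem,
                "letters": [letters[g] for g in self.groups],
            },
            index=list(self.groups),
        )


def _coerce_groups(
    data: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> dict[str, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        if not {"group", "value"}.issubset(data.columns):
            raise ValidationError("long-format data needs 'group' and 'value' columns")
        data = {
            str(g): sub["value"].to_numpy(float) for g, sub in data.groupby("group", sort=False)
        }
    out = {}
    for name, values in data.items():
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValidationError(f"group {name!r} needs >= 2 replicates for ANOVA")
        if np.any(~np.isfinite(arr)):
            raise ValidationError(f"group {name!r} contains non-finite values")
        out[str(name)] = arr
    if len(out) < 2:
        raise ValidationError("need at least 2 groups")
    return out


def anova_tukey(
    data: Mapping[str, Sequence[float]] | pd.DataFrame, alpha: float = 0.05
) -> GroupComparison:
    """One-way ANOVA F test plus Tukey HSD pairwise p-values.

    ``data`` is either a ``{group: replicate values}`` mapping or a
    long-format DataFrame with ``group``/``value`` columns.  Unbalanced
    group sizes are handled with the Tukey–Kramer studentized-range
    statistic.
    """
    groups = _coerce_groups(data)
    names = tuple(groups)
    samples = [groups[g] for g in names]
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate all-identical input is mapped to F=0, p=1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        f_stat, p_val = stats.f_oneway(*samples)
        tukey = stats.tukey_hsd(*samples)
    if not np.isfinite(f_stat):  # all observations identical
        f_stat, p_val = 0.0, 1.0
    pmat = np.asarray(tukey.pvalue, dtype=float)
    # zero within-group variance with equal means yields nan: no difference
    pmat[np.isnan(pmat)] = 1.0
    np.fill_diagonal(pmat, 1.0)
    pairwise = pd.DataFrame(pmat, index=list(names), columns=list(names))
    means = pd.Series({g: groups[g].mean() for g in names})
    sem = pd.Series({g: groups[g].std(ddof=1) / np.sqrt(groups[g].size) for g in names})
    n = pd.Series({g: groups[g].size for g in names})
    return GroupComparison(
        groups=names,
        n=n,
        means=means,
        sem=sem,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        pairwise_p=pairwise,
        alpha=alpha,
    )


def compact_letters(
    pairwise_p: pd.DataFrame,
    means: pd.Series | Mapping[str, float],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Two groups share a letter iff their pairwise p-value is >= ``alpha``.
    Groups are processed in descending-mean order, so the highest-mean
    group receives "a"; the letter set is minimised by absorbing subset
    columns.
    """
    pmat = pairwise_p
    if not isinstance(pmat, pd.DataFrame):
        raise ValidationError("pairwise_p must be a labelled DataFrame")
    if list(pmat.index) != list(pmat.columns):
        raise ValidationError("pairwise_p must be square with matching labels")
    if not np.allclose(pmat.to_numpy(float), pmat.to_numpy(float).T):
        raise ValidationError("pairwise_p must be symmetric")
    means = pd.Series(means)
    order = list(means.loc[list(pmat.index)].sort_values(ascending=False, kind="stable").index)
    rank = {g: i for i, g in enumerate(order)}

    # columns are sets of mutually non-different groups; start with one
    columns: list[set[str]] = [set(order)]
    sig_pairs = [
        (a, b)
        for i, a in enumerate(order)
        for b in order[i + 1 :]
        if pmat.loc[a, b] < alpha
    ]
    for a, b in sig_pairs:
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop any column contained in another
        columns = []
        for col in new_columns:
            if not col:
                continue
            if any(col < other for other in new_columns if other is not col):
                continue
            if any(col == other for other in columns):
                continue
            columns.append(col)
    # deterministic letter order: by the rank of each column's best member
    columns.sort(key=lambda col: min(rank[g] for g in col))
    letters = {g: "" for g in order}
    for i, col in enumerate(columns):
        letter = chr(ord("a") + i)
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in letters}
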