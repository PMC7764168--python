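"""One-way ANOVA, Tukey pairwise comparison and compact letter displays.

Published film-property tables mark group means with superscript letters:
means sharing a letter are not significantly different pairwise at the
chosen alpha (Tukey's honestly-significant-difference test, Tukey-Kramer
adjusted for unequal group sizes).  The ANOVA F-test and the pairwise Tukey
p-values come from scipy; the letter assignment is the insert-and-absorb
algorithm, which guarantees the display is exactly consistent with the
pairwise significance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, DomainError

__all__ = ["GroupedData", "LetterDisplay", "anova_oneway", "tukey_cld"]

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class GroupedData:
    """Replicate measurements keyed by group label."""

    groups: dict[str, np.ndarray]

    def __init__(self, groups: Mapping[str, Sequence[float]]):
        clean = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
        if len(clean) < 2:
            raise DomainError("need at least 2 groups")
        for k, v in clean.items():
            if v.ndim != 1 or v.size < 2:
                raise DomainError(f"group {k!r} needs >= 2 replicates")
        object.__setattr__(self, "groups", clean)

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    def means(self) -> dict[str, float]:
        return {k: float(v.mean()) for k, v in self.groups.items()}


@dataclass(frozen=True)
class LetterDisplay:
    """Letters per group plus the pairwise significance matrix behind them.

    ``significant[i, j]`` refers to ``labels[i]`` vs ``labels[j]``; two
    groups share a letter iff their comparison is non-significant.
    """

    letters: dict[str, str]
    labels: list[str]
    p_values: np.ndarray
    significant: np.ndarray
    alpha: float

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def _check_not_degenerate(data: GroupedData) -> None:
    values = np.concatenate(list(data.groups.values()))
    if np.allclose(values, values[0]):
        raise DegenerateDataError(
            "all observations are identical; the F statistic is undefined"
        )


def anova_oneway(data: GroupedData) -> tuple[float, float]:
    """Classical one-way ANOVA: returns (F, p).

    Raises :class:`DegenerateDataError` when every observation is identical
    (zero between- and within-group variance).
    """
    _check_not_degenerate(data)
    res = sps.f_oneway(*data.groups.values())
    return float(res.statistic), float(res.pvalue)


def _absorb(columns: list[set[int]]) -> list[set[int]]:
    """Drop columns that are subsets (or duplicates) of another column."""
    kept: list[set[int]] = []
    for c in sorted(columns, key=len, reverse=True):
        if not any(c <= k for k in kept):
            kept.append(c)
    return kept


def _insert_absorb(labels: list[str], significant: np.ndarray,
                   means: np.ndarray) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Start from one column holding every group; for each significant pair
    split every column containing both (one copy drops each member); then
    absorb columns that are subsets of others.  Any non-significant pair
    keeps sharing a column, any significant pair never does.
    """
    k = len(labels)
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not significant[i, j]:
                continue
            split = [c for c in columns if i in c and j in c]
            if not split:
                continue
            columns = [c for c in columns if not (i in c and j in c)]
            for c in split:
                columns.extend([c - {i}, c - {j}])
            columns = _absorb([c for c in columns if c])
    # letter order: columns ranked by the best (largest) mean they contain
    columns.sort(key=lambda c: (-max(means[i] for i in c),
                                -min(means[i] for i in c)))
    if len(columns) > len(_ALPHABET):  # pragma: no cover
        raise DomainError("more letter groups than available letters")
    letters: dict[str, list[str]] = {lab: [] for lab in labels}
    for letter, col in zip(_ALPHABET, columns):
        for i in sorted(col):
            letters[labels[i]].append(letter)
    return {lab: "".join(sorted(ls)) for lab, ls in letters.items()}


def tukey_cld(data: GroupedData, alpha: float = 0.05) -> LetterDisplay:
    """Tukey HSD pairwise comparison with a compact letter display.

    Pairwise p-values come from the studentized-range distribution
    (Tukey-Kramer for unbalanced groups); letters are assigned by
    insert-and-absorb so that two groups share a letter exactly when their
    comparison is non-significant at ``alpha``.
    """
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    _check_not_degenerate(data)
    labels = data.labels
    res = sps.tukey_hsd(*(data.groups[lab] for lab in labels))
    p = np.asarray(res.pvalue, dtype=float)
    significant = p < alpha
    np.fill_diagonal(significant, False)
    means = np.array([data.groups[lab].mean() for lab in labels])
    letters = _insert_absorb(labels, significant, means)
    return LetterDisplay(letters=letters, labels=labels, p_values=p,
                         significant=significant, alpha=alpha)
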