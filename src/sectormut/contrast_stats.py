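"""Exact 2×2 contingency testing for junction-feature and spectrum contrasts.

Two-sided Fisher's exact p-values use the standard convention: the sum of
hypergeometric point probabilities of all tables with the observed margins
whose probability does not exceed that of the observed table (within
relative tolerance 1e-7). No multiple-testing correction is applied;
contrasts are reported as raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .records import InputError

__all__ = [
    "ContingencyResult",
    "fisher_exact_two_sided",
    "fisher_enumeration",
    "compare_category_proportions",
]


@dataclass
class ContingencyResult:
    table: "tuple[tuple[int, int], tuple[int, int]]"
    odds_ratio: float
    p_two_sided: float
    label: str = ""


def _check_table(table) -> "np.ndarray":
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise InputError("table must be 2x2")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise InputError("table entries must be non-negative integers")
    if arr.sum() == 0:
        raise InputError("at least one positive margin required")
    return arr.astype(int)


def fisher_exact_two_sided(table: Sequence[Sequence[int]], label: str = "") -> ContingencyResult:
    """Fisher's exact test, two-sided, with the sample odds ratio."""
    arr = _check_table(table)
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    a, b = arr[0]
    c, d = arr[1]
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return ContingencyResult(
        table=((int(a), int(b)), (int(c), int(d))),
        odds_ratio=odds,
        p_two_sided=float(min(p, 1.0)),
        label=label,
    )


def fisher_enumeration(table: Sequence[Sequence[int]], rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher p by explicit hypergeometric enumeration.

    Independent of :func:`fisher_exact_two_sided`'s backend: point
    probabilities come from log-binomial coefficients and the p-value is the
    explicit sum over the support. Serves as the oracle in agreement tests.
    """
    arr = _check_table(table)
    a, b = arr[0]
    c, d = arr[1]
    n1, n2, k = a + b, c + d, a + c
    lo, hi = max(0, k - n2), min(k, n1)
    support = np.arange(lo, hi + 1)
    from scipy.special import gammaln

    def logcomb(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    logp = (
        logcomb(n1, support)
        + logcomb(n2, k - support)
        - logcomb(n1 + n2, k)
    )
    p_obs = logp[a - lo]
    total = float(np.sum(np.exp(logp[logp <= p_obs + np.log1p(rel_tol)])))
    return min(total, 1.0)


def compare_category_proportions(
    counts: "dict[str, tuple[int, int]]",
    comparisons: "list[tuple[str, str]]",
) -> "list[ContingencyResult]":
    """One Fisher result per declared pairwise comparison.

    ``counts`` maps a category label to (feature-positive, feature-negative)
    counts; each comparison is a pair of labels.
    """
    results = []
    for a, b in comparisons:
        for lab in (a, b):
            if lab not in counts:
                raise InputError(f"unknown category label {lab!r}")
        res = fisher_exact_two_sided(
            [list(counts[a]), list(counts[b])], label=f"{a} vs {b}"
        )
        results.append(res)
    return results
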