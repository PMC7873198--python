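"""Simple group statistics: SEM and one/two-tailed t-tests.

p-values are reported unadjusted — no multiple-testing correction is
applied anywhere in the pipeline, and outputs label them accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


def sem(values: np.ndarray) -> float:
    """Standard error of the mean: sample sd (ddof = 1) / sqrt(n)."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise ValueError("sem requires n >= 2")
    return float(values.std(ddof=1) / math.sqrt(values.size))


@dataclass
class GroupComparison:
    """Two-group t-test result; ``sidedness`` travels with every p-value."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    sidedness: str  # "one" or "two"
    equal_var: bool
    alpha: float = ALPHA
    adjusted: bool = False  # p-values are never multiplicity-adjusted

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def group_ttest(
    values_a: np.ndarray,
    values_b: np.ndarray,
    sidedness: str = "two",
    equal_var: bool = False,
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sample t-test between groups (Welch by default).

    ``sidedness='one'`` tests the alternative in the observed direction of
    the mean difference, so its p equals half the two-sided p in the
    equal-variance case.  Each group needs n >= 2.
    """
    a = np.asarray(values_a, dtype=np.float64).ravel()
    b = np.asarray(values_b, dtype=np.float64).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if sidedness not in ("one", "two"):
        raise ValueError("sidedness must be 'one' or 'two'")
    if sidedness == "two":
        alternative = "two-sided"
    else:
        alternative = "greater" if a.mean() >= b.mean() else "less"
    result = sps.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    return GroupComparison(
        group_a=labels[0],
        group_b=labels[1],
        n_a=a.size,
        n_b=b.size,
        statistic=float(result.statistic),
        p_value=float(result.pvalue),
        sidedness=sidedness,
        equal_var=equal_var,
    )
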