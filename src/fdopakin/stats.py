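"""Cohort-level statistics: asymmetry index, one-way ANOVA with Tukey HSD,
paired t test, and Q–Q normality points.

The study design is balanced (three genotypes per age, equal n); Tukey HSD
uses the studentized-range distribution and extends to unequal group sizes
by the Tukey–Kramer rule so unbalanced synthetic cohorts do not crash.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .tac import ValidationError

__all__ = [
    "AsymmetryResult",
    "GroupComparison",
    "PairedComparison",
    "asymmetry_index",
    "anova_tukey",
    "paired_t",
    "qq_points",
]


@dataclass(frozen=True)
class AsymmetryResult:
    edvr_contralateral: float
    edvr_ipsilateral: float
    asymmetry: float
    side_convention: str = "contralateral=right"


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple
    mean_difference: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class GroupComparison:
    group_labels: tuple
    F_statistic: float
    p_value: float
    pairwise: tuple  # of PairwiseComparison
    alpha: float


@dataclass(frozen=True)
class PairedComparison:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float


def asymmetry_index(contralateral_edvr: float, ipsilateral_edvr: float) -> float:
    """(EDVR_contra − EDVR_ipsi) / EDVR_contra; negative when the
    ipsilateral side has the larger EDVR."""
    if contralateral_edvr == 0:
        raise ValidationError("contralateral EDVR is zero; asymmetry undefined")
    return (contralateral_edvr - ipsilateral_edvr) / contralateral_edvr


def anova_tukey(groups, labels=None, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA F test plus Tukey HSD adjusted pairwise comparisons."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValidationError("every group needs at least 2 observations")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if labels is None:
        labels = tuple(f"group{i}" for i in range(len(groups)))
    labels = tuple(labels)
    if len(labels) != len(groups):
        raise ValidationError("one label per group required")

    grand = np.concatenate(groups)
    if grand.var() == 0.0:
        F, p = 0.0, 1.0
    else:
        F, p = sps.f_oneway(*groups)
        if not np.isfinite(F):  # zero within-group variance
            F, p = np.inf, 0.0
    hsd = sps.tukey_hsd(*groups)
    pairwise = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p_adj = float(hsd.pvalue[i, j])
            pairwise.append(
                PairwiseComparison(
                    pair=(labels[i], labels[j]),
                    mean_difference=float(groups[i].mean() - groups[j].mean()),
                    p_adjusted=p_adj,
                    significant=bool(p_adj < alpha),
                )
            )
    return GroupComparison(
        group_labels=labels,
        F_statistic=float(F),
        p_value=float(p),
        pairwise=tuple(pairwise),
        alpha=alpha,
    )


def paired_t(left, right) -> PairedComparison:
    """Two-sided paired t test on (left − right)."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.ndim != 1:
        raise ValidationError("left and right must be equal-length 1-D samples")
    if left.size < 2:
        raise ValidationError("need at least 2 pairs")
    d = left - right
    if d.std(ddof=1) == 0.0:
        raise ValidationError("zero variance of paired differences; t undefined")
    t, p = sps.ttest_rel(left, right)
    return PairedComparison(
        t_statistic=float(t), degrees_of_freedom=left.size - 1, p_value=float(p)
    )


def qq_points(sample) -> tuple[np.ndarray, np.ndarray]:
    """Normal Q–Q points: standard-normal quantiles at plotting positions
    (i − 0.5)/n versus the ordered sample."""
    x = np.sort(np.asarray(sample, dtype=float))
    if x.size < 3:
        raise ValidationError("need at least 3 observations for a Q-Q plot")
    positions = (np.arange(1, x.size + 1) - 0.5) / x.size
    return sps.norm.ppf(positions), x
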