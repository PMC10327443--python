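"""Group comparisons for reporting.

Two-sided tests throughout: paired-sample t for the same cells measured
twice (in/out of field, pre/post plasticity), two-sample t for independent
groups, Kruskal-Wallis when distributions are non-Gaussian.  Error ranges
are reported as SEM.  No multiple-comparison correction is applied by
default; Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import AnalysisError


@dataclass
class GroupComparison:
    test_name: str               # paired-t | two-sample-t | kruskal-wallis
    statistic: float
    p_value: float
    n: tuple                     # (n_a, n_b)
    effect_direction: int        # sign of mean(a) - mean(b)
    sem: tuple                   # (sem_a, sem_b)
    degenerate: bool = False     # zero-variance difference / machine-precision p


def compare_groups(a, b, paired: bool = False, nonparametric: bool = False) -> GroupComparison:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError("need at least 2 observations per group")
    if paired and len(a) != len(b):
        raise AnalysisError("paired test requires equal-length samples")
    if a.std() == 0 and b.std() == 0 and not paired:
        raise AnalysisError("zero variance in both groups")

    sem = (float(sps.sem(a)), float(sps.sem(b)))
    direction = int(np.sign(a.mean() - b.mean()))
    n = (len(a), len(b))

    if nonparametric:
        stat, p = sps.kruskal(a, b)
        return GroupComparison("kruskal-wallis", float(stat), float(p), n, direction, sem)

    if paired:
        d = a - b
        if np.all(d == d[0]):
            if d[0] == 0:
                return GroupComparison("paired-t", 0.0, 1.0, n, 0, sem)
            # constant nonzero difference: p below the machine-precision floor
            return GroupComparison("paired-t", np.sign(d[0]) * np.inf, 0.0, n,
                                   direction, sem, degenerate=True)
        stat, p = sps.ttest_rel(a, b)
        return GroupComparison("paired-t", float(stat), float(p), n, direction, sem)

    stat, p = sps.ttest_ind(a, b)
    return GroupComparison("two-sample-t", float(stat), float(p), n, direction, sem)


def benjamini_hochberg(p_values, alpha: float = 0.05) -> np.ndarray:
    """BH-adjusted p-values (off by default in reports; provided as an option)."""
    p = np.asarray(p_values, float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adj, 0, 1)
    return out
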