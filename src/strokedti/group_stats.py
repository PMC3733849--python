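"""Group-level statistics: mean ± SEM, Student's t-test, Tukey HSD.

Conventions match the classical forms used throughout experimental
neuroscience reporting: the sample SD uses the n-1 denominator, "Student's
t-test" means the pooled-variance two-sided two-sample test (Welch is
offered as an option), and Tukey's multiple comparison uses the studentized
range distribution with the Tukey-Kramer adjustment for unequal group
sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["StatsResult", "mean_sem", "student_t", "tukey_hsd"]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class StatsResult:
    """One comparison's outcome."""

    comparison: str
    statistic: float
    df: float
    p: float
    significant: bool
    alpha: float = DEFAULT_ALPHA
    flag: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")
        if self.significant != (self.p < self.alpha):
            raise ValueError("significance flag inconsistent with p and alpha")


def mean_sem(values) -> tuple[float, float]:
    """Sample mean and standard error (SD with n-1 denominator over √n)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError(f"mean ± SEM needs n >= 2, got n = {v.size}")
    return float(np.mean(v)), float(np.std(v, ddof=1) / math.sqrt(v.size))


def student_t(
    a,
    b,
    alpha: float = DEFAULT_ALPHA,
    *,
    comparison: str = "A vs B",
    equal_var: bool = True,
) -> StatsResult:
    """Two-sided two-sample t-test; pooled-variance by default.

    Degenerate case: when the pooled variance is zero the test statistic is
    undefined; equal means yield t = 0, p = 1, and unequal means are
    reported as p = 0 with a flag.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = a.size, b.size
    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / df
        if sp2 == 0.0:
            if np.mean(a) == np.mean(b):
                return StatsResult(comparison, 0.0, float(df), 1.0, False, alpha)
            return StatsResult(
                comparison, math.inf, float(df), 0.0, True, alpha, flag="zero pooled variance"
            )
        t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        p = 2.0 * sps.t.sf(abs(t), df)
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
        df = sps.ttest_ind(a, b, equal_var=False).df
    p = min(float(p), 1.0)
    return StatsResult(comparison, float(t), float(df), p, p < alpha, alpha)


def tukey_hsd(groups: dict[str, "np.ndarray"], alpha: float = DEFAULT_ALPHA) -> list[StatsResult]:
    """All pairwise comparisons by Tukey's HSD.

    ``groups`` maps group name to sample.  The pooled within-group variance
    uses df = N - k; each pair's studentized statistic applies the
    Tukey-Kramer standard error sqrt(s²/2·(1/n_i + 1/n_j)), and p-values
    come from the studentized range distribution with k groups.  With k = 2
    this reduces exactly to the pooled two-sided t-test.
    """
    names = list(groups)
    k = len(names)
    if k < 2:
        raise ValueError("Tukey HSD needs at least 2 groups")
    samples = [np.asarray(groups[n], dtype=float).ravel() for n in names]
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    ns = np.array([s.size for s in samples])
    big_n = int(ns.sum())
    df = big_n - k
    s2 = sum((n - 1) * np.var(s, ddof=1) for n, s in zip(ns, samples)) / df
    means = [float(np.mean(s)) for s in samples]
    out: list[StatsResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            label = f"{names[i]} vs {names[j]}"
            if s2 == 0.0:
                if means[i] == means[j]:
                    out.append(StatsResult(label, 0.0, float(df), 1.0, False, alpha))
                else:
                    out.append(
                        StatsResult(
                            label, math.inf, float(df), 0.0, True, alpha,
                            flag="zero pooled variance",
                        )
                    )
                continue
            se = math.sqrt(s2 / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se
            p = float(sps.studentized_range.sf(q, k, df))
            p = min(max(p, 0.0), 1.0)
            out.append(StatsResult(label, q, float(df), p, p < alpha, alpha))
    return out
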