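"""Statistical tests and the empirical p-value machinery.

All hypothesis tests return plain result records (statistic + p); empirical
p-values from resampling nulls use the add-one estimator
``p = (1 + #extreme) / (1 + n_samples)`` so that a p-value of exactly zero is
never reported — when no resample is as extreme as the observation the result
is flagged as a bound (reported downstream as ``< 1/n_samples``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class NullDistribution:
    """A statistic evaluated on resampled backgrounds."""

    values: np.ndarray
    statistic_name: str
    seed: int
    constraint: str = ""
    n_samples: int = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("null values must be a non-empty 1-d vector")
        self.n_samples = int(self.values.size)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    df: float | None = None


def welch_t(a, b) -> TestResult:
    """Welch's unequal-variance t-test, two-sided.

    Degenerate convention: if both samples have zero variance and equal
    means, t = 0 and p = 1; zero variance on both sides with unequal means
    has no defined t statistic and raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs at least two values per sample")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("welch_t requires finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, float(a.size + b.size - 2))
        raise ValueError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), float(res.df))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts.

    Two-sided by the "probability at most observed" rule (the convention of
    R's ``fisher.test``).  Any empty margin leaves a degenerate table and
    returns p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


def two_prop_yates(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Two-proportion chi-square test with Yates' continuity correction.

    Matches R's ``prop.test`` on a 2x2 success/failure table (1 df).  If the
    pooled proportion is 0 or 1 the table is degenerate and p = 1.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise ValueError("need 0 <= x <= n and n >= 1")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return TestResult(0.0, 1.0, 1.0)
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return TestResult(float(chi2), float(p), 1.0)


def empirical_p(null: NullDistribution, observed: float,
                tail: str = "upper") -> tuple[float, bool]:
    """Add-one empirical p-value of an observation against a resampling null.

    Returns ``(p, is_bound)``; ``is_bound`` is True when no null value is as
    extreme as the observation, i.e. the value is the estimator's floor
    ``1/(1 + n_samples)`` and should be reported as ``< 1/n_samples``.
    """
    if tail == "upper":
        count = int((null.values >= observed).sum())
    elif tail == "lower":
        count = int((null.values <= observed).sum())
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    p = (1 + count) / (1 + null.n_samples)
    return p, count == 0


def ks_two_sample(a, b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return TestResult(float(res.statistic), float(min(1.0, res.pvalue)))
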