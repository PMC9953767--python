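"""Statistical layer: correlation significance, paired symmetric-region
comparisons with a normality gate, and test-retest reliability.

The correlation test converts a fit correlation r at sample size n into
t = r*sqrt(n-2)/sqrt(1-r^2), referred to a one-tailed Student t distribution
with n-2 degrees of freedom.  Paired left/right comparisons first check the
differences for normality (Lilliefors-corrected Kolmogorov-Smirnov, since
mean and SD are estimated from the sample) and use a paired t-test when
normality holds, a Wilcoxon signed-rank test otherwise.  Significance level
is 0.05 throughout; no multiple-testing correction is applied by default
(a Holm option is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class RegressionResult:
    """One-tailed significance of a correlation coefficient."""

    r: float
    n: int
    t: float
    p: float
    df: int
    perfect: bool = False  # |r| = 1: t is infinite, p reported as 0


def correlation_t_test(r: float, n: int) -> RegressionResult:
    """t = r*sqrt(n-2)/sqrt(1-r^2), one-tailed p with n-2 df.

    Odd in r (t(-r) = -t(r)); p is monotone decreasing in |r| at fixed n and
    in n at fixed r > 0.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if abs(r) > 1:
        raise ValueError(f"|r| = {abs(r)} > 1")
    df = n - 2
    if abs(r) == 1.0:
        return RegressionResult(r, n, np.inf * np.sign(r), 0.0, df, perfect=True)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = float(sps.t.sf(t, df))
    return RegressionResult(float(r), int(n), float(t), p, df)


@dataclass
class PairedComparison:
    """Paired two-sided comparison with its normality gate."""

    test: str          # 'paired-t', 'wilcoxon', or 'degenerate'
    statistic: float
    p: float
    normality_p: float
    degenerate: bool = False


def paired_compare(left: Sequence[float], right: Sequence[float],
                   alpha: float = ALPHA) -> PairedComparison:
    """Compare paired samples (e.g. symmetric lobes), two-sided.

    The Lilliefors test on the paired differences (at `alpha`) selects a
    paired t-test when normality is not rejected, a Wilcoxon signed-rank test
    otherwise.  Identical vectors are reported as degenerate without running
    a test.
    """
    from statsmodels.stats.diagnostic import lilliefors

    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.ndim != 1:
        raise ValueError("left and right must be equal-length 1-d arrays")
    if left.size < 5:
        raise ValueError(f"need at least 5 pairs, got {left.size}")
    d = left - right
    if np.all(d == 0):
        return PairedComparison("degenerate", 0.0, 1.0, 1.0, degenerate=True)
    if np.std(d) == 0:
        # constant nonzero shift: KS is undefined; the shift is systematic
        return PairedComparison("paired-t", np.inf, 0.0, 1.0)
    _, norm_p = lilliefors(d, dist="norm")
    if norm_p >= alpha:
        stat, p = sps.ttest_rel(left, right)
        return PairedComparison("paired-t", float(stat), float(p), float(norm_p))
    stat, p = sps.wilcoxon(left, right)
    return PairedComparison("wilcoxon", float(stat), float(p), float(norm_p))


def holm_correct(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default upstream)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, float), method="holm")[1]


def test_retest(features_t1: pd.DataFrame,
                features_t2: pd.DataFrame) -> pd.Series:
    """Pearson r per feature between two sessions of the same subjects.

    Rows are subjects (aligned by index), columns are features.  Constant
    features yield NaN.
    """
    if not features_t1.index.equals(features_t2.index):
        features_t2 = features_t2.loc[features_t1.index]
    if len(features_t1) < 3:
        raise ValueError("test-retest needs at least 3 matched subjects")
    out = {}
    for col in features_t1.columns:
        a = features_t1[col].to_numpy(dtype=float)
        b = features_t2[col].to_numpy(dtype=float)
        if np.std(a) == 0 or np.std(b) == 0:
            out[col] = np.nan
        else:
            out[col] = float(np.corrcoef(a, b)[0, 1])
    return pd.Series(out)
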