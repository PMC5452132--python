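"""Small shared statistics helpers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TTestResult:
    p_value: float | None
    statistic: float | None
    degenerate: bool
    incomparable: bool = False


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-tailed equal-variance two-sample t-test with degenerate handling.

    - a group is empty -> incomparable, no p;
    - any group of size 1, or zero pooled variance -> degenerate flag;
      with zero pooled variance, p = 1 if means are equal else p = 0.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        return TTestResult(None, None, degenerate=True, incomparable=True)

    degenerate = a.size < 2 or b.size < 2
    ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if ss == 0.0 or a.size + b.size < 3:
        p = 1.0 if a.mean() == b.mean() else 0.0
        return TTestResult(p, None, degenerate=True)
    stat, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(p), float(stat), degenerate=degenerate)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
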