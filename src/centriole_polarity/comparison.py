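"""Group comparison of polarity statistics.

Two-sample t-test between experimental groups on per-image summaries (the
per-image ABP score or a per-image quartile fraction).  The sampling unit
is the image, not the centriole: centrioles within one image share tissue
context and are not independent.  Welch's unequal-variance variant is the
default; the pooled Student's test is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["ComparisonResult", "compare_groups"]


@dataclass
class ComparisonResult:
    metric: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    n_a: int
    n_b: int

    def significance_marker(self) -> str:
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return "ns"

    def summary(self) -> str:
        return (
            f"{self.metric}: {self.group_a} (mean {self.mean_a:.4f}, n={self.n_a}) "
            f"vs {self.group_b} (mean {self.mean_b:.4f}, n={self.n_b}): "
            f"t = {self.t_statistic:.4f}, df = {self.degrees_of_freedom:.2f}, "
            f"p = {self.p_value:.4g} [{self.significance_marker()}]"
        )


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    metric: str = "ABP",
    group_a: str = "WT",
    group_b: str = "IR",
    equal_var: bool = False,
) -> ComparisonResult:
    """Two-sided two-sample t-test on per-image summaries.

    Each group needs at least two per-image values.  ``equal_var=False``
    (default) runs Welch's test with Satterthwaite degrees of freedom.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            "insufficient replicates: each group needs >= 2 per-image values"
        )
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        n_a=int(a.size),
        n_b=int(b.size),
    )
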