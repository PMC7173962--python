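"""Group comparisons with a single declared testing policy.

The default test is a two-sided Mann–Whitney U (exact when sample sizes are
small and tie-free, normal approximation with tie correction otherwise),
reported with a rank-biserial effect size.  A Welch t-test is available
behind a flag.  No multiple-testing correction is applied: comparisons are
per-figure single contrasts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    effect_size: float  # rank-biserial for MW-U, Cohen's d for Welch
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "effect_size": float(self.effect_size),
            "n_a": int(self.n_a),
            "n_b": int(self.n_b),
        }


def compare(group_a, group_b, test: str = "mannwhitney") -> GroupComparison:
    """Two-sided comparison of two independent numeric samples.

    Symmetric under label exchange; requires at least 3 values per group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError(
            f"at least 3 values per group are required (got {a.size} and {b.size})"
        )
    if test == "mannwhitney":
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (not has_ties and max(a.size, b.size) <= 25) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        u = float(res.statistic)
        # rank-biserial correlation: +1 when every a exceeds every b
        effect = 2.0 * u / (a.size * b.size) - 1.0
        return GroupComparison("mannwhitney-u", u, float(res.pvalue), effect,
                               a.size, b.size)
    if test == "welch":
        res = sps.ttest_ind(a, b, equal_var=False)
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        d = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
        return GroupComparison("welch-t", float(res.statistic), float(res.pvalue),
                               float(d), a.size, b.size)
    raise ValueError(f"unknown test {test!r}; use 'mannwhitney' or 'welch'")
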