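"""Significance gate between related and unrelated score distributions.

Before any ROC analysis, the two groups must differ significantly (p < 0.05).
Normality is screened per group with Shapiro-Wilk; if both groups look normal
the gate uses Welch's unequal-variance t-test, otherwise a Mann-Whitney U
with normal approximation and tie correction. Which test fired is always
recorded; downstream cutoff selection does not depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .profiles import KinshipDataError

__all__ = ["GroupTestResult", "compare_groups"]


@dataclass(frozen=True)
class GroupTestResult:
    test_used: str  # "welch_t" | "mann_whitney_u"
    statistic: float
    p_value: float
    significant: bool
    group_means: tuple[float, float]  # (related, unrelated)
    group_sds: tuple[float, float]  # sample SDs, n-1 denominator
    shapiro_p: tuple[Optional[float], Optional[float]]

    def to_dict(self) -> dict:
        return {
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significant": self.significant,
            "group_means": list(self.group_means),
            "group_sds": list(self.group_sds),
            "shapiro_p": list(self.shapiro_p),
        }


def _shapiro_p(x: np.ndarray) -> Optional[float]:
    # Shapiro-Wilk is undefined for a constant sample; treat as non-normal.
    if np.ptp(x) == 0:
        return None
    return float(stats.shapiro(x).pvalue)


def compare_groups(
    related: Sequence[float], unrelated: Sequence[float], alpha: float = 0.05
) -> GroupTestResult:
    """Test whether related and unrelated scores differ; gate at p < alpha."""
    rel = np.asarray(related, dtype=float)
    unrel = np.asarray(unrelated, dtype=float)
    if len(rel) < 3 or len(unrel) < 3:
        raise KinshipDataError("each group needs at least 3 scores")

    means = (float(rel.mean()), float(unrel.mean()))
    sds = (float(rel.std(ddof=1)), float(unrel.std(ddof=1)))
    sp = (_shapiro_p(rel), _shapiro_p(unrel))

    pooled = np.concatenate([rel, unrel])
    if np.ptp(pooled) == 0:
        # Degenerate: every score identical in both groups.
        return GroupTestResult(
            test_used="mann_whitney_u",
            statistic=float(len(rel) * len(unrel) / 2),
            p_value=1.0,
            significant=False,
            group_means=means,
            group_sds=sds,
            shapiro_p=sp,
        )

    if sp[0] is not None and sp[1] is not None and sp[0] > alpha and sp[1] > alpha:
        res = stats.ttest_ind(rel, unrel, equal_var=False)
        test = "welch_t"
    else:
        res = stats.mannwhitneyu(rel, unrel, alternative="two-sided", method="asymptotic")
        test = "mann_whitney_u"
    p = float(res.pvalue)
    return GroupTestResult(
        test_used=test,
        statistic=float(res.statistic),
        p_value=p,
        significant=p < alpha,
        group_means=means,
        group_sds=sds,
        shapiro_p=sp,
    )
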