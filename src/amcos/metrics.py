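"""Diagnostic-test metrics for an AMCOS screen: 2x2 tables, point estimates, CIs.

A pair screens positive when its allele-matching score is >= the AMCOS.
Point estimates are kept as exact integer fractions alongside their float
values. Interval choices: Clopper-Pearson (exact) for sensitivity,
specificity, and accuracy; Wilson score for the predictive values; the
standard log-method (Simel/Altman) for the likelihood ratios. Metrics with a
zero denominator — e.g. LR+ when specificity is 1 — are reported as explicit
undefined markers, never as 0 or infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .profiles import KinshipDataError
from .roc import ScoreSample

__all__ = [
    "ConfusionTable",
    "MetricValue",
    "MetricsReport",
    "confusion_at",
    "metrics",
    "evaluate",
    "proportion_ci_exact",
    "predictive_value_ci",
    "lr_ci",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise KinshipDataError("confusion counts must be non-negative")

    @property
    def n_related(self) -> int:
        return self.tp + self.fn

    @property
    def n_unrelated(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_at(scores: ScoreSample, amcos: int) -> ConfusionTable:
    """2x2 table at a given AMCOS under the score >= AMCOS positivity rule."""
    if amcos < 0:
        raise KinshipDataError("amcos must be non-negative")
    tp = sum(1 for v in scores.related if v >= amcos)
    fp = sum(1 for v in scores.unrelated if v >= amcos)
    return ConfusionTable(
        tp=tp, fp=fp, fn=len(scores.related) - tp, tn=len(scores.unrelated) - fp
    )


@dataclass(frozen=True)
class MetricValue:
    """A point estimate with optional exact fraction and 95% CI.

    ``value`` is None when the metric is undefined (zero denominator, or an
    infinite likelihood ratio); that state mirrors the blank cells of the
    original study's summary table.
    """

    value: Optional[float]
    numer: Optional[int] = None
    denom: Optional[int] = None
    ci95: Optional[tuple[float, float]] = None

    @property
    def defined(self) -> bool:
        return self.value is not None

    def as_percent(self, decimals: int = 2) -> str:
        if self.value is None:
            return "-"
        s = f"{100 * self.value:.{decimals}f}%"
        if self.ci95 is not None:
            s += f" ({100 * self.ci95[0]:.{decimals}f}-{100 * self.ci95[1]:.{decimals}f}%)"
        return s


def proportion_ci_exact(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial interval for k successes out of n."""
    if not (0 <= k <= n) or n <= 0:
        raise KinshipDataError(f"invalid proportion {k}/{n}")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
    # statsmodels returns NaN at the boundaries where the interval is closed.
    lo = 0.0 if math.isnan(lo) else float(lo)
    hi = 1.0 if math.isnan(hi) else float(hi)
    return lo, hi


def _wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def predictive_value_ci(
    tp: int, fp: int, fn: int, tn: int, level: float = 0.95
) -> tuple[Optional[tuple[float, float]], Optional[tuple[float, float]]]:
    """Wilson score intervals for PPV (tp/(tp+fp)) and NPV (tn/(tn+fn)).

    Returns (ppv_ci, npv_ci); an interval is None when its denominator is 0.
    """
    ppv_ci = _wilson_ci(tp, tp + fp, level) if tp + fp > 0 else None
    npv_ci = _wilson_ci(tn, tn + fn, level) if tn + fn > 0 else None
    return ppv_ci, npv_ci


def lr_ci(
    confusion: ConfusionTable, level: float = 0.95
) -> tuple[Optional[tuple[float, float]], Optional[tuple[float, float]]]:
    """Log-method intervals for LR+ and LR-: exp(ln LR +/- z * SE).

    SE(ln LR+) = sqrt(1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn));
    SE(ln LR-) = sqrt(1/fn - 1/(tp+fn) + 1/tn - 1/(fp+tn)).
    None where the ratio or its SE is undefined (zero cells).
    """
    tp, fp, fn, tn = confusion.tp, confusion.fp, confusion.fn, confusion.tn
    nr, nu = confusion.n_related, confusion.n_unrelated
    z = stats.norm.ppf(0.5 + level / 2)

    def interval(lr: float, se2: float) -> tuple[float, float]:
        se = math.sqrt(se2)
        return math.exp(math.log(lr) - z * se), math.exp(math.log(lr) + z * se)

    plus = None
    if tp > 0 and fp > 0 and nr > 0 and nu > 0:
        lr_plus = (tp / nr) / (fp / nu)
        plus = interval(lr_plus, 1 / tp - 1 / nr + 1 / fp - 1 / nu)
    minus = None
    if fn > 0 and tn > 0 and nr > 0 and nu > 0:
        lr_minus = (fn / nr) / (tn / nu)
        minus = interval(lr_minus, 1 / fn - 1 / nr + 1 / tn - 1 / nu)
    return plus, minus


@dataclass(frozen=True)
class MetricsReport:
    """The full metric set at one AMCOS: estimates, fractions, and 95% CIs."""

    amcos: int
    confusion: ConfusionTable
    sensitivity: MetricValue
    specificity: MetricValue
    ppv: MetricValue
    npv: MetricValue
    accuracy: MetricValue
    lr_plus: MetricValue
    lr_minus: MetricValue

    def to_dict(self) -> dict:
        def mv(m: MetricValue) -> dict:
            return {
                "value": m.value,
                "fraction": [m.numer, m.denom] if m.denom is not None else None,
                "ci95": list(m.ci95) if m.ci95 is not None else None,
            }

        c = self.confusion
        return {
            "amcos": self.amcos,
            "confusion": {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn},
            "sensitivity": mv(self.sensitivity),
            "specificity": mv(self.specificity),
            "ppv": mv(self.ppv),
            "npv": mv(self.npv),
            "accuracy": mv(self.accuracy),
            "lr_plus": mv(self.lr_plus),
            "lr_minus": mv(self.lr_minus),
        }

    def to_table(self, decimals: int = 2) -> str:
        """Human-readable summary, percentages with CI strings."""
        lines = [f"AMCOS: {self.amcos}  (tp {self.confusion.tp}, fp {self.confusion.fp}, "
                 f"fn {self.confusion.fn}, tn {self.confusion.tn})"]
        for label in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            lines.append(f"{label}\t{getattr(self, label).as_percent(decimals)}")
        for label in ("lr_plus", "lr_minus"):
            m: MetricValue = getattr(self, label)
            if m.value is None:
                lines.append(f"{label}\t-")
            else:
                s = f"{m.value:.{decimals}f}"
                if m.ci95 is not None:
                    s += f" ({m.ci95[0]:.{decimals}f}-{m.ci95[1]:.{decimals}f})"
                lines.append(f"{label}\t{s}")
        return "\n".join(lines)


def metrics(confusion: ConfusionTable, amcos: int = 0, level: float = 0.95) -> MetricsReport:
    """Point estimates and CIs from a 2x2 table.

    Requires at least one related and one unrelated pair; other zero
    denominators yield undefined markers for the affected metrics only.
    """
    tp, fp, fn, tn = confusion.tp, confusion.fp, confusion.fn, confusion.tn
    nr, nu = confusion.n_related, confusion.n_unrelated
    if nr == 0 or nu == 0:
        raise KinshipDataError("metrics require both related and unrelated pairs")

    def prop(k: int, n: int, exact: bool) -> MetricValue:
        if n == 0:
            return MetricValue(None)
        ci = proportion_ci_exact(k, n, level) if exact else _wilson_ci(k, n, level)
        return MetricValue(k / n, k, n, ci)

    sens = prop(tp, nr, exact=True)
    spec = prop(tn, nu, exact=True)
    ppv = prop(tp, tp + fp, exact=False)
    npv = prop(tn, tn + fn, exact=False)
    acc = prop(tp + tn, confusion.total, exact=True)

    plus_ci, minus_ci = lr_ci(confusion, level)
    if fp > 0:
        lr_plus = MetricValue((tp / nr) / (fp / nu), ci95=plus_ci)
    elif tp > 0:
        lr_plus = MetricValue(None)  # infinite: specificity is 1
    else:
        lr_plus = MetricValue(None)  # 0/0
    if tn > 0:
        lr_minus = MetricValue((fn / nr) / (tn / nu), ci95=minus_ci)
    else:
        lr_minus = MetricValue(None)  # specificity is 0

    return MetricsReport(
        amcos=amcos,
        confusion=confusion,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=acc,
        lr_plus=lr_plus,
        lr_minus=lr_minus,
    )


def evaluate(scores: ScoreSample, amcos: int, level: float = 0.95) -> MetricsReport:
    """Confusion table and full metric set for a score sample at one AMCOS."""
    return metrics(confusion_at(scores, amcos), amcos=amcos, level=level)
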