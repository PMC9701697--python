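"""Empirical ROC curves over integer allele-matching scores and AMCOS selection.

Cutoffs follow the SPSS convention: the smallest cutoff is the minimum pooled
observed score minus 1, the largest is the maximum plus 1, and every interior
cutoff is the average of two consecutive distinct observed scores. A pair
screens positive when its score is >= the cutoff; because interior cutoffs are
half-integers, >= and > coincide on integer scores.

Two selection criteria are provided. ``youden`` maximises J = sensitivity -
(1 - specificity). ``closest_topleft`` minimises the Euclidean distance to the
ideal (0, 1) ROC corner; this is the rule that reproduces every cutoff chosen
in the original AMCOS study, whose selections depart from strict Youden
maximisation in three of the ten analyses (see docs/methods.md). Ties under
either criterion resolve to the largest cutoff, favouring specificity in the
screen-then-confirm workflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .profiles import KinshipDataError

__all__ = [
    "ScoreSample",
    "RocPoint",
    "RocCurve",
    "spss_cutoffs",
    "roc_curve",
    "auc_trapezoid",
    "AmcosSelection",
    "select_amcos",
    "youden_select",
    "PUBLISHED_CRITERION",
]

#: Selection criterion that reproduces the original study's published cutoffs.
PUBLISHED_CRITERION = "closest_topleft"


@dataclass(frozen=True)
class ScoreSample:
    """Integer pair scores for one analysis group, split by ground truth."""

    related: tuple[int, ...]
    unrelated: tuple[int, ...]

    def __post_init__(self) -> None:
        for name, vals in (("related", self.related), ("unrelated", self.unrelated)):
            if any(v < 0 or v != int(v) for v in vals):
                raise KinshipDataError(f"{name} scores must be non-negative integers")

    @classmethod
    def from_records(cls, values: Iterable[int], truths: Iterable[str]) -> "ScoreSample":
        rel, unrel = [], []
        for v, t in zip(values, truths, strict=True):
            if t == "related":
                rel.append(int(v))
            elif t == "unrelated":
                unrel.append(int(v))
            else:
                raise KinshipDataError(f"truth must be 'related' or 'unrelated', got {t!r}")
        return cls(tuple(rel), tuple(unrel))

    @classmethod
    def from_counts(cls, related: dict[int, int], unrelated: dict[int, int]) -> "ScoreSample":
        expand = lambda d: tuple(v for v, k in sorted(d.items()) for _ in range(k))
        return cls(expand(related), expand(unrelated))

    @property
    def pooled(self) -> tuple[int, ...]:
        return self.related + self.unrelated

    def require_both_classes(self) -> None:
        if not self.related or not self.unrelated:
            raise KinshipDataError(
                "ROC construction requires at least one related and one unrelated score"
            )


def spss_cutoffs(values: Sequence[int]) -> np.ndarray:
    """SPSS-convention candidate cutoffs for a set of observed test values.

    Distinct sorted values v1 < ... < vk map to
    [v1 - 1, (v1+v2)/2, ..., (v_{k-1}+v_k)/2, vk + 1]; a single distinct value
    degenerates to (v - 1, v + 1).
    """
    if len(values) == 0:
        raise KinshipDataError("no observed values")
    distinct = np.unique(np.asarray(values, dtype=float))
    cuts = np.empty(len(distinct) + 1)
    cuts[0] = distinct[0] - 1.0
    cuts[-1] = distinct[-1] + 1.0
    cuts[1:-1] = (distinct[:-1] + distinct[1:]) / 2.0
    return cuts


@dataclass(frozen=True)
class RocPoint:
    cutoff: float
    sensitivity: float
    one_minus_specificity: float


@dataclass(frozen=True)
class RocCurve:
    """Ordered (cutoff, sensitivity, 1 - specificity) coordinates.

    Cutoffs are strictly increasing; both fractions are non-increasing; the
    first point is (min - 1, 1, 1) and the last (max + 1, 0, 0).
    """

    points: tuple[RocPoint, ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise KinshipDataError("a ROC curve needs at least two points")
        cuts = self.cutoffs
        if not np.all(np.diff(cuts) > 0):
            raise KinshipDataError("ROC cutoffs must be strictly increasing")
        for arr, label in ((self.sensitivities, "sensitivity"),
                           (self.one_minus_specificities, "1-specificity")):
            if np.any(np.diff(arr) > 1e-12):
                raise KinshipDataError(f"{label} must be non-increasing with cutoff")
            if arr[0] != 1.0 or arr[-1] != 0.0:
                raise KinshipDataError(f"{label} must start at 1 and end at 0")

    @property
    def cutoffs(self) -> np.ndarray:
        return np.array([p.cutoff for p in self.points])

    @property
    def sensitivities(self) -> np.ndarray:
        return np.array([p.sensitivity for p in self.points])

    @property
    def one_minus_specificities(self) -> np.ndarray:
        return np.array([p.one_minus_specificity for p in self.points])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "sensitivity": self.sensitivities,
                "one_minus_specificity": self.one_minus_specificities,
            }
        )


def roc_curve(sample: ScoreSample) -> RocCurve:
    """Empirical ROC over SPSS-convention cutoffs pooled from both groups."""
    sample.require_both_classes()
    rel = np.asarray(sample.related, dtype=float)
    unrel = np.asarray(sample.unrelated, dtype=float)
    points = tuple(
        RocPoint(
            cutoff=float(c),
            sensitivity=float(np.mean(rel >= c)),
            one_minus_specificity=float(np.mean(unrel >= c)),
        )
        for c in spss_cutoffs(sample.pooled)
    )
    return RocCurve(points)


def auc_trapezoid(curve: RocCurve) -> float:
    """Trapezoidal area under the curve, integrating sensitivity over 1 - specificity."""
    x = curve.one_minus_specificities[::-1]
    y = curve.sensitivities[::-1]
    return float(np.trapezoid(y, x))


@dataclass(frozen=True)
class AmcosSelection:
    """The chosen cutoff, Youden's J there, and the integer screening score."""

    optimal_cutoff: float
    youden_j: float
    amcos: int
    criterion: str

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.youden_j <= 1.0 + 1e-12):
            raise KinshipDataError("Youden's J out of range")


def _objective(criterion: str, sens: float, fpr: float) -> float:
    # Larger is better for both criteria.
    if criterion == "youden":
        return sens - fpr
    if criterion == "closest_topleft":
        return -((1.0 - sens) ** 2 + fpr**2)
    raise KinshipDataError(f"unknown selection criterion {criterion!r}")


def select_amcos(curve: RocCurve, criterion: str = PUBLISHED_CRITERION) -> AmcosSelection:
    """Pick the screening cutoff; the AMCOS is its ceiling (scores are integers).

    Endpoint cutoffs (min - 1, max + 1) are eligible but lose ties against
    interior cutoffs; remaining ties resolve to the largest cutoff.
    """
    n = len(curve.points)
    scored = [
        (_objective(criterion, p.sensitivity, p.one_minus_specificity), i, p)
        for i, p in enumerate(curve.points)
    ]
    best = max(s for s, _, _ in scored)
    candidates = [(i, p) for s, i, p in scored if abs(s - best) <= 1e-12]
    interior = [(i, p) for i, p in candidates if 0 < i < n - 1]
    if interior:
        candidates = interior
    i, point = max(candidates, key=lambda ip: ip[1].cutoff)
    return AmcosSelection(
        optimal_cutoff=point.cutoff,
        youden_j=point.sensitivity - point.one_minus_specificity,
        amcos=math.ceil(point.cutoff - 1e-12),
        criterion=criterion,
    )


def youden_select(curve: RocCurve) -> AmcosSelection:
    """Strict Youden-index maximisation (J = sensitivity + specificity - 1)."""
    return select_amcos(curve, criterion="youden")
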