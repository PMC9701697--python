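"""Identity-by-state allele sharing: per-locus shared counts and OAM/TAM pair scores.

A pair's score summarises, locus by locus, how many alleles the two genotypes
share by state (exact label equality, multiset intersection). For autosomal
panels the one-allele-match (OAM) score counts loci sharing *exactly* one
allele and the two-allele-match (TAM) score counts loci sharing both; for
X panels, where males are hemizygous and a full match is a single allele,
OAM counts loci sharing *at least* one allele and no TAM is produced.
Loci are always scored independently — no linkage-group aggregation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .profiles import (
    ChromosomeClass,
    IncompleteProfileError,
    KinshipDataError,
    PairRecord,
    Panel,
)

__all__ = [
    "shared_allele_count",
    "locus_sharing",
    "AmsScore",
    "score_autosomal_pair",
    "score_x_pair",
    "score_pair",
    "score_pairs",
]


def shared_allele_count(geno_a: Sequence[str], geno_b: Sequence[str]) -> int:
    """Size of the multiset intersection of two genotypes (0, 1, or 2).

    {A,A} vs {A,B} shares one allele; {A,B} vs {B,A} shares two; a hemizygous
    {A} can share at most one.
    """
    if not geno_a or not geno_b:
        raise KinshipDataError("cannot score an empty genotype")
    return sum((Counter(geno_a) & Counter(geno_b)).values())


def locus_sharing(pair: PairRecord, panel: Panel, permissive: bool = False) -> dict[str, int]:
    """Per-marker shared-allele counts for a pair over ``panel``.

    In permissive mode, loci absent from either profile are skipped instead of
    raising; the caller can see which loci were used from the returned keys.
    """
    counts: dict[str, int] = {}
    for marker in panel:
        a = pair.profile_a.genotypes.get(marker.name)
        b = pair.profile_b.genotypes.get(marker.name)
        if a is None or b is None:
            if permissive:
                continue
            missing = pair.profile_a if a is None else pair.profile_b
            raise IncompleteProfileError(
                f"incomplete profile: sample {missing.sample_id!r} has no genotype "
                f"at marker {marker.name!r}"
            )
        counts[marker.name] = shared_allele_count(a, b)
    return counts


@dataclass(frozen=True)
class AmsScore:
    """Aggregate allele-matching scores for one pair.

    ``tam`` is None for X panels, where a two-allele category is not defined
    across mixed ploidies.
    """

    oam: int
    tam: Optional[int]
    loci_used: int

    def __post_init__(self) -> None:
        total = self.oam + (self.tam or 0)
        if not (0 <= total <= self.loci_used):
            raise KinshipDataError(
                f"inconsistent score: oam {self.oam} + tam {self.tam} exceeds "
                f"loci_used {self.loci_used}"
            )


def score_autosomal_pair(pair: PairRecord, panel: Panel, permissive: bool = False) -> AmsScore:
    """OAM/TAM score over an autosomal panel.

    OAM counts loci with exactly one shared allele; TAM counts loci with two.
    The categories are exclusive: a fully matching locus contributes to TAM
    only.
    """
    if panel.chromosome_class is not ChromosomeClass.AUTOSOMAL:
        raise KinshipDataError(f"panel {panel.name} is not autosomal")
    counts = locus_sharing(pair, panel, permissive=permissive)
    vals = counts.values()
    return AmsScore(
        oam=sum(1 for c in vals if c == 1),
        tam=sum(1 for c in vals if c == 2),
        loci_used=len(counts),
    )


def score_x_pair(pair: PairRecord, panel: Panel, permissive: bool = False) -> AmsScore:
    """OAM score over an X panel: loci sharing at least one allele by state.

    The at-least-one rule lets obligate-sharing configurations (sisters via
    their father's X; paternal grandmother to granddaughter) reach the full
    panel size regardless of the second allele.
    """
    if panel.chromosome_class is not ChromosomeClass.X_LINKED:
        raise KinshipDataError(f"panel {panel.name} is not X-linked")
    counts = locus_sharing(pair, panel, permissive=permissive)
    return AmsScore(
        oam=sum(1 for c in counts.values() if c >= 1),
        tam=None,
        loci_used=len(counts),
    )


def score_pair(pair: PairRecord, panel: Panel, permissive: bool = False) -> AmsScore:
    if panel.chromosome_class is ChromosomeClass.AUTOSOMAL:
        return score_autosomal_pair(pair, panel, permissive=permissive)
    return score_x_pair(pair, panel, permissive=permissive)


def score_pairs(
    pairs: Iterable[PairRecord],
    panel: Panel,
    pair_ids: Optional[Sequence[str]] = None,
    permissive: bool = False,
) -> pd.DataFrame:
    """Score many pairs; returns columns pair_id, hypothesis, truth, oam, tam, loci_used."""
    rows = []
    for i, pair in enumerate(pairs):
        score = score_pair(pair, panel, permissive=permissive)
        rows.append(
            {
                "pair_id": pair_ids[i] if pair_ids is not None else f"pair{i:04d}",
                "hypothesis": pair.hypothesis,
                "truth": pair.truth,
                "oam": score.oam,
                "tam": score.tam if score.tam is not None else pd.NA,
                "loci_used": score.loci_used,
            }
        )
    df = pd.DataFrame(
        rows, columns=["pair_id", "hypothesis", "truth", "oam", "tam", "loci_used"]
    )
    df["tam"] = df["tam"].astype("Int64")
    return df
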