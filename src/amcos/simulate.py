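"""Seeded pedigree simulator: STR genotypes for related and unrelated pairs.

Founders are drawn locus-wise from allele frequencies (two independent draws
at autosomal loci; two for females and one for hemizygous males at X loci).
Transmission is Mendelian with free recombination — every locus independent,
including the X loci, mirroring marker-by-marker matching with no linkage
groups. X transmission is sex-aware: a mother passes one of her two alleles,
a father passes his single allele to daughters and nothing to sons.

Founder alleles carry unique origin tags so identity-by-descent can be
counted exactly per locus; IBD never exceeds the identity-by-state shared
count. An optional single-step mutation model (+/-1 repeat, equal
probability, per meiosis per locus) is available; the default rate is 0 so
obligate-sharing configurations (sisters via their father's X, paternal
grandmother to granddaughter) are exact.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .profiles import (
    ChromosomeClass,
    FrequencyTable,
    KinshipDataError,
    Marker,
    PairRecord,
    Panel,
    Profile,
    Sex,
)

__all__ = [
    "SimConfig",
    "SimResult",
    "sample_founder",
    "transmit",
    "simulate_pairs",
    "synthetic_frequency_table",
    "GP_LINEAGES",
]

GP_LINEAGES = (
    "paternal-grandfather",
    "paternal-grandmother",
    "maternal-grandfather",
    "maternal-grandmother",
)

PAIR_TYPES = ("B-S", "B-B", "S-S", "GP-GC")

# Internal tagged allele: (label, origin_id). Tags survive mutation, so IBD
# bookkeeping reflects descent, not state.
_Tagged = tuple[str, int]


@dataclass
class SimConfig:
    panel: Panel
    freqs: FrequencyTable
    pair_type: str  # one of PAIR_TYPES
    n_related: int
    n_unrelated: int
    seed: int
    lineage: Optional[str] = None  # required for GP-GC
    grandchild_sex: Optional[Sex] = None  # GP-GC only; default female
    mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.pair_type not in PAIR_TYPES:
            raise KinshipDataError(f"unknown pair type {self.pair_type!r}")
        if self.pair_type == "GP-GC":
            if self.lineage not in GP_LINEAGES:
                raise KinshipDataError(
                    f"GP-GC requires a lineage from {GP_LINEAGES}, got {self.lineage!r}"
                )
            if self.grandchild_sex is None:
                self.grandchild_sex = Sex.FEMALE
        if self.mutation_rate < 0:
            raise KinshipDataError("mutation_rate must be >= 0")
        missing = [m.name for m in self.panel if m.name not in self.freqs.markers()]
        if missing:
            raise KinshipDataError(f"frequency table missing panel markers: {missing}")


@dataclass
class SimResult:
    pairs: list[PairRecord]
    #: Per related pair: marker name -> IBD allele count; aligned with the
    #: related entries of ``pairs`` in order.
    ibd: list[dict[str, int]]
    pair_ids: list[str]

    @property
    def profiles(self) -> list[Profile]:
        out = []
        for p in self.pairs:
            out.extend([p.profile_a, p.profile_b])
        return out


class _TagSource:
    def __init__(self) -> None:
        self._counter = itertools.count()

    def new(self) -> int:
        return next(self._counter)


def _draw_allele(freqs: dict[str, float], rng: np.random.Generator) -> str:
    alleles = list(freqs)
    probs = np.array([freqs[a] for a in alleles])
    return alleles[rng.choice(len(alleles), p=probs / probs.sum())]


def _founder_tagged(
    freqs: FrequencyTable, sex: Sex, panel: Panel, rng: np.random.Generator, tags: _TagSource
) -> dict[str, tuple[_Tagged, ...]]:
    geno: dict[str, tuple[_Tagged, ...]] = {}
    for marker in panel:
        n = 2 if (marker.chromosome_class is ChromosomeClass.AUTOSOMAL or sex is Sex.FEMALE) else 1
        geno[marker.name] = tuple(
            (_draw_allele(freqs[marker.name], rng), tags.new()) for _ in range(n)
        )
    return geno


def _strip(tagged: dict[str, tuple[_Tagged, ...]]) -> dict[str, tuple[str, ...]]:
    return {m: tuple(sorted(a for a, _ in g)) for m, g in tagged.items()}


def _mutate_label(label: str, rng: np.random.Generator) -> str:
    """Single-step mutation: repeat count +/-1, fractional microvariant part kept."""
    whole, dot, frac = label.partition(".")
    step = int(rng.integers(0, 2)) * 2 - 1
    new_whole = max(1, int(whole) + step)
    return f"{new_whole}{dot}{frac}" if dot else str(new_whole)


def _transmit_tagged(
    parent_geno: tuple[_Tagged, ...],
    parent_sex: Sex,
    child_sex: Sex,
    chromosome_class: ChromosomeClass,
    rng: np.random.Generator,
    mutation_rate: float = 0.0,
) -> Optional[_Tagged]:
    if chromosome_class is ChromosomeClass.X_LINKED and parent_sex is Sex.MALE:
        if child_sex is Sex.MALE:
            raise KinshipDataError("father-to-son X transmission does not occur")
        allele = parent_geno[0]  # hemizygous father: deterministic to daughters
    else:
        allele = parent_geno[int(rng.integers(0, len(parent_geno)))]
    if mutation_rate > 0 and rng.random() < mutation_rate:
        allele = (_mutate_label(allele[0], rng), allele[1])
    return allele


def sample_founder(
    freqs: FrequencyTable, sex: Sex, panel: Panel, rng: np.random.Generator,
    sample_id: str = "founder",
) -> Profile:
    """Draw an unrelated founder profile from the allele frequencies."""
    tagged = _founder_tagged(freqs, sex, panel, rng, _TagSource())
    return Profile(sample_id, sex, _strip(tagged))


def transmit(
    parent: Profile,
    child_sex: Sex,
    marker: Marker,
    rng: np.random.Generator,
    mutation_rate: float = 0.0,
) -> str:
    """One Mendelian transmission of ``marker`` from ``parent`` to a child.

    Raises for the structurally impossible father-to-son X transmission.
    """
    geno = tuple((a, i) for i, a in enumerate(parent.genotype(marker.name)))
    allele = _transmit_tagged(
        geno, parent.sex, child_sex, marker.chromosome_class, rng, mutation_rate
    )
    return allele[0]


def _child_tagged(
    father: dict[str, tuple[_Tagged, ...]],
    mother: dict[str, tuple[_Tagged, ...]],
    child_sex: Sex,
    panel: Panel,
    rng: np.random.Generator,
    mutation_rate: float,
) -> dict[str, tuple[_Tagged, ...]]:
    geno: dict[str, tuple[_Tagged, ...]] = {}
    for marker in panel:
        maternal = _transmit_tagged(
            mother[marker.name], Sex.FEMALE, child_sex, marker.chromosome_class, rng, mutation_rate
        )
        if marker.chromosome_class is ChromosomeClass.X_LINKED and child_sex is Sex.MALE:
            geno[marker.name] = (maternal,)
        else:
            paternal = _transmit_tagged(
                father[marker.name], Sex.MALE, child_sex, marker.chromosome_class, rng, mutation_rate
            )
            geno[marker.name] = (paternal, maternal)
    return geno


def _ibd_counts(
    a: dict[str, tuple[_Tagged, ...]], b: dict[str, tuple[_Tagged, ...]]
) -> dict[str, int]:
    return {
        m: sum((Counter(t for _, t in a[m]) & Counter(t for _, t in b[m])).values())
        for m in a
    }


def _sibling_sexes(pair_type: str) -> tuple[Sex, Sex]:
    return {
        "B-S": (Sex.MALE, Sex.FEMALE),
        "B-B": (Sex.MALE, Sex.MALE),
        "S-S": (Sex.FEMALE, Sex.FEMALE),
    }[pair_type]


def _hypothesis(config: SimConfig) -> str:
    if config.pair_type != "GP-GC":
        return config.pair_type
    if config.panel.chromosome_class is ChromosomeClass.AUTOSOMAL:
        return "GP-GC-autosomal"
    side = config.lineage.split("-")[0]  # "paternal" | "maternal"
    return f"GP-GC-{side}-X"


def _grandparent_sexes(lineage: str) -> tuple[Sex, Sex]:
    """(sex of the named grandparent, sex of the linking parent)."""
    side, _, gp = lineage.partition("-")
    gp_sex = Sex.MALE if gp == "grandfather" else Sex.FEMALE
    parent_sex = Sex.MALE if side == "paternal" else Sex.FEMALE
    return gp_sex, parent_sex


def _related_pair_tagged(
    config: SimConfig, rng: np.random.Generator, tags: _TagSource
) -> tuple[dict, Sex, dict, Sex]:
    """Build one related pair; returns (tagged_a, sex_a, tagged_b, sex_b)."""
    panel, freqs, mu = config.panel, config.freqs, config.mutation_rate
    if config.pair_type in ("B-S", "B-B", "S-S"):
        father = _founder_tagged(freqs, Sex.MALE, panel, rng, tags)
        mother = _founder_tagged(freqs, Sex.FEMALE, panel, rng, tags)
        sex_a, sex_b = _sibling_sexes(config.pair_type)
        child_a = _child_tagged(father, mother, sex_a, panel, rng, mu)
        child_b = _child_tagged(father, mother, sex_b, panel, rng, mu)
        return child_a, sex_a, child_b, sex_b

    # GP-GC: three-generation chain through the configured lineage.
    gp_sex, parent_sex = _grandparent_sexes(config.lineage)
    gc_sex = config.grandchild_sex
    if (
        panel.chromosome_class is ChromosomeClass.X_LINKED
        and parent_sex is Sex.MALE
        and gc_sex is Sex.MALE
    ):
        raise KinshipDataError(
            "paternal-lineage X simulation requires a granddaughter: "
            "fathers do not transmit X to sons"
        )
    grandfather = _founder_tagged(freqs, Sex.MALE, panel, rng, tags)
    grandmother = _founder_tagged(freqs, Sex.FEMALE, panel, rng, tags)
    named_gp = grandfather if gp_sex is Sex.MALE else grandmother
    parent = _child_tagged(grandfather, grandmother, parent_sex, panel, rng, mu)
    spouse = _founder_tagged(
        freqs, Sex.FEMALE if parent_sex is Sex.MALE else Sex.MALE, panel, rng, tags
    )
    father_g, mother_g = (parent, spouse) if parent_sex is Sex.MALE else (spouse, parent)
    grandchild = _child_tagged(father_g, mother_g, gc_sex, panel, rng, mu)
    return named_gp, gp_sex, grandchild, gc_sex


def _unrelated_sexes(config: SimConfig) -> tuple[Sex, Sex]:
    if config.pair_type != "GP-GC":
        return _sibling_sexes(config.pair_type)
    gp_sex, _ = _grandparent_sexes(config.lineage)
    return gp_sex, config.grandchild_sex


def simulate_pairs(config: SimConfig) -> SimResult:
    """Generate related pairs by explicit pedigree construction plus unrelated
    founder pairs, reproducibly from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    tags = _TagSource()
    hypothesis = _hypothesis(config)
    pairs: list[PairRecord] = []
    ibd: list[dict[str, int]] = []
    pair_ids: list[str] = []

    for i in range(config.n_related):
        ta, sex_a, tb, sex_b = _related_pair_tagged(config, rng, tags)
        pid = f"R{i:04d}"
        pa = Profile(f"{pid}a", sex_a, _strip(ta))
        pb = Profile(f"{pid}b", sex_b, _strip(tb))
        pairs.append(PairRecord(pa, pb, hypothesis, "related"))
        ibd.append(_ibd_counts(ta, tb))
        pair_ids.append(pid)

    sex_a, sex_b = _unrelated_sexes(config)
    for i in range(config.n_unrelated):
        pid = f"U{i:04d}"
        pa = sample_founder(config.freqs, sex_a, config.panel, rng, f"{pid}a")
        pb = sample_founder(config.freqs, sex_b, config.panel, rng, f"{pid}b")
        pairs.append(PairRecord(pa, pb, hypothesis, "unrelated"))
        pair_ids.append(pid)

    return SimResult(pairs=pairs, ibd=ibd, pair_ids=pair_ids)


def synthetic_frequency_table(
    panel: Panel,
    alleles_per_locus: int = 8,
    concentration: float = 1.0,
    seed: int = 0,
    min_allele: int = 6,
) -> FrequencyTable:
    """Symmetric-Dirichlet allele frequencies per locus, reproducible by seed.

    Allele labels are consecutive integer repeat counts starting at
    ``min_allele``, matching typical forensic STR ranges.
    """
    if alleles_per_locus < 2:
        raise KinshipDataError("alleles_per_locus must be >= 2")
    rng = np.random.default_rng(seed)
    labels = [str(min_allele + j) for j in range(alleles_per_locus)]
    freqs = {}
    for marker in panel:
        p = rng.dirichlet(np.full(alleles_per_locus, concentration))
        # Guard against zero-probability alleles from extreme Dirichlet draws.
        p = np.clip(p, 1e-9, None)
        p = p / p.sum()
        freqs[marker.name] = dict(zip(labels, p.tolist()))
    return FrequencyTable(freqs)
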