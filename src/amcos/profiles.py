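"""Data model and I/O for STR panels, genotype profiles, pairs, and allele frequencies.

Alleles are repeat-count labels kept as exact decimal strings ("9", "9.3");
microvariants never collide with integer alleles through numeric coercion.
Autosomal genotypes always carry two alleles (homozygotes as two explicit
copies); X-linked genotypes carry two alleles for females and one for
hemizygous males.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "ChromosomeClass",
    "Sex",
    "Marker",
    "Panel",
    "Profile",
    "PairRecord",
    "FrequencyTable",
    "KinshipDataError",
    "IncompleteProfileError",
    "PloidyError",
    "UnnormalizedFrequencyError",
    "IDENTIFILER15",
    "ARGUS_X12",
    "PANELS",
    "get_panel",
    "read_genotype_table",
    "write_genotype_table",
    "read_frequency_table",
    "write_frequency_table",
    "HYPOTHESES",
]


class KinshipDataError(ValueError):
    """Base class for genotype/pair data validation errors."""


class IncompleteProfileError(KinshipDataError):
    """A sample is missing a genotype at a panel marker."""


class PloidyError(KinshipDataError):
    """Allele count at a locus is inconsistent with chromosome class and sex."""


class UnnormalizedFrequencyError(KinshipDataError):
    """Per-locus allele frequencies do not sum to 1."""


class ChromosomeClass(str, enum.Enum):
    AUTOSOMAL = "autosomal"
    X_LINKED = "x_linked"


class Sex(str, enum.Enum):
    MALE = "M"
    FEMALE = "F"

    @classmethod
    def parse(cls, code: str) -> "Sex":
        c = str(code).strip().upper()
        if c in ("M", "MALE"):
            return cls.MALE
        if c in ("F", "FEMALE"):
            return cls.FEMALE
        raise KinshipDataError(f"unknown sex code: {code!r} (expected M or F)")


@dataclass(frozen=True)
class Marker:
    name: str
    chromosome_class: ChromosomeClass

    def __post_init__(self) -> None:
        if not self.name:
            raise KinshipDataError("marker name must be nonempty")


@dataclass(frozen=True)
class Panel:
    """An ordered, homogeneous set of STR markers."""

    name: str
    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        if not self.markers:
            raise KinshipDataError("panel must contain at least one marker")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise KinshipDataError(f"duplicate marker names in panel {self.name}")
        classes = {m.chromosome_class for m in self.markers}
        if len(classes) != 1:
            raise KinshipDataError(
                f"panel {self.name} mixes chromosome classes: {sorted(c.value for c in classes)}"
            )

    @property
    def chromosome_class(self) -> ChromosomeClass:
        return self.markers[0].chromosome_class

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self) -> Iterator[Marker]:
        return iter(self.markers)

    def __contains__(self, name: object) -> bool:
        return name in self.marker_names


def _panel(name: str, chrom: ChromosomeClass, markers: Iterable[str]) -> Panel:
    return Panel(name, tuple(Marker(m, chrom) for m in markers))


#: AmpFlSTR Identifiler 15-locus autosomal panel.
IDENTIFILER15 = _panel(
    "identifiler15",
    ChromosomeClass.AUTOSOMAL,
    (
        "D8S1179", "D21S11", "D7S820", "CSF1PO", "D3S1358", "TH01", "D13S317",
        "D16S539", "D2S1338", "D19S433", "vWA", "TPOX", "D18S51", "D5S818", "FGA",
    ),
)

#: Investigator Argus X-12 12-locus X-chromosomal panel.
ARGUS_X12 = _panel(
    "argusx12",
    ChromosomeClass.X_LINKED,
    (
        "DXS10103", "DXS8378", "DXS7132", "DXS10134", "DXS10074", "DXS10101",
        "DXS10135", "DXS7423", "DXS10146", "DXS10079", "HPRTB", "DXS10148",
    ),
)

PANELS: dict[str, Panel] = {p.name: p for p in (IDENTIFILER15, ARGUS_X12)}


def get_panel(name: str) -> Panel:
    try:
        return PANELS[name]
    except KeyError:
        raise KinshipDataError(
            f"unknown panel {name!r}; built-in panels: {sorted(PANELS)}"
        ) from None


def expected_ploidy(marker: Marker, sex: Sex) -> int:
    if marker.chromosome_class is ChromosomeClass.AUTOSOMAL:
        return 2
    return 2 if sex is Sex.FEMALE else 1


@dataclass
class Profile:
    """One individual's STR genotypes: per-locus allele multiset keyed by marker name."""

    sample_id: str
    sex: Sex
    genotypes: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def genotype(self, marker_name: str) -> tuple[str, ...]:
        try:
            return self.genotypes[marker_name]
        except KeyError:
            raise IncompleteProfileError(
                f"incomplete profile: sample {self.sample_id!r} has no genotype "
                f"at marker {marker_name!r}"
            ) from None

    def validate(self, panel: Panel) -> None:
        """Check completeness and ploidy against ``panel``; raise on violation."""
        for marker in panel:
            geno = self.genotype(marker.name)
            want = expected_ploidy(marker, self.sex)
            if len(geno) != want:
                raise PloidyError(
                    f"ploidy error: sample {self.sample_id!r} ({self.sex.value}) has "
                    f"{len(geno)} allele(s) at {marker.name} "
                    f"({marker.chromosome_class.value}); expected {want}"
                )
            if any(not a for a in geno):
                raise PloidyError(
                    f"ploidy error: sample {self.sample_id!r} has an empty allele "
                    f"label at {marker.name}"
                )


# Kinship hypotheses: pair ordering is (elder, younger) for GP-GC types.
HYPOTHESES = (
    "B-S",
    "B-B",
    "S-S",
    "GP-GC-autosomal",
    "GP-GC-paternal-X",
    "GP-GC-maternal-X",
)

# Sex constraints per hypothesis: (allowed sex multisets) or None for unconstrained,
# expressed as a predicate on (sex_a, sex_b).
def _sexes_ok(hypothesis: str, sex_a: Sex, sex_b: Sex) -> bool:
    if hypothesis == "B-S":
        return {sex_a, sex_b} == {Sex.MALE, Sex.FEMALE}
    if hypothesis == "B-B":
        return sex_a is Sex.MALE and sex_b is Sex.MALE
    if hypothesis == "S-S":
        return sex_a is Sex.FEMALE and sex_b is Sex.FEMALE
    if hypothesis == "GP-GC-paternal-X":
        # X sharing through the father requires a female grandparent (the
        # paternal grandmother) and a granddaughter.
        return sex_a is Sex.FEMALE and sex_b is Sex.FEMALE
    return True  # GP-GC-autosomal, GP-GC-maternal-X: unconstrained


@dataclass
class PairRecord:
    """An ordered pair of profiles with a kinship hypothesis and ground truth."""

    profile_a: Profile
    profile_b: Profile
    hypothesis: str
    truth: str  # "related" | "unrelated"

    def __post_init__(self) -> None:
        if self.hypothesis not in HYPOTHESES:
            raise KinshipDataError(
                f"unknown hypothesis {self.hypothesis!r}; expected one of {HYPOTHESES}"
            )
        if self.truth not in ("related", "unrelated"):
            raise KinshipDataError(f"truth must be 'related' or 'unrelated', got {self.truth!r}")
        if not _sexes_ok(self.hypothesis, self.profile_a.sex, self.profile_b.sex):
            raise KinshipDataError(
                f"sexes ({self.profile_a.sex.value}, {self.profile_b.sex.value}) "
                f"inconsistent with hypothesis {self.hypothesis}"
            )


_GENO_COLUMNS = ["Sample", "Sex", "Marker", "Allele1", "Allele2"]


def read_genotype_table(source, panel: Panel) -> list[Profile]:
    """Parse a long-format genotype table (one row per sample x marker).

    Expected columns: Sample, Sex, Marker, Allele1, Allele2 (CSV or TSV,
    delimiter sniffed). Allele2 may be blank only for males at X loci.
    """
    df = pd.read_csv(source, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = [c for c in _GENO_COLUMNS if c not in df.columns]
    if missing:
        raise KinshipDataError(f"genotype table missing column(s): {missing}")

    profiles: dict[str, Profile] = {}
    for row in df.itertuples(index=False):
        sample = str(row.Sample).strip()
        sex = Sex.parse(row.Sex)
        marker_name = str(row.Marker).strip()
        if marker_name not in panel:
            raise KinshipDataError(
                f"unknown marker {marker_name!r} for sample {sample!r}: "
                f"not in panel {panel.name}"
            )
        marker = panel.markers[panel.marker_names.index(marker_name)]
        a1 = str(row.Allele1).strip()
        a2 = str(row.Allele2).strip()
        if not a1:
            raise PloidyError(
                f"ploidy error: sample {sample!r} has blank Allele1 at {marker_name}"
            )
        if a2:
            geno = tuple(sorted((a1, a2)))
        else:
            geno = (a1,)
        want = expected_ploidy(marker, sex)
        if len(geno) != want:
            kind = "male X locus with two alleles" if want == 1 else "missing Allele2"
            raise PloidyError(
                f"ploidy error ({kind}): sample {sample!r} ({sex.value}) at "
                f"{marker_name}: got {len(geno)} allele(s), expected {want}"
            )
        prof = profiles.get(sample)
        if prof is None:
            prof = profiles[sample] = Profile(sample, sex)
        elif prof.sex is not sex:
            raise KinshipDataError(f"sample {sample!r} has inconsistent sex codes")
        if marker_name in prof.genotypes:
            raise KinshipDataError(f"duplicate row: sample {sample!r}, marker {marker_name}")
        prof.genotypes[marker_name] = geno

    out = list(profiles.values())
    for prof in out:
        prof.validate(panel)
    return out


def write_genotype_table(profiles: Iterable[Profile], dest, panel: Panel, sep: str = ",") -> None:
    """Write profiles in the long-format dialect read by :func:`read_genotype_table`."""
    rows = []
    for prof in profiles:
        for marker in panel:
            geno = prof.genotype(marker.name)
            rows.append(
                {
                    "Sample": prof.sample_id,
                    "Sex": prof.sex.value,
                    "Marker": marker.name,
                    "Allele1": geno[0],
                    "Allele2": geno[1] if len(geno) > 1 else "",
                }
            )
    pd.DataFrame(rows, columns=_GENO_COLUMNS).to_csv(dest, sep=sep, index=False)


@dataclass
class FrequencyTable:
    """Per-locus allele frequency maps; each locus sums to 1 (within 1e-6)."""

    frequencies: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for marker, freqs in self.frequencies.items():
            if not freqs:
                raise UnnormalizedFrequencyError(f"no alleles for marker {marker!r}")
            if any(f <= 0 for f in freqs.values()):
                raise UnnormalizedFrequencyError(
                    f"non-positive frequency at marker {marker!r}"
                )
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-6:
                raise UnnormalizedFrequencyError(
                    f"unnormalized frequencies at marker {marker!r}: sum {total:.6f}"
                )

    def markers(self) -> tuple[str, ...]:
        return tuple(self.frequencies)

    def __getitem__(self, marker: str) -> dict[str, float]:
        return self.frequencies[marker]


def read_frequency_table(source, panel: Panel, renormalize: bool = False) -> FrequencyTable:
    """Parse a Marker/Allele/Frequency table restricted to ``panel``.

    Loci whose frequencies sum outside [1 - 1e-4, 1 + 1e-4] raise
    :class:`UnnormalizedFrequencyError` unless ``renormalize`` is set, in which
    case each locus is rescaled to sum exactly to 1.
    """
    df = pd.read_csv(source, sep=None, engine="python", dtype={"Marker": str, "Allele": str})
    for col in ("Marker", "Allele", "Frequency"):
        if col not in df.columns:
            raise KinshipDataError(f"frequency table missing column {col!r}")
    freqs: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        marker = str(row.Marker).strip()
        if marker not in panel:
            raise KinshipDataError(f"frequency table marker {marker!r} not in panel {panel.name}")
        freqs.setdefault(marker, {})[str(row.Allele).strip()] = float(row.Frequency)
    for marker, table in freqs.items():
        total = sum(table.values())
        if not renormalize and abs(total - 1.0) > 1e-4:
            raise UnnormalizedFrequencyError(
                f"unnormalized frequencies at marker {marker!r}: sum {total:.6f} "
                f"(pass renormalize=True to rescale)"
            )
        freqs[marker] = {a: f / total for a, f in table.items()}
    return FrequencyTable(freqs)


def write_frequency_table(table: FrequencyTable, dest, sep: str = ",") -> None:
    rows = [
        {"Marker": m, "Allele": a, "Frequency": f}
        for m in table.markers()
        for a, f in table[m].items()
    ]
    pd.DataFrame(rows, columns=["Marker", "Allele", "Frequency"]).to_csv(dest, sep=sep, index=False)
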