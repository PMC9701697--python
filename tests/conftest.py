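import io

import numpy as np
import pytest

from amcos import (
    ARGUS_X12,
    IDENTIFILER15,
    ChromosomeClass,
    Marker,
    PairRecord,
    Panel,
    Profile,
    Sex,
)


@pytest.fixture
def auto3():
    """Tiny 3-locus autosomal panel for hand-checkable scores."""
    return Panel("auto3", tuple(Marker(n, ChromosomeClass.AUTOSOMAL) for n in ("L1", "L2", "L3")))


@pytest.fixture
def x2():
    return Panel("x2", tuple(Marker(n, ChromosomeClass.X_LINKED) for n in ("X1", "X2")))


@pytest.fixture
def identifiler():
    return IDENTIFILER15


@pytest.fixture
def argusx():
    return ARGUS_X12


def make_profile(sample_id, sex, panel, genotypes):
    """Build a Profile from a list of genotype tuples ordered like the panel."""
    return Profile(
        sample_id,
        sex,
        {m.name: tuple(sorted(g)) for m, g in zip(panel.markers, genotypes)},
    )


@pytest.fixture
def auto_pair_factory(auto3):
    def factory(genos_a, genos_b, truth="related"):
        a = make_profile("a", Sex.MALE, auto3, genos_a)
        b = make_profile("b", Sex.FEMALE, auto3, genos_b)
        return PairRecord(a, b, "B-S", truth)

    return factory


@pytest.fixture
def rng():
    return np.random.default_rng(17)


def genotype_csv(rows):
    """Build an in-memory genotype CSV from (sample, sex, marker, a1, a2) rows."""
    lines = ["Sample,Sex,Marker,Allele1,Allele2"]
    lines += [",".join(str(x) for x in row) for row in rows]
    return io.StringIO("\n".join(lines))
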