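"""Pedigree simulator: founder sampling, Mendelian/X transmission, IBD bookkeeping."""

import numpy as np
import pytest

from amcos import (
    ARGUS_X12,
    IDENTIFILER15,
    ChromosomeClass,
    FrequencyTable,
    KinshipDataError,
    Marker,
    Panel,
    Sex,
    SimConfig,
    sample_founder,
    simulate_pairs,
    synthetic_frequency_table,
    transmit,
)
from amcos.scoring import locus_sharing, score_pair

from conftest import make_profile


@pytest.fixture
def auto1():
    return Panel("auto1", (Marker("L1", ChromosomeClass.AUTOSOMAL),))


@pytest.fixture
def skewed_freqs(auto1):
    return FrequencyTable({"L1": {"8": 0.6, "9": 0.3, "10": 0.1}})


class TestFounder:
    def test_fixed_allele_gives_homozygote(self, auto1, rng):
        freqs = FrequencyTable({"L1": {"12": 1.0}})
        prof = sample_founder(freqs, Sex.FEMALE, auto1, rng)
        assert prof.genotype("L1") == ("12", "12")

    def test_male_founder_hemizygous_on_x(self, x2, rng):
        freqs = FrequencyTable({m.name: {"7": 0.5, "8": 0.5} for m in x2})
        prof = sample_founder(freqs, Sex.MALE, x2, rng)
        for m in x2:
            assert len(prof.genotype(m.name)) == 1

    def test_founder_allele_proportions_match_frequencies(self, auto1, skewed_freqs, rng):
        counts = {"8": 0, "9": 0, "10": 0}
        n = 2500
        for _ in range(n):
            for a in sample_founder(skewed_freqs, Sex.MALE, auto1, rng).genotype("L1"):
                counts[a] += 1
        for allele, freq in skewed_freqs["L1"].items():
            assert counts[allele] / (2 * n) == pytest.approx(freq, abs=0.02)


class TestTransmit:
    def test_homozygous_parent_transmits_deterministically(self, auto1, rng):
        parent = make_profile("p", Sex.FEMALE, auto1, [("9", "9")])
        marker = auto1.markers[0]
        assert all(transmit(parent, Sex.MALE, marker, rng) == "9" for _ in range(20))

    def test_father_daughter_x_is_deterministic(self, x2, rng):
        father = make_profile("f", Sex.MALE, x2, [("10",), ("22.2",)])
        assert transmit(father, Sex.FEMALE, x2.markers[0], rng) == "10"
        assert transmit(father, Sex.FEMALE, x2.markers[1], rng) == "22.2"

    def test_father_son_x_is_structural_error(self, x2, rng):
        father = make_profile("f", Sex.MALE, x2, [("10",), ("11",)])
        with pytest.raises(KinshipDataError, match="father-to-son"):
            transmit(father, Sex.MALE, x2.markers[0], rng)

    def test_heterozygous_transmission_is_fair(self, auto1, rng):
        parent = make_profile("p", Sex.FEMALE, auto1, [("8", "9")])
        marker = auto1.markers[0]
        n = 10_000
        eights = sum(transmit(parent, Sex.MALE, marker, rng) == "8" for _ in range(n))
        assert eights / n == pytest.approx(0.5, abs=0.02)

    def test_mutation_steps_one_repeat_and_keeps_microvariant(self, auto1, rng):
        parent = make_profile("p", Sex.FEMALE, auto1, [("9.3", "9.3")])
        marker = auto1.markers[0]
        seen = {transmit(parent, Sex.MALE, marker, rng, mutation_rate=1.0) for _ in range(50)}
        assert seen <= {"8.3", "10.3"} and len(seen) == 2


def _config(panel, pair_type, n_rel, n_unrel, seed, **kw):
    freqs = synthetic_frequency_table(panel, alleles_per_locus=10, concentration=1.0, seed=7)
    return SimConfig(
        panel=panel, freqs=freqs, pair_type=pair_type,
        n_related=n_rel, n_unrelated=n_unrel, seed=seed, **kw
    )


class TestSimulatePairs:
    def test_reproducible_by_seed(self):
        cfg = _config(IDENTIFILER15, "B-S", 5, 5, seed=42)
        a = simulate_pairs(cfg)
        b = simulate_pairs(_config(IDENTIFILER15, "B-S", 5, 5, seed=42))
        for pa, pb in zip(a.pairs, b.pairs):
            assert pa.profile_a.genotypes == pb.profile_a.genotypes
            assert pa.profile_b.genotypes == pb.profile_b.genotypes

    def test_full_sibling_ibd_proportions(self):
        # Full sibs share 0/1/2 alleles IBD with probability 1/4, 1/2, 1/4.
        cfg = _config(IDENTIFILER15, "B-S", 700, 0, seed=9)
        result = simulate_pairs(cfg)
        counts = np.zeros(3)
        for record in result.ibd:
            for v in record.values():
                counts[v] += 1
        props = counts / counts.sum()
        assert counts.sum() == 700 * 15
        assert props[0] == pytest.approx(0.25, abs=0.02)
        assert props[1] == pytest.approx(0.50, abs=0.02)
        assert props[2] == pytest.approx(0.25, abs=0.02)

    def test_ibd_never_exceeds_ibs(self):
        for panel, pair_type, kw in (
            (IDENTIFILER15, "B-S", {}),
            (ARGUS_X12, "S-S", {}),
            (ARGUS_X12, "GP-GC", {"lineage": "maternal-grandmother"}),
        ):
            cfg = _config(panel, pair_type, 30, 0, seed=13, **kw)
            result = simulate_pairs(cfg)
            for pair, ibd in zip(result.pairs, result.ibd):
                ibs = locus_sharing(pair, panel)
                for marker, n_ibd in ibd.items():
                    assert n_ibd <= ibs[marker]

    def test_sisters_reach_full_x_panel_oam(self):
        cfg = _config(ARGUS_X12, "S-S", 40, 0, seed=3)
        result = simulate_pairs(cfg)
        for pair in result.pairs:
            assert score_pair(pair, ARGUS_X12).oam == 12

    def test_paternal_grandmother_granddaughter_obligate_sharing(self):
        cfg = _config(ARGUS_X12, "GP-GC", 40, 0, seed=21, lineage="paternal-grandmother")
        result = simulate_pairs(cfg)
        for pair in result.pairs:
            assert pair.hypothesis == "GP-GC-paternal-X"
            assert score_pair(pair, ARGUS_X12).oam == 12

    def test_brothers_share_maternal_x_half_the_time(self):
        cfg = _config(ARGUS_X12, "B-B", 850, 0, seed=5)
        result = simulate_pairs(cfg)
        shared = sum(v == 1 for record in result.ibd for v in record.values())
        total = sum(len(record) for record in result.ibd)
        assert total == 850 * 12
        assert shared / total == pytest.approx(0.5, abs=0.02)

    def test_unrelated_pairs_have_zero_ibd_and_lower_scores(self):
        cfg = _config(ARGUS_X12, "B-B", 60, 60, seed=8)
        result = simulate_pairs(cfg)
        # IBD records exist only for related pairs (unrelated share nothing by descent).
        assert len(result.ibd) == 60
        rel = [score_pair(p, ARGUS_X12).oam for p in result.pairs if p.truth == "related"]
        unrel = [score_pair(p, ARGUS_X12).oam for p in result.pairs if p.truth == "unrelated"]
        assert np.mean(rel) > np.mean(unrel) + 2

    def test_paternal_x_to_grandson_rejected(self):
        with pytest.raises(KinshipDataError, match="granddaughter"):
            cfg = _config(
                ARGUS_X12, "GP-GC", 1, 0, seed=1,
                lineage="paternal-grandmother", grandchild_sex=Sex.MALE,
            )
            simulate_pairs(cfg)

    def test_gp_gc_requires_lineage(self):
        with pytest.raises(KinshipDataError, match="lineage"):
            _config(IDENTIFILER15, "GP-GC", 1, 1, seed=1)


class TestSyntheticFrequencies:
    def test_deterministic_and_normalized(self):
        a = synthetic_frequency_table(ARGUS_X12, seed=99)
        b = synthetic_frequency_table(ARGUS_X12, seed=99)
        assert a.frequencies == b.frequencies
        for marker in a.markers():
            assert sum(a[marker].values()) == pytest.approx(1.0, abs=1e-9)

    def test_large_concentration_approaches_uniform(self):
        table = synthetic_frequency_table(ARGUS_X12, alleles_per_locus=5,
                                          concentration=5000.0, seed=1)
        for marker in table.markers():
            for f in table[marker].values():
                assert f == pytest.approx(0.2, abs=0.03)

    def test_minimum_allele_count(self):
        with pytest.raises(KinshipDataError):
            synthetic_frequency_table(ARGUS_X12, alleles_per_locus=1)
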