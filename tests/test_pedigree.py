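"""Mendelian consistency, missing-parent inference and phasing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlrpop.pedigree import (
    GenotypeTable,
    Pedigree,
    infer_missing_parent,
    min_offspring_for,
    nondetection_probability,
    phase_by_pedigree,
    trio_consistent,
)
from tlrpop.seqvar import SnpSite
from tlrpop.synthdata import SimConfig, simulate_population

SITE = SnpSite("l", 1, ("A", "T"))
GENOTYPES = [("A", "A"), ("A", "T"), ("T", "T")]


class TestTrioConsistent:
    def test_simple_cross(self):
        assert trio_consistent(("A", "T"), ("A", "A"), ("T", "T"))

    def test_impossible_transmission(self):
        assert not trio_consistent(("A", "A"), ("T", "T"), ("A", "T"))

    def test_exhaustive_against_transmission_enumeration(self):
        """All 27 diallelic trios vs direct enumeration of the 4 possible
        (dam allele, sire allele) transmission events."""
        for off, dam, sire in itertools.product(GENOTYPES, repeat=3):
            oracle = any(
                tuple(sorted((d, s))) == tuple(sorted(off))
                for d in dam
                for s in sire
            )
            assert trio_consistent(off, dam, sire) == oracle


class TestNondetectionProbability:
    def test_five_offspring_meet_design_threshold(self):
        assert nondetection_probability(5) == pytest.approx(0.03125)
        assert nondetection_probability(5) < 0.035

    def test_no_offspring_no_information(self):
        assert nondetection_probability(0) == 1.0

    def test_fifteen(self):
        assert nondetection_probability(15) == pytest.approx(3.0517578125e-5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            nondetection_probability(-1)

    def test_monte_carlo_transmission_oracle(self):
        """Fraction of 1e6 simulated 15-offspring broods in which a het
        parent's second allele goes unobserved, vs (1/2)^15, within 3 SE."""
        rng = np.random.default_rng(2024)
        n, reps = 15, 10**6
        transmissions = rng.integers(0, 2, size=(reps, n))
        miss = np.all(transmissions == 0, axis=1).mean()
        expected = nondetection_probability(n)
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(miss - expected) <= 3 * se

    @pytest.mark.parametrize(
        "alpha,expected", [(0.035, 5), (0.5, 2), (1e-6, 20)]
    )
    def test_min_offspring_design_inverse(self, alpha, expected):
        assert min_offspring_for(alpha) == expected

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 2.0])
    def test_min_offspring_rejects_bad_alpha(self, alpha):
        with pytest.raises(ValueError):
            min_offspring_for(alpha)


class TestInferMissingParent:
    def test_homozygous_offspring_forces_unique_parent(self):
        entry = infer_missing_parent(
            SITE, ("A", "A"), [("A", "T"), ("A", "T"), ("A", "A")]
        )
        assert entry.status == "unique"
        assert entry.consistent == (("A", "T"),)

    def test_all_het_brood_is_ambiguous(self):
        entry = infer_missing_parent(SITE, ("A", "T"), [("A", "T")] * 5)
        assert entry.status == "ambiguous"
        assert set(entry.consistent) == {("A", "A"), ("A", "T"), ("T", "T")}
        assert entry.nondetection_prob == pytest.approx(0.03125)

    def test_single_homozygous_offspring(self):
        entry = infer_missing_parent(SITE, ("A", "A"), [("A", "A")])
        assert entry.status == "ambiguous"
        assert set(entry.consistent) == {("A", "A"), ("A", "T")}

    def test_impossible_brood_flagged_inconsistent(self):
        entry = infer_missing_parent(SITE, ("A", "A"), [("T", "T")])
        assert entry.status == "inconsistent"
        assert entry.consistent == ()

    def test_joint_inference_over_both_parents(self):
        entry = infer_missing_parent(SITE, None, [("A", "A"), ("T", "T")])
        assert entry.joint
        # each parent pair must be able to produce both an AA and a TT child
        for g1, g2 in entry.consistent:
            assert trio_consistent(("A", "A"), g1, g2)
            assert trio_consistent(("T", "T"), g1, g2)

    @given(
        known=st.sampled_from(GENOTYPES),
        offspring=st.lists(st.sampled_from(GENOTYPES), min_size=1, max_size=6),
    )
    @settings(deadline=None, derandomize=True)
    def test_equals_brute_force_filter(self, known, offspring):
        """Inference output equals filtering every candidate genotype through
        trio_consistent over the whole brood."""
        entry = infer_missing_parent(SITE, known, offspring)
        oracle = tuple(
            g for g in GENOTYPES
            if all(trio_consistent(o, known, g) for o in offspring)
        )
        assert entry.consistent == oracle

    @pytest.mark.parametrize("n_offspring", [1, 3, 5])
    def test_allele_miss_rate_recovers_half_power_law(self, n_offspring):
        """Empirical probability that the second allele of a het parent is
        hidden from inference matches (1/2)^n within 3 binomial SE."""
        rng = np.random.default_rng(100 + n_offspring)
        reps = 10**5
        # het parent A/T crossed to an AA co-parent; offspring reveal the
        # missing parent's transmitted allele directly
        transmitted = rng.integers(0, 2, size=(reps, n_offspring))
        missed = np.all(transmitted == 0, axis=1)
        p_hat = missed.mean()
        p = nondetection_probability(n_offspring)
        se = np.sqrt(p * (1 - p) / reps)
        assert abs(p_hat - p) <= 3 * se
        # spot-check agreement with the inference machinery on a few draws
        for row in transmitted[:50]:
            brood = [tuple(sorted(("A", "AT"[t]))) for t in row]
            entry = infer_missing_parent(SITE, ("A", "A"), brood)
            if np.all(row == 0):
                # second allele hidden: the all-A genotype stays plausible
                assert ("A", "A") in entry.consistent
            else:
                # a transmitted T proves the parent carries T
                assert all("T" in g for g in entry.consistent)


class TestPhaseByPedigree:
    def _toy_trio(self):
        s1 = SnpSite("loc", 10, ("A", "G"))
        s2 = SnpSite("loc", 20, ("C", "T"))
        table = GenotypeTable(sites=[s1, s2])
        ped = Pedigree()
        ped.add("dam", sex="F", founder=True)
        ped.add("sire", sex="M", founder=True)
        ped.add("kid", dam="dam", sire="sire")
        return s1, s2, table, ped

    def test_double_homozygous_parent_forces_phase(self):
        s1, s2, table, ped = self._toy_trio()
        table.set("dam", s1, ("A", "A"))
        table.set("dam", s2, ("C", "C"))
        table.set("sire", s1, ("G", "G"))
        table.set("sire", s2, ("T", "T"))
        table.set("kid", s1, ("A", "G"))
        table.set("kid", s2, ("C", "T"))
        phased = phase_by_pedigree(table, ped, "loc")
        kid = phased["kid"]
        assert kid.certainty == "certain"
        assert tuple(sorted((kid.hap_a, kid.hap_b))) == (
            ("A", "C"), ("G", "T")
        )

    def test_unrelated_double_heterozygote_is_uncertain(self):
        s1 = SnpSite("loc", 1, ("A", "G"))
        s2 = SnpSite("loc", 2, ("C", "T"))
        table = GenotypeTable(sites=[s1, s2])
        ped = Pedigree()
        ped.add("solo", founder=True)
        table.set("solo", s1, ("A", "G"))
        table.set("solo", s2, ("C", "T"))
        phased = phase_by_pedigree(table, ped, "loc")
        assert phased["solo"].certainty == "uncertain"
        # EM with no information ties; lexicographic tie-break is stable
        assert phased["solo"].hap_a <= phased["solo"].hap_b

    def test_output_always_consistent_with_genotypes(self):
        cfg = SimConfig(seed=5, n_loci=3, offspring_per_pair=5,
                        haplotypes_per_locus=(2, 4))
        data = simulate_population(cfg)
        for locus in data.loci:
            sites = data.table.sites_for_locus(locus)
            phased = phase_by_pedigree(data.table, data.pedigree, locus)
            for ind, ph in phased.items():
                for si, site in enumerate(sites):
                    pair = tuple(sorted((ph.hap_a[si], ph.hap_b[si])))
                    assert pair == data.table.get(ind, site)

    def test_certain_calls_match_simulated_truth(self):
        cfg = SimConfig(seed=9, n_loci=2, offspring_per_pair=7,
                        haplotypes_per_locus=(2, 2))
        data = simulate_population(cfg)
        for locus in data.loci:
            vecs = data.truth.haplotype_pools[locus]
            phased = phase_by_pedigree(data.table, data.pedigree, locus)
            n_certain = 0
            for ind, ph in phased.items():
                if ph.certainty != "certain":
                    continue
                n_certain += 1
                h1, h2 = data.truth.individual_haplotypes[(ind, locus)]
                truth = tuple(sorted((vecs[h1], vecs[h2])))
                assert tuple(sorted((ph.hap_a, ph.hap_b))) == truth
            assert n_certain > 0

    def test_pedigree_genotype_contradiction_flagged(self):
        s1, s2, table, ped = self._toy_trio()
        table.set("dam", s1, ("A", "A"))
        table.set("dam", s2, ("C", "C"))
        table.set("sire", s1, ("A", "A"))
        table.set("sire", s2, ("C", "C"))
        table.set("kid", s1, ("G", "G"))  # impossible from these parents
        table.set("kid", s2, ("C", "C"))
        phased = phase_by_pedigree(table, ped, "loc")
        assert any(p.certainty == "inconsistent" for p in phased.values())


class TestPedigreeStructure:
    def test_cycle_rejected(self):
        ped = Pedigree()
        ped.add("a", founder=True)
        ped.add("b", dam="a", sire="c")
        with pytest.raises(ValueError):
            ped.add("c", dam="b", sire="a")

    def test_founder_with_parents_rejected(self):
        ped = Pedigree()
        with pytest.raises(ValueError):
            ped.add("f", dam="x", sire="y", founder=True)

    def test_trio_and_brood_lookups(self):
        ped = Pedigree()
        for f in ("d", "s"):
            ped.add(f, founder=True)
        ped.add("o1", dam="d", sire="s")
        ped.add("o2", dam="d", sire="s")
        assert set(ped.offspring_of("d")) == {"o1", "o2"}
        assert ped.co_parents_of("d") == {"s": ["o1", "o2"]}
        assert sorted(ped.trios()) == [("o1", "d", "s"), ("o2", "d", "s")]
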