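"""Meiosis, crosses, and the exact-enumeration oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sefscreen import (
    ABSENT_X,
    HERMAPHRODITE,
    MALE,
    WILD,
    CapacityError,
    CrossSpec,
    GeneticsError,
    Genotype,
    Individual,
    Locus,
    PhenotypeRule,
    cross,
    enumerate_offspring_distribution,
    make_gamete,
    make_locus_map,
    phenotype_frequencies,
    recombination_fraction,
)
from conftest import individual


class TestRecombinationFraction:
    def test_linear_reads_cm_as_percent_capped(self):
        assert recombination_fraction(10.0) == 0.1
        assert recombination_fraction(80.0) == 0.5

    def test_haldane_approaches_half(self):
        assert recombination_fraction(1.0, "haldane") == pytest.approx(0.0099, abs=1e-4)
        assert recombination_fraction(1000.0, "haldane") == pytest.approx(0.5, abs=1e-6)

    def test_negative_distance_rejected(self):
        with pytest.raises(GeneticsError):
            recombination_fraction(-1.0)


class TestLocusValidation:
    def test_bad_chromosome_rejected(self):
        with pytest.raises(GeneticsError):
            Locus("x", "VII", 0.0)

    def test_negative_position_rejected(self):
        with pytest.raises(GeneticsError):
            Locus("x", "I", -3.0)

    def test_duplicate_names_rejected(self):
        with pytest.raises(GeneticsError):
            make_locus_map([Locus("a", "I"), Locus("a", "II")])


class TestGameteSampling:
    def test_homozygote_transmits_its_only_haplotype(self, sef_map, rng):
        parent = individual(sef_map, {"sef": ("m", "m")})
        for _ in range(20):
            assert make_gamete(parent, rng).alleles["sef"] == "m"

    def test_heterozygote_transmits_each_allele_half_the_time(self, sef_het_herm, rng):
        n = 10_000
        k = sum(make_gamete(sef_het_herm, rng).alleles["sef"] == "m" for _ in range(n))
        assert abs(k / n - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_male_x_gametes_half_nullo(self, rng):
        loci = make_locus_map([Locus("unc-2", "X", 0.0)])
        male = individual(loci, {"unc-2": ("m", ABSENT_X)}, sex=MALE)
        n = 10_000
        k = sum(make_gamete(male, rng).carries_x for _ in range(n))
        assert abs(k / n - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_male_hemizygosity_enforced(self):
        loci = make_locus_map([Locus("unc-2", "X", 0.0)])
        with pytest.raises(GeneticsError):
            individual(loci, {"unc-2": ("m", "+")}, sex=MALE)


class TestCross:
    def test_sef_het_male_outcross_transmits_to_half(self, sef_map, sef_het_male,
                                                     plain_herm, rng):
        brood = cross(CrossSpec(plain_herm, sef_het_male, 8000), rng)
        frac = np.mean([c.genotype.is_carrier("sef") for c in brood])
        assert abs(frac - 0.5) < 4 * math.sqrt(0.25 / 8000)

    def test_xlinked_suppressor_reaches_all_cross_hermaphrodites(self, rng):
        # eat-5; unc-2/O male x eat-5 hermaphrodite: every hermaphrodite child
        # receives the father's X, every male child none of it
        loci = make_locus_map([Locus("unc-2", "X", 0.0)])
        father = individual(loci, {"unc-2": ("m", ABSENT_X)}, sex=MALE)
        mother = individual(loci, {"unc-2": ("+", "+")})
        brood = cross(CrossSpec(mother, father, 2000), rng)
        herms = [c for c in brood if c.sex == HERMAPHRODITE]
        males = [c for c in brood if c.sex == MALE]
        assert herms and males
        assert all(c.genotype.is_carrier("unc-2") for c in herms)
        assert not any(c.genotype.is_carrier("unc-2") for c in males)

    def test_outcross_sex_ratio_near_half(self, sef_map, sef_het_male, plain_herm, rng):
        n = 8000
        brood = cross(CrossSpec(plain_herm, sef_het_male, n), rng)
        male_frac = np.mean([c.sex == MALE for c in brood])
        assert abs(male_frac - 0.5) < 4 * math.sqrt(0.25 / n)

    def test_selfing_of_homozygote_breeds_true(self, sef_map, rng):
        parent = individual(sef_map, {"sef": ("m", "m")})
        brood = cross(CrossSpec(parent, offspring_count=50), rng)
        assert all(c.sex == HERMAPHRODITE for c in brood)
        assert all(c.genotype.alleles == parent.genotype.alleles for c in brood)

    def test_bad_cross_specs_rejected(self, sef_map, sef_het_male, plain_herm):
        with pytest.raises(GeneticsError):
            CrossSpec(sef_het_male, sef_het_male, 10)  # male mother
        with pytest.raises(GeneticsError):
            CrossSpec(plain_herm, offspring_count=0)


class TestEnumeration:
    def test_monohybrid_selfing_gives_1_2_1(self, sef_het_herm):
        dist = enumerate_offspring_distribution(CrossSpec(sef_het_herm))
        by_class = {k[1]: p for k, p in dist.items()}
        assert by_class[(("sef", ("+", "+")),)] == pytest.approx(0.25)
        assert by_class[(("sef", ("+", "m")),)] == pytest.approx(0.5)
        assert by_class[(("sef", ("m", "m")),)] == pytest.approx(0.25)

    def test_recessive_suppressor_homozygote_quarter_of_self_progeny(self, sef_het_herm):
        # the "suppressed F2 frequency is f/2" arithmetic: carrier frequency 2f
        # times this 1/4
        dist = enumerate_offspring_distribution(CrossSpec(sef_het_herm))
        hom = sum(p for (sex, k), p in dist.items() if dict(k)["sef"] == ("m", "m"))
        assert hom == pytest.approx(0.25)

    def test_linked_testcross_recombinant_class_probability_is_theta(self):
        loci = make_locus_map([Locus("a", "I", 0.0), Locus("b", "I", 10.0)])
        # repulsion double het x homozygous tester
        mother = individual(loci, {"a": ("A", "+"), "b": ("+", "B")})
        father = individual(loci, {"a": ("+", "+"), "b": ("+", "+")}, sex=MALE)
        dist = enumerate_offspring_distribution(CrossSpec(mother, father))
        # recombinant maternal gametes carry both A and B, or neither
        both = sum(
            p for (sex, k), p in dist.items()
            if "A" in dict(k)["a"] and "B" in dict(k)["b"]
        )
        assert both == pytest.approx(0.05)  # theta/2 of all offspring

    def test_probabilities_conserve_mass(self, sef_het_herm, sef_het_male, plain_herm):
        for spec in (CrossSpec(sef_het_herm), CrossSpec(plain_herm, sef_het_male)):
            dist = enumerate_offspring_distribution(spec)
            assert abs(sum(dist.values()) - 1.0) < 1e-12

    def test_capacity_guard(self):
        loci = make_locus_map([Locus(f"l{i}", "I", float(i)) for i in range(13)])
        parent = individual(loci, {f"l{i}": ("+", "m") for i in range(13)})
        with pytest.raises(CapacityError):
            enumerate_offspring_distribution(CrossSpec(parent))

    def test_haplotype_relabeling_leaves_distribution_unchanged(self):
        loci = make_locus_map([Locus("a", "I", 0.0), Locus("b", "I", 15.0),
                               Locus("c", "IV", 2.0)])
        mother = individual(loci, {"a": ("A", "+"), "b": ("+", "B"), "c": ("C", "+")})
        swapped = Individual(HERMAPHRODITE, mother.genotype.swapped_haplotypes())
        d1 = enumerate_offspring_distribution(CrossSpec(mother))
        d2 = enumerate_offspring_distribution(CrossSpec(swapped))
        assert set(d1) == set(d2)
        assert all(abs(d1[k] - d2[k]) < 1e-12 for k in d1)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(theta=st.floats(min_value=0.0, max_value=0.5),
       selfing=st.booleans())
def test_enumeration_mass_conservation_property(theta, selfing):
    """Any two-locus cross enumerates to total probability 1."""
    loci = make_locus_map([Locus("a", "III", 0.0), Locus("b", "III", 100.0 * theta)])
    mother = individual(loci, {"a": ("A", "+"), "b": ("+", "B")})
    father = None if selfing else individual(
        loci, {"a": ("+", "+"), "b": ("B", "+")}, sex=MALE)
    dist = enumerate_offspring_distribution(CrossSpec(mother, father))
    assert abs(sum(dist.values()) - 1.0) < 1e-12


class TestMonteCarloAgainstOracle:
    def test_two_locus_linked_cross_matches_enumeration(self, rng):
        loci = make_locus_map([Locus("a", "I", 0.0), Locus("b", "I", 20.0)])
        mother = individual(loci, {"a": ("A", "+"), "b": ("+", "B")})
        father = individual(loci, {"a": ("+", "A"), "b": ("B", "+")}, sex=MALE)
        spec = CrossSpec(mother, father, 20_000)
        exact = enumerate_offspring_distribution(spec)
        counts = {}
        for child in cross(spec, rng):
            key = (child.sex, tuple(sorted(
                (n, tuple(sorted(p))) for n, p in child.genotype.alleles.items())))
            counts[key] = counts.get(key, 0) + 1
        n = spec.offspring_count
        for key, p in exact.items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts.get(key, 0) / n - p) < 4 * max(se, 1e-9), key


class TestPhenotypeFrequencies:
    def test_dominant_suppressor_raises_cross_progeny_escape(self, rng):
        # dominance test: eat-5; sef(dom)/+ male x eat-5 hermaphrodite
        loci = make_locus_map([Locus("sef", "II", 10.0, "dominant")])
        rule = PhenotypeRule(escapes_arrest=lambda g: g.expresses("sef"))
        father = individual(loci, {"sef": ("m", "+")}, sex=MALE)
        control_father = individual(loci, {"sef": ("+", "+")}, sex=MALE)
        mother = individual(loci, {"sef": ("+", "+")})
        freq = phenotype_frequencies(CrossSpec(mother, father), rule)
        control = phenotype_frequencies(CrossSpec(mother, control_father), rule)
        assert freq[HERMAPHRODITE].get("escape", 0.0) == pytest.approx(0.5)
        assert freq[HERMAPHRODITE]["escape"] > control[HERMAPHRODITE].get("escape", 0.0)

    def test_recessive_suppressor_matches_control_cross(self):
        loci = make_locus_map([Locus("sef", "II", 10.0, "recessive")])
        rule = PhenotypeRule(escapes_arrest=lambda g: g.expresses("sef"))
        father = individual(loci, {"sef": ("m", "+")}, sex=MALE)
        control_father = individual(loci, {"sef": ("+", "+")}, sex=MALE)
        mother = individual(loci, {"sef": ("+", "+")})
        freq = phenotype_frequencies(CrossSpec(mother, father), rule)
        control = phenotype_frequencies(CrossSpec(mother, control_father), rule)
        assert freq[HERMAPHRODITE].get("escape", 0.0) == pytest.approx(
            control[HERMAPHRODITE].get("escape", 0.0))

    def test_constant_rule_gives_unit_mass(self, sef_het_herm):
        rule = PhenotypeRule(escapes_arrest=lambda g: True)
        freq = phenotype_frequencies(CrossSpec(sef_het_herm), rule)
        assert freq[HERMAPHRODITE]["escape"] == pytest.approx(1.0)

    def test_sums_to_one_per_sex(self, sef_map, sef_het_male, plain_herm):
        rule = PhenotypeRule(
            escapes_arrest=lambda g: g.expresses("sef"),
            visible_markers={"Sef": lambda g: g.is_homozygous_mutant("sef")},
        )
        freq = phenotype_frequencies(CrossSpec(plain_herm, sef_het_male), rule)
        for sex, labels in freq.items():
            assert abs(sum(labels.values()) - 1.0) < 1e-12
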