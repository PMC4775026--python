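import itertools

import pytest
from hypothesis import given, strategies as st

from col4dx.config import PhenotypeThresholds
from col4dx.core import GenotypeCall, Individual, InheritanceMode, Pedigree, Sex
from col4dx.inheritance import (
    DosageGenotype,
    Phase,
    PhenotypeClass,
    SupportingVariant,
    Zygosity,
    classify_family,
    dosage_from_genotypes,
    functional_trimer_fraction,
    homotypic_assembly_fraction,
    infer_phase,
    phenotype_class,
)


class TestFunctionalTrimerFraction:
    def test_wild_type_is_one(self):
        for sex in Sex:
            x = 1 if sex is Sex.MALE else 2
            assert functional_trimer_fraction(DosageGenotype(2, 2, x, sex)) == 1.0

    def test_autosomal_het_is_half(self):
        assert functional_trimer_fraction(DosageGenotype(1, 2, 2, Sex.FEMALE)) == 0.5
        assert functional_trimer_fraction(DosageGenotype(2, 1, 1, Sex.MALE)) == 0.5

    def test_balanced_female_x_carrier_is_half(self):
        g = DosageGenotype(2, 2, 1, Sex.FEMALE, x_wt_active_fraction=0.5)
        assert functional_trimer_fraction(g) == 0.5

    def test_unknown_x_fraction_defaults_to_balanced(self):
        g = DosageGenotype(2, 2, 1, Sex.FEMALE, x_wt_active_fraction=None)
        assert functional_trimer_fraction(g) == 0.5

    def test_hemizygous_male_is_zero(self):
        assert functional_trimer_fraction(DosageGenotype(2, 2, 0, Sex.MALE)) == 0.0

    def test_autosomal_compound_het_is_zero(self):
        assert functional_trimer_fraction(DosageGenotype(0, 2, 2, Sex.FEMALE)) == 0.0

    def test_skewed_x_fraction_passes_through(self):
        g = DosageGenotype(2, 2, 1, Sex.FEMALE, x_wt_active_fraction=0.8)
        assert functional_trimer_fraction(g) == pytest.approx(0.8)

    def test_multiplicative(self):
        g = DosageGenotype(1, 1, 1, Sex.FEMALE, x_wt_active_fraction=0.5)
        assert functional_trimer_fraction(g) == pytest.approx(0.5 * 0.5 * 0.5)

    def test_monotone_in_functional_alleles(self):
        # removing any wild-type allele never increases f
        for a3, a4, x in itertools.product((0, 1, 2), (0, 1, 2), (0, 1, 2)):
            f = functional_trimer_fraction(DosageGenotype(a3, a4, x, Sex.FEMALE))
            assert 0.0 <= f <= 1.0
            if a3 > 0:
                assert functional_trimer_fraction(DosageGenotype(a3 - 1, a4, x, Sex.FEMALE)) <= f
            if a4 > 0:
                assert functional_trimer_fraction(DosageGenotype(a3, a4 - 1, x, Sex.FEMALE)) <= f
            if x > 0:
                assert functional_trimer_fraction(DosageGenotype(a3, a4, x - 1, Sex.FEMALE)) <= f

    def test_ploidy_enforced(self):
        with pytest.raises(ValueError):
            DosageGenotype(2, 2, 2, Sex.MALE)
        with pytest.raises(ValueError):
            DosageGenotype(3, 2, 2, Sex.FEMALE)


class TestHomotypicAssembly:
    def test_heterozygous_dimer_quarter(self):
        assert homotypic_assembly_fraction(2, 0.5) == 0.25

    def test_heterozygous_trimer_eighth(self):
        assert homotypic_assembly_fraction(3, 0.5) == 0.125

    def test_wild_type(self):
        assert homotypic_assembly_fraction(2, 1.0) == 1.0

    def test_dominant_negative_worse_than_null(self):
        # at het chain fraction 0.5, homotypic assembly loses more than the
        # ~50% a null allele costs, and more chains lose strictly more
        assert homotypic_assembly_fraction(2, 0.5) < 0.5
        assert homotypic_assembly_fraction(3, 0.5) < homotypic_assembly_fraction(2, 0.5)

    def test_invalid_chain_count(self):
        with pytest.raises(ValueError):
            homotypic_assembly_fraction(4, 0.5)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_bounded(self, wt):
        for n in (2, 3):
            assert 0.0 <= homotypic_assembly_fraction(n, wt) <= 1.0


class TestPhenotypeClass:
    @pytest.mark.parametrize(
        "f,expected",
        [
            (1.0, PhenotypeClass.NORMAL),
            (0.75, PhenotypeClass.NORMAL),
            (0.5, PhenotypeClass.FBH_TBMN_SPECTRUM),
            (0.25, PhenotypeClass.FBH_TBMN_SPECTRUM),
            (0.2, PhenotypeClass.AS_SEVERE),
            (0.0, PhenotypeClass.AS_SEVERE),
        ],
    )
    def test_default_thresholds(self, f, expected):
        assert phenotype_class(f) is expected

    def test_monotone_severity(self):
        order = {PhenotypeClass.NORMAL: 0, PhenotypeClass.FBH_TBMN_SPECTRUM: 1, PhenotypeClass.AS_SEVERE: 2}
        previous = 2
        for i in range(101):
            severity = order[phenotype_class(i / 100)]
            assert severity <= previous
            previous = severity

    def test_custom_thresholds(self):
        thresholds = PhenotypeThresholds(normal_min=0.9, severe_max=0.1)
        assert phenotype_class(0.8, thresholds) is PhenotypeClass.FBH_TBMN_SPECTRUM


class TestClassifyFamily:
    def test_two_autosomal_variants_same_gene(self):
        d = classify_family(
            "F4",
            [SupportingVariant("COL4A3:c.687G>A"), SupportingVariant("COL4A3:c.3490G>T")],
        )
        assert d.mode is InheritanceMode.AUTOSOMAL_AS

    def test_single_het_autosomal_is_fbh(self):
        d = classify_family("F13", [SupportingVariant("COL4A3:c.3410G>A")])
        assert d.mode is InheritanceMode.FBH

    def test_homozygous_autosomal_is_autosomal_as(self):
        d = classify_family("H", [SupportingVariant("COL4A3:c.3410G>A", Zygosity.HOM)])
        assert d.mode is InheritanceMode.AUTOSOMAL_AS

    def test_x_variant_is_x_linked(self):
        d = classify_family("F6", [SupportingVariant("COL4A5:c.2741G>A")])
        assert d.mode is InheritanceMode.X_LINKED_AS

    def test_no_variants_unresolved(self):
        assert classify_family("F0", []).mode is InheritanceMode.UNRESOLVED

    def test_digenic_flagged_with_warning(self):
        d = classify_family(
            "D",
            [SupportingVariant("COL4A3:c.3410G>A"), SupportingVariant("COL4A4:c.2320G>C")],
        )
        assert d.mode is InheritanceMode.DIGENIC_FLAG
        assert d.warnings

    def test_composite_x_plus_autosomal_flagged_not_raised(self):
        d = classify_family(
            "C",
            [SupportingVariant("COL4A5:c.2741G>A"), SupportingVariant("COL4A3:c.3410G>A")],
        )
        assert d.composite
        assert d.mode is InheritanceMode.X_LINKED_AS
        assert d.warnings

    def test_cis_phase_downgrades_to_fbh(self):
        variants = [SupportingVariant("COL4A3:c.687G>A"), SupportingVariant("COL4A3:c.3490G>T")]
        assert classify_family("F", variants, phase=Phase.CIS).mode is InheritanceMode.FBH
        assert classify_family("F", variants, phase=Phase.TRANS).mode is InheritanceMode.AUTOSOMAL_AS

    def test_vocabulary_has_no_autosomal_dominant(self):
        assert not any("dominant" in m.value for m in InheritanceMode)

    def test_reference_roster(self, reference_run):
        _, _, diagnoses = reference_run
        by_case = {d.family_id: d.mode for d in diagnoses}
        expected_x = {"F1", "F5", "F6", "F7", "F9", "F10", "F11", "F14", "I1", "I2"}
        expected_auto = {"F3", "F4"}
        expected_fbh = {"F2", "F8", "F12", "F13", "I3"}
        assert {c for c, m in by_case.items() if m is InheritanceMode.X_LINKED_AS} == expected_x
        assert {c for c, m in by_case.items() if m is InheritanceMode.AUTOSOMAL_AS} == expected_auto
        assert {c for c, m in by_case.items() if m is InheritanceMode.FBH} == expected_fbh


class TestInferPhase:
    def _family(self):
        ped = Pedigree("F")
        ped.add(Individual("dad", Sex.MALE))
        ped.add(Individual("mom", Sex.FEMALE))
        ped.add(Individual("kid", Sex.FEMALE, father_id="dad", mother_id="mom"))
        return ped

    def test_trans_proven(self):
        ped = self._family()
        a, b = "COL4A3:c.687G>A", "COL4A3:c.3490G>T"
        calls = [
            GenotypeCall("dad", a, 1),
            GenotypeCall("mom", b, 1),
            GenotypeCall("kid", a, 1),
            GenotypeCall("kid", b, 1),
        ]
        assert infer_phase(ped, calls, a, b) is Phase.TRANS

    def test_cis_proven(self):
        ped = self._family()
        a, b = "COL4A3:c.687G>A", "COL4A3:c.3490G>T"
        calls = [
            GenotypeCall("dad", a, 1),
            GenotypeCall("dad", b, 1),
            GenotypeCall("kid", a, 1),
            GenotypeCall("kid", b, 1),
        ]
        assert infer_phase(ped, calls, a, b) is Phase.CIS

    def test_unknown_without_parents(self):
        ped = Pedigree("F")
        ped.add(Individual("kid", Sex.FEMALE))
        a, b = "COL4A3:c.687G>A", "COL4A3:c.3490G>T"
        calls = [GenotypeCall("kid", a, 1), GenotypeCall("kid", b, 1)]
        assert infer_phase(ped, calls, a, b) is Phase.UNKNOWN


class TestDosageFromGenotypes:
    def test_builds_counts(self):
        calls = [GenotypeCall("i", "COL4A3:c.687G>A", 1), GenotypeCall("i", "COL4A3:c.3490G>T", 1)]
        g = dosage_from_genotypes(calls, Sex.FEMALE)
        assert (g.col4a3_wt, g.col4a4_wt, g.col4a5_wt) == (0, 2, 2)
        assert functional_trimer_fraction(g) == 0.0

    def test_male_x(self):
        calls = [GenotypeCall("i", "COL4A5:c.2741G>A", 1)]
        g = dosage_from_genotypes(calls, Sex.MALE)
        assert g.col4a5_wt == 0
        assert functional_trimer_fraction(g) == 0.0
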