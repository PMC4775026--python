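import itertools

import pytest

from oracle_helpers import enumerate_member_states, segregation_oracle

from col4dx.config import PathogenicityConfig
from col4dx.core import (
    Affection,
    AnnotationRecord,
    ClassificationLabel,
    Consequence,
    ConsequenceCategory,
    GenotypeCall,
    Individual,
    Pedigree,
    PublishedStatus,
    Sex,
    get_gene,
)
from col4dx.pathogenicity import (
    VariantRecord,
    classify_cohort,
    classify_variant,
    segregates_exclusively,
    summarize,
)

AUTO_KEY = "COL4A3:c.3410G>A"
X_KEY = "COL4A5:c.2741G>A"


def build_pedigree(spec):
    """spec: list of (id, sex, affection); everyone unrelated (segregation ignores links)."""
    ped = Pedigree("F")
    for iid, sex, aff in spec:
        ped.add(Individual(iid, sex, aff))
    return ped


class TestSegregatesExclusively:
    def test_autosomal_consistent(self):
        ped = build_pedigree(
            [
                ("a1", Sex.FEMALE, Affection.AFFECTED),
                ("a2", Sex.MALE, Affection.AFFECTED),
                ("a3", Sex.FEMALE, Affection.AFFECTED),
                ("u1", Sex.MALE, Affection.UNAFFECTED),
                ("u2", Sex.FEMALE, Affection.UNAFFECTED),
            ]
        )
        calls = [GenotypeCall(i, AUTO_KEY, 1) for i in ("a1", "a2", "a3")] + [
            GenotypeCall(i, AUTO_KEY, 0) for i in ("u1", "u2")
        ]
        result = segregates_exclusively(AUTO_KEY, calls, ped)
        assert result.consistent
        assert all(r.ok for r in result.detail)

    def test_autosomal_unaffected_carrier_breaks_strict(self):
        ped = build_pedigree(
            [("a1", Sex.FEMALE, Affection.AFFECTED), ("u1", Sex.MALE, Affection.UNAFFECTED)]
        )
        calls = [GenotypeCall("a1", AUTO_KEY, 1), GenotypeCall("u1", AUTO_KEY, 1)]
        assert not segregates_exclusively(AUTO_KEY, calls, ped).consistent

    def test_autosomal_penetrance_tolerant_flag(self):
        ped = build_pedigree(
            [("a1", Sex.FEMALE, Affection.AFFECTED), ("u1", Sex.MALE, Affection.UNAFFECTED)]
        )
        calls = [GenotypeCall("a1", AUTO_KEY, 1), GenotypeCall("u1", AUTO_KEY, 1)]
        config = PathogenicityConfig(penetrance_tolerant=True)
        assert segregates_exclusively(AUTO_KEY, calls, ped, config=config).consistent

    def test_compound_het_sibling_variant_absence_tolerated(self):
        # affected compound-het child, each parent affected carrying one allele:
        # the other parent's non-carriage of this variant must not falsify
        ped = build_pedigree(
            [
                ("dad", Sex.MALE, Affection.AFFECTED),
                ("mom", Sex.FEMALE, Affection.AFFECTED),
                ("kid", Sex.FEMALE, Affection.AFFECTED),
            ]
        )
        calls = [
            GenotypeCall("dad", AUTO_KEY, 1),
            GenotypeCall("mom", AUTO_KEY, 0),
            GenotypeCall("kid", AUTO_KEY, 1),
        ]
        assert segregates_exclusively(AUTO_KEY, calls, ped).consistent

    def test_x_linked_unaffected_female_carrier_tolerated(self):
        ped = build_pedigree(
            [
                ("carrier", Sex.FEMALE, Affection.UNAFFECTED),
                ("son", Sex.MALE, Affection.AFFECTED),
            ]
        )
        calls = [GenotypeCall("carrier", X_KEY, 1), GenotypeCall("son", X_KEY, 1)]
        result = segregates_exclusively(X_KEY, calls, ped)
        assert result.consistent

    def test_x_linked_unaffected_male_carrier_breaks(self):
        ped = build_pedigree(
            [("son", Sex.MALE, Affection.UNAFFECTED), ("aff", Sex.MALE, Affection.AFFECTED)]
        )
        calls = [GenotypeCall("son", X_KEY, 1), GenotypeCall("aff", X_KEY, 1)]
        assert not segregates_exclusively(X_KEY, calls, ped).consistent

    def test_x_linked_affected_male_noncarrier_breaks(self):
        ped = build_pedigree(
            [("aff", Sex.MALE, Affection.AFFECTED), ("c", Sex.FEMALE, Affection.AFFECTED)]
        )
        calls = [GenotypeCall("aff", X_KEY, 0), GenotypeCall("c", X_KEY, 1)]
        assert not segregates_exclusively(X_KEY, calls, ped).consistent

    def test_unknown_affection_ignored(self):
        ped = build_pedigree(
            [("nd", Sex.FEMALE, Affection.UNKNOWN), ("aff", Sex.FEMALE, Affection.AFFECTED)]
        )
        calls = [GenotypeCall("nd", AUTO_KEY, 1), GenotypeCall("aff", AUTO_KEY, 1)]
        assert segregates_exclusively(AUTO_KEY, calls, ped).consistent

    def test_no_affected_carrier_fails(self):
        ped = build_pedigree([("u", Sex.FEMALE, Affection.UNAFFECTED)])
        assert not segregates_exclusively(AUTO_KEY, [GenotypeCall("u", AUTO_KEY, 0)], ped).consistent

    def test_missing_individual_raises(self):
        ped = build_pedigree([("a", Sex.FEMALE, Affection.AFFECTED)])
        with pytest.raises(KeyError):
            segregates_exclusively(AUTO_KEY, [GenotypeCall("ghost", AUTO_KEY, 1)], ped)

    @pytest.mark.parametrize("x_linked", [False, True])
    @pytest.mark.parametrize("n_members", [1, 2, 3, 4])
    def test_matches_oracle_small_pedigrees(self, x_linked, n_members):
        # exhaustive over sexes x affection x allele count for small n
        # (the full <=6-member sweep lives in the acceptance suite)
        key = X_KEY if x_linked else AUTO_KEY
        for sexes in itertools.product(("male", "female"), repeat=n_members):
            for states in enumerate_member_states(n_members, x_linked, sexes):
                ped = Pedigree("F")
                calls = []
                members = []
                for i, (sex, (aff, count)) in enumerate(zip(sexes, states)):
                    iid = f"i{i}"
                    ped.add(Individual(iid, Sex(sex), Affection(aff)))
                    calls.append(GenotypeCall(iid, key, count))
                    members.append((sex, aff, count))
                got = segregates_exclusively(key, calls, ped).consistent
                assert got == segregation_oracle(members, x_linked), (sexes, states)


def make_record(
    category=ConsequenceCategory.MISSENSE,
    collagenous=False,
    secondary=False,
    key=AUTO_KEY,
):
    return VariantRecord(
        key,
        get_gene(key.split(":")[0]),
        Consequence(category, secondary),
        collagenous_glycine=collagenous,
    )


def make_annotation(key=AUTO_KEY, status=PublishedStatus.NONE, in_controls=False, maf=None):
    return AnnotationRecord(key, status, "src", in_controls, maf)


def seg_result(consistent, key=AUTO_KEY):
    from col4dx.pathogenicity import SegregationResult

    return SegregationResult(key, "F", consistent)


class TestClassifyVariant:
    def test_control_presence_gives_polymorphism(self):
        record = make_record()
        result = classify_variant(
            record, make_annotation(in_controls=True, maf=0.121, status=PublishedStatus.POLYMORPHISM),
            None,
        )
        assert result.label is ClassificationLabel.POLYMORPHISM

    def test_common_maf_alone_gives_polymorphism(self):
        result = classify_variant(make_record(), make_annotation(maf=0.05), seg_result(True))
        assert result.label is ClassificationLabel.POLYMORPHISM

    def test_published_pathogenic_with_consistent_family(self):
        result = classify_variant(
            make_record(), make_annotation(status=PublishedStatus.PATHOGENIC), seg_result(True)
        )
        assert result.label is ClassificationLabel.PATHOGENIC
        assert not result.is_novel

    def test_published_pathogenic_failing_segregation_is_vus(self):
        result = classify_variant(
            make_record(), make_annotation(status=PublishedStatus.PATHOGENIC), seg_result(False)
        )
        assert result.label is ClassificationLabel.VUS
        assert "published_but_segregation_failed" in result.flags

    def test_novel_canonical_with_segregation_is_pathogenic(self):
        for record in (
            make_record(ConsequenceCategory.SPLICE_DONOR),
            make_record(ConsequenceCategory.SPLICE_ACCEPTOR),
            make_record(ConsequenceCategory.DELETION_WITH_SPLICE),
            make_record(ConsequenceCategory.SPLICE_REGION_EXONIC),
            make_record(ConsequenceCategory.MISSENSE, collagenous=True),
            make_record(ConsequenceCategory.MISSENSE, secondary=True),
        ):
            result = classify_variant(record, make_annotation(), seg_result(True))
            assert result.label is ClassificationLabel.PATHOGENIC, record.consequence
            assert result.is_novel

    def test_intronic_splice_region_is_presumed(self):
        result = classify_variant(
            make_record(ConsequenceCategory.SPLICE_REGION_INTRONIC), make_annotation(), seg_result(True)
        )
        assert result.label is ClassificationLabel.PRESUMED_PATHOGENIC

    def test_non_collagenous_missense_is_vus(self):
        result = classify_variant(make_record(), make_annotation(), seg_result(True))
        assert result.label is ClassificationLabel.VUS

    def test_failed_segregation_novel_is_vus(self):
        result = classify_variant(
            make_record(ConsequenceCategory.SPLICE_DONOR), make_annotation(), seg_result(False)
        )
        assert result.label is ClassificationLabel.VUS

    def test_isolated_case_caps_at_presumed(self):
        result = classify_variant(
            make_record(ConsequenceCategory.MISSENSE, collagenous=True), make_annotation(), None
        )
        assert result.label is ClassificationLabel.PRESUMED_PATHOGENIC

    def test_missing_annotation_raises(self):
        with pytest.raises(ValueError):
            classify_variant(make_record(), None, None)

    def test_trace_has_four_criteria(self):
        result = classify_variant(make_record(), make_annotation(), seg_result(True))
        names = [c.name for c in result.criteria_trace]
        assert names[:4] == [
            "published",
            "absent_from_controls",
            "not_common_allele",
            "exclusive_segregation",
        ]


def _all_combinations():
    statuses = list(PublishedStatus)
    mafs = [None, 0.001, 0.2]
    segs = [None, True, False]
    categories = list(ConsequenceCategory)
    for status, in_controls, maf, seg, category, collagenous, secondary in itertools.product(
        statuses, [False, True], mafs, segs, categories, [False, True], [False, True]
    ):
        yield status, in_controls, maf, seg, category, collagenous, secondary


class TestDecisionTableProperties:
    def test_completeness_and_determinism(self):
        for status, in_controls, maf, seg, category, collagenous, secondary in _all_combinations():
            record = make_record(category, collagenous, secondary)
            annotation = make_annotation(status=status, in_controls=in_controls, maf=maf)
            segregation = None if seg is None else seg_result(seg)
            first = classify_variant(record, annotation, segregation)
            second = classify_variant(record, annotation, segregation)
            assert isinstance(first.label, ClassificationLabel)
            assert first.label is second.label
            assert first.criteria_trace == second.criteria_trace

    def test_in_controls_monotonicity(self):
        severity = {
            ClassificationLabel.POLYMORPHISM: 0,
            ClassificationLabel.VUS: 1,
            ClassificationLabel.PRESUMED_PATHOGENIC: 2,
            ClassificationLabel.PATHOGENIC: 3,
        }
        for status, _, maf, seg, category, collagenous, secondary in _all_combinations():
            record = make_record(category, collagenous, secondary)
            segregation = None if seg is None else seg_result(seg)
            without = classify_variant(
                record, make_annotation(status=status, in_controls=False, maf=maf), segregation
            )
            with_controls = classify_variant(
                record, make_annotation(status=status, in_controls=True, maf=maf), segregation
            )
            assert severity[with_controls.label] <= severity[without.label]


class TestClassifyCohort:
    def test_empty(self):
        assert classify_cohort([], {}, {}) == []

    def test_missing_annotation_raises(self):
        with pytest.raises(ValueError):
            classify_cohort([make_record()], {}, {})

    def test_reference_fixture_counts(self, reference_run):
        results, summary, _ = reference_run
        assert len(results) == 38
        assert summary.counts_by_label["polymorphism"] == 21
        assert summary.mutation_count == 17
        assert summary.novel_count == 14
        assert summary.polymorphisms_by_gene == {"COL4A3": 11, "COL4A4": 9, "COL4A5": 1}

    def test_reference_fixture_named_examples(self, reference_run):
        results, _, _ = reference_run
        by_key = {r.variant_key: r for r in results}
        assert by_key["COL4A3:c.1721C>T"].label is ClassificationLabel.POLYMORPHISM
        assert by_key["COL4A5:c.1033-6A>G"].label is ClassificationLabel.PRESUMED_PATHOGENIC
        assert by_key["COL4A4:c.2320G>C"].label is ClassificationLabel.PATHOGENIC
        assert by_key["COL4A5:c.82G>T"].label is ClassificationLabel.PATHOGENIC

    def test_ambiguous_rows_carry_note(self, reference_run):
        results, _, _ = reference_run
        by_key = {r.variant_key: r for r in results}
        for key in ("COL4A4:c.2996G>A", "COL4A4:c.4394G>A"):
            assert by_key[key].label is ClassificationLabel.POLYMORPHISM
            assert "annotation_note" in by_key[key].flags

    def test_summary_counts_sum(self, reference_run):
        results, summary, _ = reference_run
        assert sum(summary.counts_by_label.values()) == len(results)
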