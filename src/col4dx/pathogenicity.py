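"""Four-criterion variant classification with pedigree segregation.

A variant is concluded pathogenic when it (1) was published previously
or is found in mutation databases, (2) is absent from the control
cohort, (3) is not a common allele, and (4) its exclusive presence
among affected family members is genetically proven.  No computational
pathogenicity predictor contributes to the decision.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from col4dx.config import PathogenicityConfig
from col4dx.core import (
    Affection,
    AnnotationRecord,
    ClassificationLabel,
    ClassificationResult,
    Consequence,
    ConsequenceCategory,
    CriterionResult,
    Gene,
    GenotypeCall,
    ParsedCdnaVariant,
    Pedigree,
    ProteinChange,
    PublishedStatus,
    Sex,
    gene_of_key,
)

__all__ = [
    "VariantRecord",
    "IndividualSegregationRecord",
    "SegregationResult",
    "segregates_exclusively",
    "classify_variant",
    "classify_cohort",
    "CohortSummary",
    "summarize",
]


@dataclass(frozen=True)
class VariantRecord:
    """Everything the rule engine needs to know about one variant."""

    variant_key: str
    gene: Gene
    consequence: Consequence
    protein_change: Optional[ProteinChange] = None
    parsed: Optional[ParsedCdnaVariant] = None
    collagenous_glycine: bool = False


@dataclass(frozen=True)
class IndividualSegregationRecord:
    individual_id: str
    sex: Sex
    affection: Affection
    allele_count: int
    expected: str
    ok: bool
    note: str = ""


@dataclass(frozen=True)
class SegregationResult:
    variant_key: str
    family_id: str
    consistent: bool
    detail: tuple[IndividualSegregationRecord, ...] = ()

    def to_dict(self) -> dict:
        return {
            "variant_key": self.variant_key,
            "family_id": self.family_id,
            "consistent": self.consistent,
            "detail": [vars(r) | {"sex": r.sex.value, "affection": r.affection.value} for r in self.detail],
        }


def segregates_exclusively(
    variant_key: str,
    genotypes: Iterable[GenotypeCall],
    pedigree: Pedigree,
    gene: Optional[Gene] = None,
    config: PathogenicityConfig = PathogenicityConfig(),
) -> SegregationResult:
    """Test exclusive presence of a variant among affected family members.

    Autosomal genes: consistent iff no unaffected genotyped member
    carries the variant (strict mode; the penetrance-tolerant flag
    permits unaffected carriers).  Affected members carrying zero
    alleles do not falsify — in compound-heterozygous families each
    causal variant is absent from some affected carriers of the other
    allele — but are recorded in the detail.

    COL4A5 (X-linked): every affected male must be a hemizygous
    carrier and every unaffected male a non-carrier; every affected
    female must carry; unaffected female carriers do NOT break
    consistency (X-inactivation makes the female carrier phenotype
    variable).

    Individuals with unknown affection are ignored.  By default at
    least one affected carrier is required for a passing test.
    """
    g = gene or gene_of_key(variant_key)
    calls = [c for c in genotypes if c.variant_key == variant_key]
    for call in calls:
        if call.individual_id not in pedigree:
            raise KeyError(
                f"genotyped individual {call.individual_id!r} missing from pedigree {pedigree.family_id!r}"
            )

    detail: list[IndividualSegregationRecord] = []
    consistent = True
    affected_carrier_seen = False
    for call in calls:
        member = pedigree.get(call.individual_id)
        carrier = call.allele_count > 0
        if member.affection is Affection.UNKNOWN:
            detail.append(
                IndividualSegregationRecord(
                    member.id, member.sex, member.affection, call.allele_count, "ignored", True,
                    "unknown affection status",
                )
            )
            continue
        affected = member.affection is Affection.AFFECTED
        if affected and carrier:
            affected_carrier_seen = True

        ok = True
        note = ""
        if g.is_x_linked:
            if member.sex is Sex.MALE:
                expected = "carrier (hemizygous)" if affected else "non-carrier"
                ok = carrier if affected else not carrier
            else:
                if affected:
                    expected = "carrier"
                    ok = carrier
                else:
                    expected = "carrier or non-carrier"
                    if carrier:
                        note = "unaffected female carrier: tolerated (variable carrier phenotype)"
        else:
            if affected:
                expected = "carrier(s) expected among affected"
                if not carrier:
                    note = "affected non-carrier: does not falsify (may carry a different causal allele)"
            else:
                expected = "non-carrier"
                if carrier:
                    if config.penetrance_tolerant:
                        note = "unaffected carrier tolerated (penetrance-tolerant mode)"
                    else:
                        ok = False
        if not ok:
            consistent = False
        detail.append(
            IndividualSegregationRecord(
                member.id, member.sex, member.affection, call.allele_count, expected, ok, note
            )
        )

    if config.require_affected_carrier and not affected_carrier_seen:
        consistent = False
        detail.append(
            IndividualSegregationRecord(
                "-", Sex.FEMALE, Affection.UNKNOWN, 0, "at least one affected carrier", False,
                "no affected carrier observed",
            )
        )
    return SegregationResult(variant_key, pedigree.family_id, consistent, tuple(detail))


#: consequences accepted as directly pathogenic once the filter criteria pass
_CANONICAL_NON_MISSENSE = frozenset(
    {
        ConsequenceCategory.SPLICE_DONOR,
        ConsequenceCategory.SPLICE_ACCEPTOR,
        ConsequenceCategory.DELETION_WITH_SPLICE,
        ConsequenceCategory.SPLICE_REGION_EXONIC,
    }
)


def _is_canonical(record: VariantRecord) -> bool:
    cat = record.consequence.category
    if cat in _CANONICAL_NON_MISSENSE:
        return True
    if cat is ConsequenceCategory.MISSENSE:
        # a missense change is canonical when it breaks a collagenous
        # glycine, or when it additionally disrupts conserved
        # exon-terminal splice bases
        return record.collagenous_glycine or record.consequence.secondary_splice
    return False


def classify_variant(
    record: VariantRecord,
    annotation: AnnotationRecord,
    segregation: Optional[SegregationResult],
    config: PathogenicityConfig = PathogenicityConfig(),
) -> ClassificationResult:
    """Apply the four criteria to one variant and derive its label.

    Label logic (deterministic in the criteria trace):

    * POLYMORPHISM — present in controls, published as a polymorphism,
      or at/above the common-allele MAF threshold.
    * PATHOGENIC — published pathogenic with carrier confinement to
      affected members wherever family data exist; or novel, absent
      from controls, not common, segregation proven, and the
      consequence is canonical (collagenous-Gly missense, canonical
      splice site, exon-terminal splice region, splice-touching
      deletion).
    * PRESUMED_PATHOGENIC — same filters but the consequence is a
      non-canonical intronic splice-region change; or a canonical
      novel variant in an isolated case where segregation cannot be
      evaluated.
    * VUS — anything else.
    """
    if annotation is None:
        raise ValueError(f"missing annotation record for {record.variant_key}")

    maf = annotation.population_maf
    is_common = maf is not None and maf >= config.common_maf_threshold
    published = annotation.published_status
    seg_passed: Optional[bool] = None if segregation is None else segregation.consistent

    trace = [
        CriterionResult(
            "published",
            published is not PublishedStatus.NONE,
            f"database status: {published.value}" + (f" ({annotation.source})" if annotation.source else ""),
        ),
        CriterionResult(
            "absent_from_controls",
            not annotation.in_controls,
            "observed in control cohort" if annotation.in_controls else "not observed in control cohort",
        ),
        CriterionResult(
            "not_common_allele",
            not is_common,
            f"population MAF {maf}" if maf is not None else "no population MAF on record",
        ),
        CriterionResult(
            "exclusive_segregation",
            seg_passed,
            "no family data: not evaluable" if segregation is None else f"family {segregation.family_id}: "
            + ("consistent" if segregation.consistent else "inconsistent"),
        ),
    ]

    flags: list[str] = []
    if published is PublishedStatus.NONE:
        flags.append("novel")
    if annotation.note:
        flags.append("annotation_note")
        trace.append(CriterionResult("annotation_note", None, annotation.note))

    if annotation.in_controls or published is PublishedStatus.POLYMORPHISM or is_common:
        label = ClassificationLabel.POLYMORPHISM
        flags = [f for f in flags if f != "novel"]
    elif published is PublishedStatus.PATHOGENIC:
        # criterion 1 satisfied; require carrier confinement where family data exist
        label = ClassificationLabel.PATHOGENIC if seg_passed in (None, True) else ClassificationLabel.VUS
        if seg_passed is False:
            flags.append("published_but_segregation_failed")
    elif not annotation.in_controls and not is_common:
        canonical = _is_canonical(record)
        presumed_ok = canonical or record.consequence.category is ConsequenceCategory.SPLICE_REGION_INTRONIC
        if seg_passed is True:
            if canonical:
                label = ClassificationLabel.PATHOGENIC
            elif record.consequence.category is ConsequenceCategory.SPLICE_REGION_INTRONIC:
                label = ClassificationLabel.PRESUMED_PATHOGENIC
            else:
                label = ClassificationLabel.VUS
        elif seg_passed is None and presumed_ok:
            # isolated case: criterion 4 not evaluable, cap at presumed
            label = ClassificationLabel.PRESUMED_PATHOGENIC
        else:
            label = ClassificationLabel.VUS
    else:
        label = ClassificationLabel.VUS

    if label in (ClassificationLabel.PATHOGENIC, ClassificationLabel.PRESUMED_PATHOGENIC):
        if record.collagenous_glycine:
            flags.append("collagenous_glycine")
    if label is ClassificationLabel.VUS:
        flags = [f for f in flags if f != "novel"]

    return ClassificationResult(record.variant_key, label, tuple(trace), tuple(flags))


@dataclass(frozen=True)
class CohortSummary:
    counts_by_label: Mapping[str, int]
    polymorphisms_by_gene: Mapping[str, int]
    novel_by_gene: Mapping[str, int]
    novel_count: int
    mutation_count: int


def classify_cohort(
    records: Sequence[VariantRecord],
    annotations: Mapping[str, AnnotationRecord],
    segregations: Mapping[str, SegregationResult],
    config: PathogenicityConfig = PathogenicityConfig(),
) -> list[ClassificationResult]:
    """Deterministic per-variant application of :func:`classify_variant`."""
    results = []
    for record in records:
        annotation = annotations.get(record.variant_key)
        if annotation is None:
            raise ValueError(f"no annotation record for {record.variant_key}")
        results.append(
            classify_variant(record, annotation, segregations.get(record.variant_key), config)
        )
    return results


def summarize(results: Sequence[ClassificationResult]) -> CohortSummary:
    by_label = Counter(r.label.value for r in results)
    poly_by_gene = Counter(
        gene_of_key(r.variant_key).name for r in results if r.label is ClassificationLabel.POLYMORPHISM
    )
    mutation_labels = (ClassificationLabel.PATHOGENIC, ClassificationLabel.PRESUMED_PATHOGENIC)
    novel = [r for r in results if r.label in mutation_labels and r.is_novel]
    novel_by_gene = Counter(gene_of_key(r.variant_key).name for r in novel)
    return CohortSummary(
        counts_by_label=dict(by_label),
        polymorphisms_by_gene=dict(poly_by_gene),
        novel_by_gene=dict(novel_by_gene),
        novel_count=len(novel),
        mutation_count=sum(1 for r in results if r.label in mutation_labels),
    )
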