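"""Shared domain types: genes, transcripts, variants, pedigrees, results.

Coordinate convention: all cDNA positions are 1-based inclusive HGVS
coding positions.  Intron offsets follow the HGVS sign convention
(``+k`` counts into the intron after an exon end, ``-k`` counts back
from the following exon start); an offset of 0 means the position is
exonic.  No genomic (chromosome:position) coordinates appear anywhere
in this package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

__all__ = [
    "ChromosomeClass",
    "Gene",
    "GENES",
    "UnknownGeneError",
    "get_gene",
    "TranscriptModel",
    "EditType",
    "ParsedCdnaVariant",
    "ProteinChange",
    "ConsequenceCategory",
    "Consequence",
    "Sex",
    "Affection",
    "Individual",
    "Pedigree",
    "GenotypeCall",
    "PublishedStatus",
    "AnnotationRecord",
    "ClassificationLabel",
    "CriterionResult",
    "ClassificationResult",
    "InheritanceMode",
    "FamilyDiagnosis",
    "PedigreeViolation",
    "validate_pedigree",
    "variant_key",
    "gene_of_key",
]


class ChromosomeClass(enum.Enum):
    AUTOSOMAL = "autosomal"
    X_LINKED = "x_linked"


@dataclass(frozen=True)
class Gene:
    """One of the three type-IV collagen genes handled by this package."""

    name: str
    chromosome_class: ChromosomeClass
    exon_count: int

    @property
    def is_x_linked(self) -> bool:
        return self.chromosome_class is ChromosomeClass.X_LINKED


GENES: Mapping[str, Gene] = {
    "COL4A3": Gene("COL4A3", ChromosomeClass.AUTOSOMAL, 52),
    "COL4A4": Gene("COL4A4", ChromosomeClass.AUTOSOMAL, 48),
    "COL4A5": Gene("COL4A5", ChromosomeClass.X_LINKED, 51),
}


class UnknownGeneError(ValueError):
    """Raised for gene symbols outside COL4A3/COL4A4/COL4A5."""


def get_gene(name: str) -> Gene:
    try:
        return GENES[name.strip().upper()]
    except KeyError:
        raise UnknownGeneError(f"unknown gene {name!r}; expected one of {sorted(GENES)}") from None


def variant_key(gene: Gene | str, cdna_hgvs: str) -> str:
    """Canonical ``GENE:c.xxx`` key; whitespace-normalized, case-preserving."""
    g = gene if isinstance(gene, Gene) else get_gene(gene)
    if not cdna_hgvs or not cdna_hgvs.strip():
        raise ValueError("empty cDNA HGVS string")
    return f"{g.name}:{''.join(cdna_hgvs.split())}"


def gene_of_key(key: str) -> Gene:
    name, _, rest = key.partition(":")
    if not rest:
        raise ValueError(f"malformed variant key {key!r}")
    return get_gene(name)


@dataclass(frozen=True)
class TranscriptModel:
    """Coding-coordinate exon structure of a gene.

    Exons are contiguous 1-based inclusive intervals over the coding
    sequence (introns have zero width in cDNA coordinates), so the model
    is fully determined by the sorted list of exon-end positions.  The
    packaged models are *partial*: they contain only the boundaries that
    the supported variant set requires, padded to the CDS length.
    """

    gene: Gene
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        if self.exons[0][0] != 1:
            raise ValueError("first exon must start at coding position 1")
        prev_end = 0
        for start, end in self.exons:
            if start != prev_end + 1:
                raise ValueError(f"exon intervals not contiguous at position {start}")
            if end < start:
                raise ValueError(f"non-positive exon length at [{start}, {end}]")
            prev_end = end

    @classmethod
    def from_exon_ends(cls, gene: Gene | str, exon_ends: Sequence[int], cds_length: int) -> "TranscriptModel":
        g = gene if isinstance(gene, Gene) else get_gene(gene)
        ends = sorted(set(int(e) for e in exon_ends if 0 < int(e) < cds_length))
        ends.append(int(cds_length))
        exons = []
        start = 1
        for end in ends:
            exons.append((start, end))
            start = end + 1
        return cls(g, tuple(exons))

    @property
    def cds_length(self) -> int:
        return self.exons[-1][1]

    def exon_containing(self, position: int) -> tuple[int, int]:
        for interval in self.exons:
            if interval[0] <= position <= interval[1]:
                return interval
        raise ValueError(
            f"coding position {position} outside transcript model for {self.gene.name} "
            f"(CDS length {self.cds_length})"
        )

    def near_exon_end(self, position: int, window: int) -> bool:
        """True iff position is within the last `window` bases of an interior exon."""
        start, end = self.exon_containing(position)
        return end != self.cds_length and end - position < window

    def near_exon_start(self, position: int, window: int) -> bool:
        """True iff position is within the first `window` bases of a non-first exon."""
        start, end = self.exon_containing(position)
        return start != 1 and position - start < window


class EditType(enum.Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"


@dataclass(frozen=True)
class ParsedCdnaVariant:
    """Structured decomposition of an HGVS ``c.`` description.

    For substitutions, (position, intron_offset) locate the changed base
    and ref/alt hold single nucleotides.  For deletions, the span runs
    from (position, intron_offset) to (span_end_position,
    span_end_offset), both inclusive, ordered lexicographically.
    """

    gene: Gene
    position: int
    intron_offset: int
    edit_type: EditType
    ref_base: str = ""
    alt_base: str = ""
    span_end_position: Optional[int] = None
    span_end_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("coding position must be >= 1")
        if self.edit_type is EditType.SUBSTITUTION:
            if len(self.ref_base) != 1 or len(self.alt_base) != 1:
                raise ValueError("substitution must have single ref and alt bases")
        else:
            end = (self.span_end_position, self.span_end_offset)
            if end[0] is None or end[1] is None:
                raise ValueError("deletion must carry span end position and offset")
            if (end[0], end[1]) < (self.position, self.intron_offset):
                raise ValueError("deletion span end precedes span start")

    @property
    def is_exonic(self) -> bool:
        return self.intron_offset == 0

    @property
    def key(self) -> str:
        from col4dx.hgvs import render_cdna  # local import to avoid cycle

        return variant_key(self.gene, render_cdna(self))

    def to_dict(self) -> dict:
        return {
            "gene": self.gene.name,
            "position": self.position,
            "intron_offset": self.intron_offset,
            "edit_type": self.edit_type.value,
            "ref_base": self.ref_base,
            "alt_base": self.alt_base,
            "span_end_position": self.span_end_position,
            "span_end_offset": self.span_end_offset,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParsedCdnaVariant":
        return cls(
            gene=get_gene(d["gene"]),
            position=d["position"],
            intron_offset=d["intron_offset"],
            edit_type=EditType(d["edit_type"]),
            ref_base=d.get("ref_base", ""),
            alt_base=d.get("alt_base", ""),
            span_end_position=d.get("span_end_position"),
            span_end_offset=d.get("span_end_offset"),
        )


@dataclass(frozen=True)
class ProteinChange:
    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("protein position must be >= 1")

    @property
    def is_missense(self) -> bool:
        return self.ref_aa != self.alt_aa

    def to_dict(self) -> dict:
        return {"ref_aa": self.ref_aa, "position": self.position, "alt_aa": self.alt_aa}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProteinChange":
        return cls(d["ref_aa"], d["position"], d["alt_aa"])

    def __str__(self) -> str:
        return f"p.{self.ref_aa}{self.position}{self.alt_aa}"


class ConsequenceCategory(enum.Enum):
    MISSENSE = "missense"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_REGION_EXONIC = "splice_region_exonic"
    SPLICE_REGION_INTRONIC = "splice_region_intronic"
    INTRONIC = "intronic"
    DELETION_WITH_SPLICE = "deletion_with_splice"
    SYNONYMOUS = "synonymous"


#: categories counted as "splice" in cohort tallies
SPLICE_CATEGORIES = frozenset(
    {
        ConsequenceCategory.SPLICE_DONOR,
        ConsequenceCategory.SPLICE_ACCEPTOR,
        ConsequenceCategory.SPLICE_REGION_EXONIC,
        ConsequenceCategory.SPLICE_REGION_INTRONIC,
    }
)


@dataclass(frozen=True)
class Consequence:
    """A single primary category plus an optional secondary splice flag.

    The secondary flag marks missense changes that also sit on conserved
    exon-terminal splice bases (e.g. the first base of an exon): they are
    tallied as missense but retain splice evidence for classification.
    """

    category: ConsequenceCategory
    secondary_splice: bool = False

    def to_dict(self) -> dict:
        return {"category": self.category.value, "secondary_splice": self.secondary_splice}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Consequence":
        return cls(ConsequenceCategory(d["category"]), bool(d.get("secondary_splice", False)))


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Affection(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Individual:
    id: str
    sex: Sex
    affection: Affection = Affection.UNKNOWN
    father_id: Optional[str] = None
    mother_id: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "sex": self.sex.value,
            "affection": self.affection.value,
            "father_id": self.father_id,
            "mother_id": self.mother_id,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Individual":
        return cls(d["id"], Sex(d["sex"]), Affection(d["affection"]), d.get("father_id"), d.get("mother_id"))


@dataclass
class Pedigree:
    family_id: str
    members: dict[str, Individual] = field(default_factory=dict)

    def add(self, individual: Individual) -> None:
        if individual.id in self.members:
            raise ValueError(f"duplicate individual id {individual.id!r} in family {self.family_id}")
        self.members[individual.id] = individual

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.members

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members.values())

    def get(self, individual_id: str) -> Individual:
        return self.members[individual_id]

    def founders(self) -> list[Individual]:
        return [m for m in self if m.father_id is None and m.mother_id is None]

    def children_of(self, individual_id: str) -> list[Individual]:
        return [m for m in self if individual_id in (m.father_id, m.mother_id)]

    def with_affection(self, individual_id: str, affection: Affection) -> None:
        self.members[individual_id] = replace(self.members[individual_id], affection=affection)

    def to_dict(self) -> dict:
        return {"family_id": self.family_id, "members": [m.to_dict() for m in self]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Pedigree":
        ped = cls(d["family_id"])
        for m in d["members"]:
            ped.add(Individual.from_dict(m))
        return ped


@dataclass(frozen=True)
class GenotypeCall:
    individual_id: str
    variant_key: str
    allele_count: int

    def __post_init__(self) -> None:
        if self.allele_count not in (0, 1, 2):
            raise ValueError("allele_count must be 0, 1 or 2")


class PublishedStatus(enum.Enum):
    NONE = "none"
    POLYMORPHISM = "polymorphism"
    PATHOGENIC = "pathogenic"


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-variant external evidence: database status, control presence, MAF."""

    variant_key: str
    published_status: PublishedStatus = PublishedStatus.NONE
    source: str = ""
    in_controls: bool = False
    population_maf: Optional[float] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.population_maf is not None and not (0.0 <= self.population_maf <= 1.0):
            raise ValueError("population_maf must lie in [0, 1]")


class ClassificationLabel(enum.Enum):
    POLYMORPHISM = "polymorphism"
    PATHOGENIC = "pathogenic"
    PRESUMED_PATHOGENIC = "presumed_pathogenic"
    VUS = "vus"


@dataclass(frozen=True)
class CriterionResult:
    """Outcome of one classification criterion; passed=None means not evaluable."""

    name: str
    passed: Optional[bool]
    evidence: str = ""

    def to_dict(self) -> dict:
        return {"name": self.name, "passed": self.passed, "evidence": self.evidence}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CriterionResult":
        return cls(d["name"], d["passed"], d.get("evidence", ""))


@dataclass(frozen=True)
class ClassificationResult:
    variant_key: str
    label: ClassificationLabel
    criteria_trace: tuple[CriterionResult, ...] = ()
    flags: tuple[str, ...] = ()

    @property
    def is_novel(self) -> bool:
        return "novel" in self.flags

    def to_dict(self) -> dict:
        return {
            "variant_key": self.variant_key,
            "label": self.label.value,
            "criteria_trace": [c.to_dict() for c in self.criteria_trace],
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClassificationResult":
        return cls(
            d["variant_key"],
            ClassificationLabel(d["label"]),
            tuple(CriterionResult.from_dict(c) for c in d.get("criteria_trace", [])),
            tuple(d.get("flags", [])),
        )


class InheritanceMode(enum.Enum):
    """Family-level diagnosis vocabulary.

    Deliberately contains no "autosomal dominant AS" value: a single
    heterozygous autosomal mutation is the FBH carrier state, two are
    semi-dominant autosomal AS.
    """

    X_LINKED_AS = "x_linked_as"
    AUTOSOMAL_AS = "autosomal_as"
    FBH = "fbh"
    DIGENIC_FLAG = "digenic_flag"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class FamilyDiagnosis:
    family_id: str
    mode: InheritanceMode
    supporting_variants: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()
    composite: bool = False

    def to_dict(self) -> dict:
        return {
            "family_id": self.family_id,
            "mode": self.mode.value,
            "supporting_variants": list(self.supporting_variants),
            "warnings": list(self.warnings),
            "composite": self.composite,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FamilyDiagnosis":
        return cls(
            d["family_id"],
            InheritanceMode(d["mode"]),
            tuple(d.get("supporting_variants", [])),
            tuple(d.get("warnings", [])),
            bool(d.get("composite", False)),
        )


@dataclass(frozen=True)
class PedigreeViolation:
    kind: str
    individual_id: str
    message: str


def validate_pedigree(
    pedigree: Pedigree, genotypes: Iterable[GenotypeCall] = ()
) -> list[PedigreeViolation]:
    """Check structural pedigree invariants; violations are data, not exceptions.

    Checks: parent references resolve within the family, fathers are
    male, mothers are female, the parent graph is acyclic, and — when
    genotype calls are supplied — males never carry two alleles of a
    COL4A5 (X-linked) variant.
    """
    violations: list[PedigreeViolation] = []
    graph = nx.DiGraph()
    for member in pedigree:
        graph.add_node(member.id)
        for parent_id, expected_sex, role in (
            (member.father_id, Sex.MALE, "father"),
            (member.mother_id, Sex.FEMALE, "mother"),
        ):
            if parent_id is None:
                continue
            if parent_id not in pedigree:
                violations.append(
                    PedigreeViolation(
                        "unresolved_parent", member.id, f"{role} {parent_id!r} not in family {pedigree.family_id}"
                    )
                )
                continue
            parent = pedigree.get(parent_id)
            if parent.sex is not expected_sex:
                violations.append(
                    PedigreeViolation(
                        "parent_sex", member.id, f"{role} {parent_id!r} has sex {parent.sex.value}"
                    )
                )
            graph.add_edge(parent_id, member.id)
    for cycle in nx.simple_cycles(graph):
        violations.append(
            PedigreeViolation("cycle", cycle[0], f"ancestry cycle through {' -> '.join(cycle)}")
        )
    for call in genotypes:
        if call.individual_id not in pedigree:
            violations.append(
                PedigreeViolation(
                    "unknown_individual", call.individual_id, f"genotyped individual not in pedigree"
                )
            )
            continue
        member = pedigree.get(call.individual_id)
        try:
            gene = gene_of_key(call.variant_key)
        except (ValueError, UnknownGeneError):
            violations.append(
                PedigreeViolation("bad_variant_key", call.individual_id, f"unparseable key {call.variant_key!r}")
            )
            continue
        if gene.is_x_linked and member.sex is Sex.MALE and call.allele_count > 1:
            violations.append(
                PedigreeViolation(
                    "hemizygosity",
                    call.individual_id,
                    f"male carries {call.allele_count} alleles of X-linked {call.variant_key}",
                )
            )
    return violations
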