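"""Family-level diagnosis and the functional-trimer dosage model.

The dosage model treats the type-IV collagen α3α4α5 network
quantitatively: each heterotrimer needs one functional chain from each
of COL4A3, COL4A4 and COL4A5, so the expected fraction of fully
functional trimer is the product of the per-gene functional-chain
fractions.  For COL4A5 the female term is the fraction of cells whose
active X carries a wild-type allele (random X inactivation, possibly
skewed).  A comparison model for homotypic collagens (identical chains)
shows why a heterozygous missense allele there behaves dominant-negative
(0.5^n functional molecules) while heterotrimer genes lose only half.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from col4dx.config import PhenotypeThresholds
from col4dx.core import (
    FamilyDiagnosis,
    Gene,
    GenotypeCall,
    InheritanceMode,
    Pedigree,
    Sex,
    gene_of_key,
    get_gene,
)

__all__ = [
    "DosageGenotype",
    "functional_trimer_fraction",
    "homotypic_assembly_fraction",
    "PhenotypeClass",
    "phenotype_class",
    "Zygosity",
    "SupportingVariant",
    "Phase",
    "infer_phase",
    "classify_family",
    "dosage_from_genotypes",
]


@dataclass(frozen=True)
class DosageGenotype:
    """Per-gene functional (wild-type) allele counts for one person.

    ``x_wt_active_fraction`` applies to heterozygous female COL4A5
    carriers only: the fraction of cells expressing the wild-type
    allele.  ``None`` means unknown and defaults to the balanced value
    0.5 with an implicit uncertainty interval of [0, 1].
    """

    col4a3_wt: int = 2
    col4a4_wt: int = 2
    col4a5_wt: int = 2
    sex: Sex = Sex.FEMALE
    x_wt_active_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.col4a3_wt not in (0, 1, 2) or self.col4a4_wt not in (0, 1, 2):
            raise ValueError("autosomal functional-allele counts must be 0, 1 or 2")
        max_x = 1 if self.sex is Sex.MALE else 2
        if not (0 <= self.col4a5_wt <= max_x):
            raise ValueError(f"col4a5_wt must be 0..{max_x} for sex {self.sex.value}")
        if self.x_wt_active_fraction is not None and not (0.0 <= self.x_wt_active_fraction <= 1.0):
            raise ValueError("x_wt_active_fraction must lie in [0, 1]")


def functional_trimer_fraction(g: DosageGenotype) -> float:
    """Expected fraction of fully functional α3α4α5 trimer, in [0, 1].

    f = (col4a3_wt / 2) x (col4a4_wt / 2) x x_term, where x_term is the
    hemizygous allele count for males and the active-X wild-type cell
    fraction for females (1 with two wild-type alleles, 0 with none,
    the X-inactivation fraction for heterozygotes).
    """
    if g.sex is Sex.MALE:
        x_term = float(g.col4a5_wt)
    elif g.col4a5_wt == 2:
        x_term = 1.0
    elif g.col4a5_wt == 0:
        x_term = 0.0
    else:
        x_term = 0.5 if g.x_wt_active_fraction is None else g.x_wt_active_fraction
    return (g.col4a3_wt / 2.0) * (g.col4a4_wt / 2.0) * x_term


def homotypic_assembly_fraction(chains_per_molecule: int, wt_chain_fraction: float) -> float:
    """Functional-molecule fraction under random homotypic assembly.

    For collagens built from identical chains, a molecule is functional
    only if every one of its ``chains_per_molecule`` chains is
    wild-type, so a heterozygote (wild-type chain fraction 0.5) retains
    0.25 of functional dimer and 0.125 of functional trimer — the
    dominant-negative contrast with a null allele's ~50%.
    """
    if chains_per_molecule not in (2, 3):
        raise ValueError("chains_per_molecule must be 2 or 3")
    if not (0.0 <= wt_chain_fraction <= 1.0):
        raise ValueError("wt_chain_fraction must lie in [0, 1]")
    return wt_chain_fraction ** chains_per_molecule


class PhenotypeClass(enum.Enum):
    NORMAL = "normal"
    FBH_TBMN_SPECTRUM = "fbh_tbmn_spectrum"
    AS_SEVERE = "as_severe"


def phenotype_class(
    f: float, thresholds: PhenotypeThresholds = PhenotypeThresholds()
) -> PhenotypeClass:
    """Map a functional-trimer fraction onto the phenotype spectrum.

    The disease spectrum is continuous in f; the cutoffs (default
    f >= 0.75 normal, f < 0.25 severe) are configurable conventions,
    monotone non-increasing in severity as f grows.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError("functional fraction must lie in [0, 1]")
    if f >= thresholds.normal_min:
        return PhenotypeClass.NORMAL
    if f < thresholds.severe_max:
        return PhenotypeClass.AS_SEVERE
    return PhenotypeClass.FBH_TBMN_SPECTRUM


class Zygosity(enum.Enum):
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"


@dataclass(frozen=True)
class SupportingVariant:
    """A (presumed-)pathogenic variant supporting a family diagnosis."""

    variant_key: str
    zygosity: Zygosity = Zygosity.HET

    @property
    def gene(self) -> Gene:
        return gene_of_key(self.variant_key)


class Phase(enum.Enum):
    UNKNOWN = "unknown"
    TRANS = "trans"
    CIS = "cis"


def infer_phase(
    pedigree: Pedigree,
    genotypes: Iterable[GenotypeCall],
    key_a: str,
    key_b: str,
) -> Phase:
    """Infer the phase of two variants in one gene from parental genotypes.

    TRANS is proven when a double carrier has genotyped parents each
    carrying exactly one of the two variants (different ones); CIS when
    a double carrier has one double-carrier parent while the other
    genotyped parent carries neither.  Anything else stays UNKNOWN.
    """
    carried: dict[str, set[str]] = {}
    for call in genotypes:
        if call.variant_key in (key_a, key_b) and call.allele_count > 0:
            carried.setdefault(call.individual_id, set()).add(call.variant_key)
    for individual_id, keys in carried.items():
        if keys != {key_a, key_b} or individual_id not in pedigree:
            continue
        member = pedigree.get(individual_id)
        parent_sets = [
            carried.get(pid, set())
            for pid in (member.father_id, member.mother_id)
            if pid is not None and pid in pedigree
        ]
        if len(parent_sets) != 2:
            continue
        if sorted(len(s) for s in parent_sets) == [1, 1] and parent_sets[0] != parent_sets[1]:
            return Phase.TRANS
        if sorted(len(s) for s in parent_sets) == [0, 2]:
            return Phase.CIS
    return Phase.UNKNOWN


def classify_family(
    family_id: str,
    variants: Sequence[SupportingVariant],
    pedigree: Optional[Pedigree] = None,
    phase: Phase = Phase.UNKNOWN,
) -> FamilyDiagnosis:
    """Assign an inheritance-mode diagnosis from the classified variants.

    Any COL4A5 variant gives X-linked AS; two distinct variants in one
    autosomal gene (or one homozygous) give autosomal semi-dominant AS
    (FBH instead if the two are proven on one haplotype); exactly one
    heterozygous autosomal variant gives FBH; one variant in each of
    COL4A3 and COL4A4 raises the digenic flag; none leaves the family
    unresolved.  Simultaneous X-linked and autosomal findings yield a
    flagged composite X-linked result, never an exception.  The output
    vocabulary deliberately lacks an "autosomal dominant AS" value.
    """
    keys = tuple(dict.fromkeys(v.variant_key for v in variants))
    x_vars = [v for v in variants if v.gene.is_x_linked]
    by_auto_gene: dict[str, list[SupportingVariant]] = {}
    for v in variants:
        if not v.gene.is_x_linked:
            by_auto_gene.setdefault(v.gene.name, []).append(v)

    warnings: list[str] = []
    composite = False
    if x_vars and by_auto_gene:
        composite = True
        warnings.append(
            "composite finding: COL4A5 variant(s) co-occur with autosomal variant(s); "
            "X-linked AS reported as primary mode"
        )
        mode = InheritanceMode.X_LINKED_AS
    elif x_vars:
        mode = InheritanceMode.X_LINKED_AS
    elif len(by_auto_gene) == 2 and all(len(vs) == 1 for vs in by_auto_gene.values()):
        mode = InheritanceMode.DIGENIC_FLAG
        warnings.append(
            "digenic constellation (one variant in each of COL4A3 and COL4A4): "
            "no reference case establishes this mode; review manually"
        )
    elif by_auto_gene:
        biallelic = any(
            len({v.variant_key for v in vs}) >= 2 or any(v.zygosity is Zygosity.HOM for v in vs)
            for vs in by_auto_gene.values()
        )
        if biallelic:
            if phase is Phase.CIS:
                mode = InheritanceMode.FBH
                warnings.append(
                    "two autosomal variants proven on one haplotype: single functional hit, FBH"
                )
            else:
                mode = InheritanceMode.AUTOSOMAL_AS
                if phase is Phase.UNKNOWN and any(
                    len({v.variant_key for v in vs}) >= 2 for vs in by_auto_gene.values()
                ):
                    warnings.append("phase of the two autosomal variants unknown; trans assumed")
        else:
            mode = InheritanceMode.FBH
    else:
        mode = InheritanceMode.UNRESOLVED

    return FamilyDiagnosis(family_id, mode, keys, tuple(warnings), composite)


def dosage_from_genotypes(
    calls: Iterable[GenotypeCall],
    sex: Sex,
    x_wt_active_fraction: Optional[float] = None,
) -> DosageGenotype:
    """Build a DosageGenotype from per-variant mutant allele counts."""
    mutant = {"COL4A3": 0, "COL4A4": 0, "COL4A5": 0}
    for call in calls:
        gene = gene_of_key(call.variant_key)
        mutant[gene.name] += call.allele_count
    x_total = 1 if sex is Sex.MALE else 2
    return DosageGenotype(
        col4a3_wt=max(0, 2 - mutant["COL4A3"]),
        col4a4_wt=max(0, 2 - mutant["COL4A4"]),
        col4a5_wt=max(0, x_total - mutant["COL4A5"]),
        sex=sex,
        x_wt_active_fraction=x_wt_active_fraction,
    )
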