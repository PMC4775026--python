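"""Synthetic pedigrees, genotypes, control cohorts and depth tracks.

The simulator produces multi-generation families segregating causal
COL4A variants under three inheritance modes, with background
polymorphisms drawn at the packaged reference minor-allele frequencies,
affection statuses derived from the functional-trimer dosage model
(Beta-distributed X-inactivation skew for female COL4A5 carriers), a
diploid/X-aware control cohort, and negative-binomial per-base amplicon
depth.  A fixed seed makes every draw reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from col4dx.config import PhenotypeThresholds, PipelineConfig, default_config
from col4dx.core import (
    Affection,
    AnnotationRecord,
    FamilyDiagnosis,
    GenotypeCall,
    Individual,
    InheritanceMode,
    Pedigree,
    PublishedStatus,
    Sex,
    gene_of_key,
)
from col4dx.inheritance import (
    DosageGenotype,
    PhenotypeClass,
    SupportingVariant,
    Zygosity,
    classify_family,
    functional_trimer_fraction,
    phenotype_class,
)
from col4dx.pathogenicity import classify_cohort, segregates_exclusively
from col4dx.qc import DepthTrack, TargetRegionSet

__all__ = [
    "SimulationConfig",
    "SimulatedFamily",
    "simulate_family",
    "ControlCohort",
    "simulate_control_cohort",
    "simulate_depth_track",
    "default_background_mafs",
    "CAUSAL_VARIANTS",
    "sample_child_alleles",
    "recover_family_mode",
]

#: default causal variants per simulated mode (drawn from the reference mutation set)
CAUSAL_VARIANTS: Mapping[InheritanceMode, tuple[str, ...]] = {
    InheritanceMode.X_LINKED_AS: ("COL4A5:c.2741G>A",),
    InheritanceMode.AUTOSOMAL_AS: ("COL4A3:c.687G>A", "COL4A3:c.3490G>T"),
    InheritanceMode.FBH: ("COL4A3:c.3410G>A",),
}


def default_background_mafs() -> dict[str, float]:
    """Reference polymorphism MAFs from the packaged control-cohort table."""
    from col4dx.io import load_fixture_bundle

    return {
        row.key: row.maf
        for row in load_fixture_bundle().polymorphisms
        if row.maf is not None
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    mode: InheritanceMode = InheritanceMode.X_LINKED_AS
    generations: int = 3
    mean_sibship: float = 2.5
    background_mafs: Optional[Mapping[str, float]] = None
    x_skew_beta_alpha: float = 5.0
    phenotype_thresholds: PhenotypeThresholds = field(default_factory=PhenotypeThresholds)
    control_cohort_n: int = 66

    def __post_init__(self) -> None:
        if self.mode not in CAUSAL_VARIANTS:
            raise ValueError(f"unsupported simulation mode {self.mode}")
        if self.generations < 2:
            raise ValueError("need at least two generations")
        if self.background_mafs is not None:
            for key, maf in self.background_mafs.items():
                if not (0.0 <= maf <= 1.0):
                    raise ValueError(f"MAF for {key} outside [0, 1]")

    def resolved_background_mafs(self) -> Mapping[str, float]:
        return self.background_mafs if self.background_mafs is not None else default_background_mafs()


Alleles = tuple[int, ...]  # one 0/1 entry per chromosome copy


def _n_copies(key: str, sex: Sex) -> int:
    return 1 if gene_of_key(key).is_x_linked and sex is Sex.MALE else 2


def sample_child_alleles(
    father: Mapping[str, Alleles],
    mother: Mapping[str, Alleles],
    child_sex: Sex,
    rng: np.random.Generator,
) -> dict[str, Alleles]:
    """Mendelian / X-linked transmission for one child.

    Autosomal: one random allele from each parent.  X-linked: the child
    always receives one random maternal X allele; daughters additionally
    receive the father's single X allele, sons never do.
    """
    child: dict[str, Alleles] = {}
    for key in father:
        maternal = mother[key][rng.integers(len(mother[key]))]
        if gene_of_key(key).is_x_linked:
            if child_sex is Sex.MALE:
                child[key] = (maternal,)
            else:
                child[key] = (father[key][0], maternal)
        else:
            paternal = father[key][rng.integers(len(father[key]))]
            child[key] = (paternal, maternal)
    return child


@dataclass
class SimulatedFamily:
    pedigree: Pedigree
    alleles: dict[str, dict[str, Alleles]]  # individual -> variant key -> alleles
    truth: dict

    def genotype_calls(self) -> list[GenotypeCall]:
        calls = []
        for individual_id, genotype in self.alleles.items():
            for key, alleles in genotype.items():
                calls.append(GenotypeCall(individual_id, key, int(sum(alleles))))
        return calls


def _sample_background(keys_mafs: Mapping[str, float], sex: Sex, rng: np.random.Generator) -> dict[str, Alleles]:
    genotype = {}
    for key, maf in keys_mafs.items():
        copies = _n_copies(key, sex)
        genotype[key] = tuple(int(rng.random() < maf) for _ in range(copies))
    return genotype


def simulate_family(config: SimulationConfig, rng: Optional[np.random.Generator] = None, family_id: str = "SIM") -> SimulatedFamily:
    """Simulate one family segregating causal variant(s) under the chosen mode.

    Founders carry the causal allele(s): for X-linked AS the founding
    mother is a heterozygous COL4A5 carrier; for autosomal AS each
    founding parent is heterozygous for a different variant of the same
    autosomal gene (guaranteeing trans phase); for FBH the founding
    mother carries one heterozygous autosomal variant.  Affection is
    ``phenotype_class(functional_trimer_fraction) != NORMAL`` with the
    X-inactivation fraction of heterozygous female carriers drawn from
    Beta(alpha, alpha).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    causal = CAUSAL_VARIANTS[config.mode]
    background = dict(config.resolved_background_mafs())
    all_keys = {**{k: 0.0 for k in causal}, **background}

    ped = Pedigree(family_id)
    alleles: dict[str, dict[str, Alleles]] = {}
    counter = [0]

    def new_member(sex: Sex, father_id=None, mother_id=None) -> Individual:
        counter[0] += 1
        ind = Individual(str(counter[0]), sex, Affection.UNKNOWN, father_id, mother_id)
        ped.add(ind)
        return ind

    def founder(sex: Sex) -> Individual:
        ind = new_member(sex)
        alleles[ind.id] = _sample_background(all_keys, sex, rng)
        return ind

    father = founder(Sex.MALE)
    mother = founder(Sex.FEMALE)

    def set_causal(individual: Individual, key: str) -> None:
        copies = _n_copies(key, individual.sex)
        alleles[individual.id][key] = (1,) + (0,) * (copies - 1)

    if config.mode is InheritanceMode.X_LINKED_AS:
        set_causal(mother, causal[0])
    elif config.mode is InheritanceMode.AUTOSOMAL_AS:
        set_causal(father, causal[0])
        set_causal(mother, causal[1])
    else:  # FBH
        set_causal(mother, causal[0])

    couples = [(father, mother)]
    for generation in range(1, config.generations):
        next_couples = []
        for dad, mom in couples:
            n_children = max(1, int(rng.poisson(config.mean_sibship)))
            for _ in range(n_children):
                sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
                child = new_member(sex, father_id=dad.id, mother_id=mom.id)
                alleles[child.id] = sample_child_alleles(alleles[dad.id], alleles[mom.id], sex, rng)
                if generation < config.generations - 1:
                    spouse = founder(Sex.FEMALE if sex is Sex.MALE else Sex.MALE)
                    next_couples.append((child, spouse) if sex is Sex.MALE else (spouse, child))
        couples = next_couples

    # affection from the dosage model
    f_by_individual: dict[str, float] = {}
    x_fraction: dict[str, float] = {}
    non_penetrant: list[str] = []
    for member in list(ped):
        mutant = {"COL4A3": 0, "COL4A4": 0, "COL4A5": 0}
        for key in causal:
            mutant[gene_of_key(key).name] += sum(alleles[member.id][key])
        x_total = 1 if member.sex is Sex.MALE else 2
        x_frac = None
        if member.sex is Sex.FEMALE and mutant["COL4A5"] == 1:
            x_frac = float(rng.beta(config.x_skew_beta_alpha, config.x_skew_beta_alpha))
            x_fraction[member.id] = x_frac
        dosage = DosageGenotype(
            col4a3_wt=max(0, 2 - mutant["COL4A3"]),
            col4a4_wt=max(0, 2 - mutant["COL4A4"]),
            col4a5_wt=max(0, x_total - mutant["COL4A5"]),
            sex=member.sex,
            x_wt_active_fraction=x_frac,
        )
        f = functional_trimer_fraction(dosage)
        f_by_individual[member.id] = f
        carrier = any(mutant.values())
        affected = phenotype_class(f, config.phenotype_thresholds) is not PhenotypeClass.NORMAL
        if carrier and not affected:
            non_penetrant.append(member.id)
        ped.with_affection(
            member.id, Affection.AFFECTED if affected else Affection.UNAFFECTED
        )

    truth = {
        "mode": config.mode.value,
        "causal_variants": list(causal),
        "functional_fraction": f_by_individual,
        "x_wt_active_fraction": x_fraction,
        "non_penetrant_carriers": non_penetrant,
    }
    return SimulatedFamily(ped, alleles, truth)


@dataclass(frozen=True)
class ControlCohort:
    sexes: Mapping[str, Sex]
    allele_counts: Mapping[str, Mapping[str, int]]  # individual -> key -> mutant alleles
    estimated_mafs: Mapping[str, float]
    allele_numbers: Mapping[str, int]

    def control_table(self) -> dict[str, tuple[int, int]]:
        """Per-variant (allele count, allele number) as the rule engine consumes it."""
        totals = {}
        for key, number in self.allele_numbers.items():
            count = sum(counts.get(key, 0) for counts in self.allele_counts.values())
            totals[key] = (count, number)
        return totals


def simulate_control_cohort(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> ControlCohort:
    """Sample an unrelated control cohort at the configured MAFs (X-aware).

    The per-variant MAF estimator is mutant allele count divided by
    allele number; for COL4A5 males contribute one allele each.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    mafs = config.resolved_background_mafs()
    sexes = {
        f"C{i + 1}": (Sex.MALE if rng.random() < 0.5 else Sex.FEMALE)
        for i in range(config.control_cohort_n)
    }
    allele_counts: dict[str, dict[str, int]] = {}
    for individual_id, sex in sexes.items():
        genotype = _sample_background(mafs, sex, rng)
        allele_counts[individual_id] = {key: int(sum(a)) for key, a in genotype.items()}
    allele_numbers = {
        key: sum(_n_copies(key, sex) for sex in sexes.values()) for key in mafs
    }
    estimated = {
        key: (
            sum(c.get(key, 0) for c in allele_counts.values()) / allele_numbers[key]
            if allele_numbers[key]
            else 0.0
        )
        for key in mafs
    }
    return ControlCohort(sexes, allele_counts, estimated, allele_numbers)


def simulate_depth_track(
    targets: TargetRegionSet,
    mean: float,
    dispersion: float,
    seed: int | np.random.Generator = 0,
) -> DepthTrack:
    """Independent negative-binomial per-base depths over the target set.

    Parameterized by mean m and dispersion r with variance m + m^2/r,
    so dispersion -> infinity approaches Poisson.
    """
    if mean <= 0 or dispersion <= 0:
        raise ValueError("mean and dispersion must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = dispersion / (dispersion + mean)
    depths = rng.negative_binomial(dispersion, p, size=targets.total_bp)
    return DepthTrack(depths.astype(np.int64), targets)


def recover_family_mode(
    family: SimulatedFamily, pipeline_config: Optional[PipelineConfig] = None
) -> FamilyDiagnosis:
    """Run the full pipeline on a simulated family and return its diagnosis.

    Variants observed in the family are annotated the way a real run
    would see them: background polymorphisms are present in the control
    set at their table MAF, causal variants are absent from controls and
    unpublished.  Segregation is recomputed from the simulated genotypes
    and affection statuses; consequences are re-derived from HGVS.
    """
    from col4dx.io import load_fixture_bundle

    cfg = pipeline_config or default_config()
    bundle = load_fixture_bundle()
    all_records = {r.variant_key: r for r in bundle.variant_records(cfg)}
    annotations = bundle.annotations()

    calls = family.genotype_calls()
    observed = sorted({c.variant_key for c in calls if c.allele_count > 0})
    records = []
    seg = {}
    zygosity: dict[str, Zygosity] = {}
    for key in observed:
        record = all_records.get(key)
        if record is None:
            continue  # variant outside the reference set: not classifiable here
        records.append(record)
        seg[key] = segregates_exclusively(
            key, calls, family.pedigree, record.gene, cfg.pathogenicity
        )
        counts = [c.allele_count for c in calls if c.variant_key == key and c.allele_count]
        if record.gene.is_x_linked and any(
            family.pedigree.get(c.individual_id).sex is Sex.MALE
            for c in calls
            if c.variant_key == key and c.allele_count
        ):
            zygosity[key] = Zygosity.HEMI
        else:
            zygosity[key] = Zygosity.HOM if counts and max(counts) == 2 else Zygosity.HET

    results = classify_cohort(
        records, annotations, seg, cfg.pathogenicity
    )
    supporting = [
        SupportingVariant(r.variant_key, zygosity[r.variant_key])
        for r in results
        if r.label.value in ("pathogenic", "presumed_pathogenic")
    ]
    return classify_family(family.pedigree.family_id, supporting, family.pedigree)
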