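"""Readers/writers for the formats the pipeline touches, plus packaged fixtures.

Formats: 6-column pre-MAKEPED PED; TSV variant/annotation/control
tables; a minimal VCFv4.2 dialect whose records carry ``GENE=`` and
``CDNA=`` INFO subfields (genomic coordinates are synthetic — this
package never performs genomic liftover); BED targets with per-base
depth as 3-column TSV or bedgraph; JSON/TSV reports.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pysam

from col4dx.config import PipelineConfig, default_config
from col4dx.core import (
    Affection,
    AnnotationRecord,
    ClassificationResult,
    Consequence,
    ConsequenceCategory,
    EditType,
    FamilyDiagnosis,
    GenotypeCall,
    Individual,
    ParsedCdnaVariant,
    Pedigree,
    ProteinChange,
    PublishedStatus,
    Sex,
    UnknownGeneError,
    get_gene,
    variant_key,
)
from col4dx.hgvs import (
    classify_consequence,
    is_collagenous_glycine_substitution,
    parse_cdna,
    parse_protein,
)
from col4dx.inheritance import SupportingVariant, Zygosity, classify_family
from col4dx.pathogenicity import (
    SegregationResult,
    VariantRecord,
    classify_cohort,
    summarize,
)

__all__ = [
    "FixtureRow",
    "CaseFixture",
    "FixtureBundle",
    "load_fixture_bundle",
    "TableError",
    "read_variant_table",
    "read_annotation_table",
    "read_control_table",
    "read_ped",
    "write_ped",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "read_depth_track",
    "write_report",
    "read_report",
]


class TableError(ValueError):
    """Malformed tabular input; message carries the file and line number."""


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureRow:
    """One transcribed variant-table row (polymorphism or mutation)."""

    gene: str
    cdna: str
    protein: str
    consequence_label: str
    secondary_splice: bool
    maf: Optional[float]
    published_status: PublishedStatus
    source: str
    cases: tuple[str, ...]
    note: str

    @property
    def key(self) -> str:
        return variant_key(self.gene, self.cdna)


@dataclass(frozen=True)
class CaseFixture:
    """Variant-to-case assignment for one family or isolated individual."""

    case_id: str
    kind: str  # "family" | "individual"
    variants: tuple[tuple[str, Zygosity], ...]


@dataclass(frozen=True)
class FixtureBundle:
    polymorphisms: tuple[FixtureRow, ...]
    mutations: tuple[FixtureRow, ...]
    cases: tuple[CaseFixture, ...]

    @property
    def all_rows(self) -> tuple[FixtureRow, ...]:
        return self.polymorphisms + self.mutations

    def variant_records(self, config: Optional[PipelineConfig] = None) -> list[VariantRecord]:
        """Build rule-engine inputs by re-deriving every consequence from HGVS."""
        cfg = config or default_config()
        records = []
        for row in self.all_rows:
            gene = get_gene(row.gene)
            parsed = parse_cdna(row.cdna, gene)
            protein = parse_protein(row.protein) if row.protein else None
            consequence = classify_consequence(parsed, protein, cfg.transcripts[gene.name])
            collagenous = bool(
                protein and is_collagenous_glycine_substitution(protein, cfg.domains, gene)
            )
            records.append(
                VariantRecord(row.key, gene, consequence, protein, parsed, collagenous)
            )
        return records

    def annotations(self) -> dict[str, AnnotationRecord]:
        out = {}
        for row in self.polymorphisms:
            out[row.key] = AnnotationRecord(
                row.key, row.published_status, row.source, in_controls=True,
                population_maf=row.maf, note=row.note,
            )
        for row in self.mutations:
            out[row.key] = AnnotationRecord(
                row.key, row.published_status, row.source, in_controls=False,
                population_maf=None, note=row.note,
            )
        return out

    def segregations(self) -> dict[str, SegregationResult]:
        """Validated-by-sequencing segregation outcomes for family-linked mutations.

        Per-member genotypes are not transcribed for the reference
        families, so these results carry the confirmed verdict
        (carriers confined to affected members) without detail rows.
        Variants seen only in isolated individuals get no entry.
        """
        case_kind = {c.case_id: c.kind for c in self.cases}
        out = {}
        for row in self.mutations:
            families = [c for c in row.cases if case_kind.get(c) == "family"]
            if families:
                out[row.key] = SegregationResult(row.key, families[0], True)
        return out

    def run_reference_cohort(self, config: Optional[PipelineConfig] = None):
        """Full fixture run: classify all variants, then diagnose all cases.

        Returns ``(classifications, summary, diagnoses)``.
        """
        cfg = config or default_config()
        results = classify_cohort(
            self.variant_records(cfg), self.annotations(), self.segregations(), cfg.pathogenicity
        )
        labels = {r.variant_key: r.label.value for r in results}
        diagnoses = []
        for case in self.cases:
            supporting = [
                SupportingVariant(key, zygosity)
                for key, zygosity in case.variants
                if labels.get(key) in ("pathogenic", "presumed_pathogenic")
            ]
            diagnoses.append(classify_family(case.case_id, supporting))
        return results, summarize(results), diagnoses


def _data_path(name: str):
    return resources.files("col4dx.data").joinpath(name)


def _read_tsv_rows(text: str, origin: str) -> list[dict]:
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    rows = []
    for lineno, row in enumerate(reader, start=2):
        row["_line"] = lineno
        row["_origin"] = origin
        rows.append(row)
    return rows


def _fixture_row(row: Mapping, with_carriers: bool) -> FixtureRow:
    maf_text = (row.get("maf") or "").strip()
    cases_field = "carriers" if with_carriers else "cases"
    cases = tuple(c for c in (row.get(cases_field) or "").split(";") if c)
    return FixtureRow(
        gene=row["gene"].strip(),
        cdna=row["cdna"].strip(),
        protein=(row.get("protein") or "").strip(),
        consequence_label=(row.get("consequence_label") or "").strip(),
        secondary_splice=(row.get("secondary_splice") or "0").strip() == "1",
        maf=float(maf_text) if maf_text else None,
        published_status=PublishedStatus((row.get("published_status") or "none").strip()),
        source=(row.get("source") or "").strip(),
        cases=cases,
        note=(row.get("note") or "").strip(),
    )


def load_fixture_bundle() -> FixtureBundle:
    """Load the packaged reference tables (21 polymorphisms, 17 mutations, 17 cases)."""
    poly = tuple(
        _fixture_row(r, with_carriers=True)
        for r in _read_tsv_rows(_data_path("polymorphisms.tsv").read_text(), "polymorphisms.tsv")
    )
    mut = tuple(
        _fixture_row(r, with_carriers=False)
        for r in _read_tsv_rows(_data_path("mutations.tsv").read_text(), "mutations.tsv")
    )
    cases = []
    for r in _read_tsv_rows(_data_path("cases.tsv").read_text(), "cases.tsv"):
        keys = [k for k in r["variants"].split(";") if k]
        zygs = [Zygosity(z) for z in r["zygosities"].split(";") if z]
        if len(zygs) != len(keys):
            raise TableError(f"cases.tsv line {r['_line']}: zygosity count mismatch")
        cases.append(CaseFixture(r["case_id"], r["kind"], tuple(zip(keys, zygs))))
    bundle = FixtureBundle(poly, mut, tuple(cases))
    mutation_keys = {m.key for m in bundle.mutations}
    for case in bundle.cases:
        for key, _ in case.variants:
            if key not in mutation_keys:
                raise TableError(f"case {case.case_id}: variant {key} missing from mutation table")
    return bundle


# ---------------------------------------------------------------------------
# user tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantTable:
    """Parsed user variant input: variants plus optional genotype calls."""

    records: tuple[VariantRecord, ...]
    genotypes: tuple[GenotypeCall, ...] = ()


def _build_record(gene_name: str, cdna: str, protein: str, cfg: PipelineConfig) -> VariantRecord:
    gene = get_gene(gene_name)
    parsed = parse_cdna(cdna, gene)
    protein_change = parse_protein(protein) if protein else None
    consequence = classify_consequence(parsed, protein_change, cfg.transcripts[gene.name])
    collagenous = bool(
        protein_change and is_collagenous_glycine_substitution(protein_change, cfg.domains, gene)
    )
    return VariantRecord(
        variant_key(gene, cdna), gene, consequence, protein_change, parsed, collagenous
    )


def read_variant_table(path: Path | str, config: Optional[PipelineConfig] = None) -> VariantTable:
    """Read a TSV with columns gene, cdna[, protein]; one variant per row."""
    cfg = config or default_config()
    path = Path(path)
    records = []
    for row in _read_tsv_rows(path.read_text(), path.name):
        if not (row.get("gene") and row.get("cdna")):
            raise TableError(f"{path.name} line {row['_line']}: gene and cdna columns required")
        try:
            records.append(_build_record(row["gene"], row["cdna"], row.get("protein") or "", cfg))
        except (ValueError, UnknownGeneError) as exc:
            raise TableError(f"{path.name} line {row['_line']}: {exc}") from exc
    return VariantTable(tuple(records))


def read_annotation_table(path: Path | str) -> dict[str, AnnotationRecord]:
    """Mutation-database TSV: variant_key, published_status, source, maf[, in_controls]."""
    path = Path(path)
    out = {}
    for row in _read_tsv_rows(path.read_text(), path.name):
        try:
            maf_text = (row.get("maf") or "").strip()
            out[row["variant_key"]] = AnnotationRecord(
                row["variant_key"],
                PublishedStatus((row.get("published_status") or "none").strip()),
                (row.get("source") or "").strip(),
                in_controls=(row.get("in_controls") or "0").strip() in ("1", "true", "True"),
                population_maf=float(maf_text) if maf_text else None,
                note=(row.get("note") or "").strip(),
            )
        except (KeyError, ValueError) as exc:
            raise TableError(f"{path.name} line {row['_line']}: {exc}") from exc
    return out


def read_control_table(path: Path | str) -> dict[str, tuple[int, int]]:
    """Control-cohort TSV: variant_key, allele_count, allele_number (e.g. 132)."""
    path = Path(path)
    out = {}
    for row in _read_tsv_rows(path.read_text(), path.name):
        try:
            out[row["variant_key"]] = (int(row["allele_count"]), int(row["allele_number"]))
        except (KeyError, ValueError) as exc:
            raise TableError(f"{path.name} line {row['_line']}: {exc}") from exc
    return out


def merge_control_evidence(
    annotations: Mapping[str, AnnotationRecord], controls: Mapping[str, tuple[int, int]]
) -> dict[str, AnnotationRecord]:
    """Overlay control-cohort presence/MAF onto annotation records."""
    merged = dict(annotations)
    for key, (count, number) in controls.items():
        base = merged.get(key, AnnotationRecord(key))
        maf = count / number if number else None
        merged[key] = AnnotationRecord(
            key, base.published_status, base.source, in_controls=count > 0,
            population_maf=base.population_maf if base.population_maf is not None else maf,
            note=base.note,
        )
    return merged


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE}
_PED_AFF = {"0": Affection.UNKNOWN, "1": Affection.UNAFFECTED, "2": Affection.AFFECTED}


def read_ped(path: Path | str) -> dict[str, Pedigree]:
    """Read 6-column pre-MAKEPED PED (family, id, father, mother, sex, phenotype)."""
    path = Path(path)
    pedigrees: dict[str, Pedigree] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise TableError(f"{path.name} line {lineno}: expected 6 columns, got {len(fields)}")
        fam, iid, father, mother, sex, pheno = fields[:6]
        if sex not in _PED_SEX:
            raise TableError(f"{path.name} line {lineno}: unknown sex code {sex!r}")
        if pheno not in _PED_AFF:
            raise TableError(f"{path.name} line {lineno}: unknown phenotype code {pheno!r}")
        ped = pedigrees.setdefault(fam, Pedigree(fam))
        ped.add(
            Individual(
                iid,
                _PED_SEX[sex],
                _PED_AFF[pheno],
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
            )
        )
    return pedigrees


def write_ped(pedigrees: Iterable[Pedigree], path: Path | str) -> None:
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2"}
    aff_code = {Affection.UNKNOWN: "0", Affection.UNAFFECTED: "1", Affection.AFFECTED: "2"}
    lines = []
    for ped in pedigrees:
        for m in ped:
            lines.append(
                "\t".join(
                    [
                        ped.family_id,
                        m.id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        sex_code[m.sex],
                        aff_code[m.affection],
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF (GENE/CDNA INFO dialect)
# ---------------------------------------------------------------------------

def write_vcf(
    variants: Sequence[VariantRecord],
    genotypes: Sequence[GenotypeCall],
    sexes: Mapping[str, Sex],
    path: Path | str,
) -> None:
    """Emit a minimal VCFv4.2 with GENE/CDNA INFO and GT calls.

    CHROM is the gene symbol and POS the cDNA coding position (synthetic
    coordinates — the CDNA INFO field is authoritative).  Male COL4A5
    calls are written haploid.
    """
    samples = sorted({g.individual_id for g in genotypes})
    by_sample = {(g.individual_id, g.variant_key): g.allele_count for g in genotypes}
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="COL4A gene symbol">',
        '##INFO=<ID=CDNA,Number=1,Type=String,Description="HGVS cDNA description">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for gene_name in ("COL4A3", "COL4A4", "COL4A5"):
        lines.append(f"##contig=<ID={gene_name}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for record in sorted(variants, key=lambda r: (r.gene.name, r.parsed.position)):
        parsed = record.parsed
        cdna = record.variant_key.partition(":")[2]
        ref = parsed.ref_base or "N"
        alt = parsed.alt_base or "<DEL>"
        info = f"GENE={record.gene.name};CDNA={cdna}"
        haploid = record.gene.is_x_linked
        gts = []
        for sample in samples:
            count = by_sample.get((sample, record.variant_key), 0)
            if haploid and sexes[sample] is Sex.MALE:
                gts.append(str(min(count, 1)))
            elif count == 0:
                gts.append("0/0")
            elif count == 1:
                gts.append("0/1")
            else:
                gts.append("1/1")
        lines.append(
            "\t".join(
                [record.gene.name, str(parsed.position), ".", ref, alt, ".", ".", info, "GT"]
                + gts
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: Path | str, config: Optional[PipelineConfig] = None) -> VariantTable:
    """Read the GENE/CDNA VCF dialect back into variants and allele counts."""
    cfg = config or default_config()
    records: list[VariantRecord] = []
    genotypes: list[GenotypeCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            info = rec.info
            if "GENE" not in info or "CDNA" not in info:
                raise TableError(f"{Path(path).name}: record at {rec.chrom}:{rec.pos} lacks GENE/CDNA INFO")
            record = _build_record(info["GENE"], info["CDNA"], "", cfg)
            records.append(record)
            for sample_name, sample in rec.samples.items():
                alleles = sample.get("GT")
                if alleles is None:
                    continue
                count = sum(1 for a in alleles if a not in (None, 0))
                genotypes.append(GenotypeCall(sample_name, record.variant_key, count))
    return VariantTable(tuple(records), tuple(genotypes))


# ---------------------------------------------------------------------------
# BED / depth
# ---------------------------------------------------------------------------

def read_bed(path: Path | str):
    """Read a 0-based half-open BED target file into a TargetRegionSet."""
    from col4dx.qc import TargetRegionSet

    path = Path(path)
    regions = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise TableError(f"{path.name} line {lineno}: expected >= 3 BED columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
        if end <= start:
            raise TableError(f"{path.name} line {lineno}: empty interval")
        regions.append((name, end - start))
    return TargetRegionSet(tuple(regions))


def read_depth_track(path: Path | str, targets=None):
    """Read per-base depth: 3-column TSV (region, offset, depth) or 4-column bedgraph."""
    from col4dx.qc import DepthTrack

    path = Path(path)
    depths: list[int] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 3:
            depths.append(int(fields[2]))
        elif len(fields) >= 4:  # bedgraph: expand constant-depth interval
            start, end, depth = int(fields[1]), int(fields[2]), int(float(fields[3]))
            depths.extend([depth] * (end - start))
        else:
            raise TableError(f"{path.name} line {lineno}: expected 3 or 4 columns")
    return DepthTrack(np.asarray(depths, dtype=np.int64), targets)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(
    classifications: Sequence[ClassificationResult],
    diagnoses: Sequence[FamilyDiagnosis] = (),
    qc: Optional[Mapping] = None,
    path: Path | str = "report.json",
    format: str = "json",
) -> None:
    """Write a deterministic classification/diagnosis report (json or tsv)."""
    if format == "json":
        payload = {
            "variants": [c.to_dict() for c in classifications],
            "diagnoses": [d.to_dict() for d in diagnoses],
            "qc": dict(qc) if qc else None,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        lines = ["variant_key\tlabel\tflags\tcriteria"]
        for c in classifications:
            criteria = ";".join(
                f"{t.name}={'NA' if t.passed is None else int(t.passed)}" for t in c.criteria_trace
            )
            lines.append(f"{c.variant_key}\t{c.label.value}\t{','.join(c.flags)}\t{criteria}")
        if diagnoses:
            lines.append("")
            lines.append("case_id\tmode\tsupporting_variants\twarnings")
            for d in diagnoses:
                lines.append(
                    f"{d.family_id}\t{d.mode.value}\t{';'.join(d.supporting_variants)}\t"
                    f"{' | '.join(d.warnings)}"
                )
        Path(path).write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: Path | str) -> tuple[list[ClassificationResult], list[FamilyDiagnosis], Optional[dict]]:
    payload = json.loads(Path(path).read_text())
    return (
        [ClassificationResult.from_dict(v) for v in payload["variants"]],
        [FamilyDiagnosis.from_dict(d) for d in payload.get("diagnoses", [])],
        payload.get("qc"),
    )
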