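"""Packaged configuration: transcript boundaries, domain map, thresholds.

All thresholds named anywhere in the pipeline live here and can be
overridden from a YAML file with the same key structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import yaml

from col4dx.core import TranscriptModel, get_gene
from col4dx.hgvs import CollagenousDomainMap

__all__ = [
    "PathogenicityConfig",
    "PhenotypeThresholds",
    "QcThresholds",
    "PipelineConfig",
    "load_transcripts",
    "load_domain_map",
    "default_config",
    "load_config",
]


@dataclass(frozen=True)
class PathogenicityConfig:
    """Thresholds and switches for the four-criterion rule engine."""

    common_maf_threshold: float = 0.01
    # strict: an unaffected carrier of an autosomal variant falsifies
    # segregation; the tolerant flag permits unaffected (e.g. elderly
    # pre-onset) carriers and is off by default.
    penetrance_tolerant: bool = False
    # require at least one affected carrier for a segregation test to pass
    require_affected_carrier: bool = True


@dataclass(frozen=True)
class PhenotypeThresholds:
    """Cutoffs mapping functional-trimer fraction to a phenotype class."""

    normal_min: float = 0.75
    severe_max: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 <= self.severe_max <= self.normal_min <= 1.0):
            raise ValueError("phenotype thresholds must satisfy 0 <= severe_max <= normal_min <= 1")


@dataclass(frozen=True)
class QcThresholds:
    """Coverage QC rules: strict (>) comparisons by default."""

    min_mean_depth: float = 25.0
    min_fraction_at: Mapping[int, float] = field(
        default_factory=lambda: {100: 0.90, 50: 0.95}
    )
    strict: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    pathogenicity: PathogenicityConfig = field(default_factory=PathogenicityConfig)
    phenotype: PhenotypeThresholds = field(default_factory=PhenotypeThresholds)
    qc: QcThresholds = field(default_factory=QcThresholds)
    transcripts: Mapping[str, TranscriptModel] = field(default_factory=dict)
    domains: Optional[CollagenousDomainMap] = None


def _data_text(name: str) -> str:
    return resources.files("col4dx.data").joinpath(name).read_text()


def _build_transcripts(spec: Mapping) -> dict[str, TranscriptModel]:
    models = {}
    for gene_name, entry in spec.items():
        gene = get_gene(gene_name)
        models[gene.name] = TranscriptModel.from_exon_ends(
            gene, entry["exon_ends"], entry["cds_length"]
        )
    return models


def _build_domains(spec: Mapping) -> CollagenousDomainMap:
    intervals = {
        gene_name: tuple(tuple(iv) for iv in ivs) for gene_name, ivs in spec["intervals"].items()
    }
    return CollagenousDomainMap(intervals, approximate=bool(spec.get("approximate", True)))


def load_transcripts(path: Optional[Path] = None) -> dict[str, TranscriptModel]:
    """Partial coding-coordinate transcript models (packaged default or user YAML)."""
    text = Path(path).read_text() if path else _data_text("transcripts.yaml")
    return _build_transcripts(yaml.safe_load(text)["transcripts"])


def load_domain_map(path: Optional[Path] = None) -> CollagenousDomainMap:
    text = Path(path).read_text() if path else _data_text("transcripts.yaml")
    return _build_domains(yaml.safe_load(text)["collagenous_domains"])


def default_config() -> PipelineConfig:
    return PipelineConfig(transcripts=load_transcripts(), domains=load_domain_map())


def load_config(path: Optional[Path] = None) -> PipelineConfig:
    """Default config, optionally overlaid with a user YAML file.

    Recognized keys: ``pathogenicity``, ``phenotype``, ``qc`` (flat
    key/value blocks mirroring the dataclass fields), ``transcripts``
    and ``collagenous_domains`` (same shape as the packaged file).
    """
    base = default_config()
    if path is None:
        return base
    overlay = yaml.safe_load(Path(path).read_text()) or {}
    pathog = PathogenicityConfig(**overlay.get("pathogenicity", {})) if "pathogenicity" in overlay else base.pathogenicity
    phen = PhenotypeThresholds(**overlay.get("phenotype", {})) if "phenotype" in overlay else base.phenotype
    qc = base.qc
    if "qc" in overlay:
        block = dict(overlay["qc"])
        if "min_fraction_at" in block:
            block["min_fraction_at"] = {int(k): float(v) for k, v in block["min_fraction_at"].items()}
        qc = QcThresholds(**block)
    transcripts = (
        _build_transcripts(overlay["transcripts"]) if "transcripts" in overlay else base.transcripts
    )
    domains = (
        _build_domains(overlay["collagenous_domains"])
        if "collagenous_domains" in overlay
        else base.domains
    )
    return PipelineConfig(pathog, phen, qc, transcripts, domains)
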