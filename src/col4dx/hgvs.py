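"""HGVS cDNA/protein parsing and molecular consequence assignment.

Supports the variant grammar this pipeline needs: single-nucleotide
substitutions (``c.1871G>A``, ``c.765+2T>C``, ``c.547-9A>C``) and
deletions with optional intronic span ends (``c.1320_1369+2del``).
Consequence calling places each variant into exactly one category using
the transcript exon structure, with a secondary splice flag for
missense changes on exon-terminal bases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from col4dx.core import (
    Consequence,
    ConsequenceCategory,
    EditType,
    Gene,
    ParsedCdnaVariant,
    ProteinChange,
    TranscriptModel,
    get_gene,
)

__all__ = [
    "HgvsParseError",
    "UnsupportedSpanError",
    "parse_cdna",
    "render_cdna",
    "parse_protein",
    "render_protein",
    "deletion_length",
    "classify_consequence",
    "CollagenousDomainMap",
    "is_collagenous_glycine_substitution",
    "protein_codon_window",
    "AMINO_ACIDS_3",
]


class HgvsParseError(ValueError):
    """Malformed HGVS string; the message names the offending token."""


class UnsupportedSpanError(ValueError):
    """Deletion span implies skipping a complete intron; length undefined here."""


AMINO_ACIDS_3 = frozenset(
    {
        "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
        "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    }
)

_POS = r"(\d+)([+-]\d+)?"
_SUB_RE = re.compile(rf"^c\.{_POS}([ACGT])>([ACGT])$")
_DEL_RE = re.compile(rf"^c\.{_POS}(?:_{_POS})?del$")


def parse_cdna(hgvs_string: str, gene: Gene | str) -> ParsedCdnaVariant:
    """Parse a cDNA HGVS description into its structured form.

    Raises :class:`HgvsParseError` for malformed input, naming the
    offending token (missing ``c.`` prefix, bad base, inverted span...).
    """
    g = gene if isinstance(gene, Gene) else get_gene(gene)
    s = "".join(hgvs_string.split())
    if not s.startswith("c."):
        raise HgvsParseError(f"cDNA description must start with 'c.': {hgvs_string!r}")

    m = _SUB_RE.match(s)
    if m:
        pos, off, ref, alt = m.groups()
        return ParsedCdnaVariant(
            gene=g,
            position=int(pos),
            intron_offset=int(off) if off else 0,
            edit_type=EditType.SUBSTITUTION,
            ref_base=ref,
            alt_base=alt,
        )

    m = _DEL_RE.match(s)
    if m:
        pos, off, end_pos, end_off = m.groups()
        start = (int(pos), int(off) if off else 0)
        if end_pos is None:
            end = start
        else:
            end = (int(end_pos), int(end_off) if end_off else 0)
        if end < start:
            raise HgvsParseError(
                f"inverted deletion span {s!r}: end {end_pos} precedes start {pos}"
            )
        return ParsedCdnaVariant(
            gene=g,
            position=start[0],
            intron_offset=start[1],
            edit_type=EditType.DELETION,
            span_end_position=end[0],
            span_end_offset=end[1],
        )

    raise HgvsParseError(f"unsupported or malformed cDNA description: {hgvs_string!r}")


def _render_pos(position: int, offset: int) -> str:
    if offset == 0:
        return str(position)
    return f"{position}{offset:+d}"


def render_cdna(variant: ParsedCdnaVariant) -> str:
    """Inverse of :func:`parse_cdna` (round-trips every supported variant)."""
    start = _render_pos(variant.position, variant.intron_offset)
    if variant.edit_type is EditType.SUBSTITUTION:
        return f"c.{start}{variant.ref_base}>{variant.alt_base}"
    end = _render_pos(variant.span_end_position, variant.span_end_offset)
    if (variant.span_end_position, variant.span_end_offset) == (variant.position, variant.intron_offset):
        return f"c.{start}del"
    return f"c.{start}_{end}del"


_PROT_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


def parse_protein(p_string: str) -> ProteinChange:
    s = "".join(p_string.split())
    if not s.startswith("p."):
        raise HgvsParseError(f"protein description must start with 'p.': {p_string!r}")
    m = _PROT_RE.match(s)
    if not m:
        raise HgvsParseError(f"unsupported or malformed protein description: {p_string!r}")
    ref_aa, pos, alt_aa = m.groups()
    for aa in (ref_aa, alt_aa):
        if aa not in AMINO_ACIDS_3:
            raise HgvsParseError(f"unknown amino acid code {aa!r} in {p_string!r}")
    return ProteinChange(ref_aa, int(pos), alt_aa)


def render_protein(change: ProteinChange) -> str:
    return str(change)


def deletion_length(parsed: ParsedCdnaVariant) -> int:
    """Number of deleted bases for a deletion span.

    length = (end_position - start_position + 1) + end_offset - start_offset.
    Valid only when the span does not skip over a complete intron, i.e.
    both ends relate to the same exon and/or its immediately flanking
    intronic bases; otherwise :class:`UnsupportedSpanError` is raised.
    """
    if parsed.edit_type is not EditType.DELETION:
        raise ValueError("deletion_length requires a deletion variant")
    ps, os_ = parsed.position, parsed.intron_offset
    pe, oe = parsed.span_end_position, parsed.span_end_offset
    if pe > ps and (os_ > 0 or oe < 0):
        raise UnsupportedSpanError(
            f"span {render_cdna(parsed)} crosses a complete intron; length is transcript-dependent"
        )
    return (pe - ps + 1) + oe - os_


@dataclass(frozen=True)
class CollagenousDomainMap:
    """Per-gene protein-coordinate intervals covering Gly-X-Y collagenous domains.

    Intervals are 1-based inclusive, sorted and non-overlapping.  The
    packaged default is a single triple-helical interval per gene — an
    approximation flagged as such in output (exact Gly-X-Y sub-interval
    boundaries are not modelled).
    """

    intervals: Mapping[str, tuple[tuple[int, int], ...]]
    approximate: bool = True

    def __post_init__(self) -> None:
        for gene_name, ivs in self.intervals.items():
            get_gene(gene_name)
            prev_end = 0
            for start, end in ivs:
                if start <= prev_end or end < start:
                    raise ValueError(f"bad collagenous interval [{start}, {end}] for {gene_name}")
                prev_end = end

    def contains(self, gene: Gene | str, protein_position: int) -> bool:
        g = gene if isinstance(gene, Gene) else get_gene(gene)
        for start, end in self.intervals.get(g.name, ()):
            if start <= protein_position <= end:
                return True
        return False


def is_collagenous_glycine_substitution(
    change: ProteinChange, domains: CollagenousDomainMap, gene: Gene | str
) -> bool:
    """True iff a glycine inside a collagenous Gly-X-Y domain is substituted.

    Such substitutions disrupt the obligatory Gly of the triple-helix
    repeat and are canonically pathogenic in Col4A chains.
    """
    return change.ref_aa == "Gly" and change.is_missense and domains.contains(gene, change.position)


def protein_codon_window(change: ProteinChange) -> tuple[int, int]:
    """Coding-position window [3p-2, 3p] of the codon for residue p."""
    return (3 * change.position - 2, 3 * change.position)


# splice geometry defaults: canonical +/-1..2, intronic splice region 3..8,
# exonic splice region = terminal 3 bases of an exon
CANONICAL_OFFSET_MAX = 2
INTRONIC_REGION_OFFSET_MAX = 8
EXONIC_REGION_WINDOW = 3


def classify_consequence(
    parsed: ParsedCdnaVariant,
    protein_change: Optional[ProteinChange],
    transcript: TranscriptModel,
) -> Consequence:
    """Assign the molecular consequence category for one variant.

    Ordered rules: deletions touching splice bases; canonical donor
    (+1/+2) / acceptor (-1/-2); intronic splice region (|offset| 3-8);
    deeper intronic; exon-terminal changes without an amino-acid change;
    missense; synonymous.  Missense changes on exon-terminal bases keep
    a secondary splice flag.
    """
    if parsed.edit_type is EditType.DELETION:
        touches_splice = parsed.intron_offset < 0 or parsed.span_end_offset > 0
        if not touches_splice:
            transcript.exon_containing(parsed.position)
            touches_splice = transcript.near_exon_end(
                parsed.span_end_position, EXONIC_REGION_WINDOW
            ) or transcript.near_exon_start(parsed.position, EXONIC_REGION_WINDOW)
        if touches_splice:
            return Consequence(ConsequenceCategory.DELETION_WITH_SPLICE)
        raise ValueError(
            f"deletion {render_cdna(parsed)} does not touch splice bases; "
            "purely interior exonic deletions are outside the supported consequence vocabulary"
        )

    offset = parsed.intron_offset
    if offset != 0:
        magnitude = abs(offset)
        if magnitude <= CANONICAL_OFFSET_MAX:
            category = (
                ConsequenceCategory.SPLICE_DONOR if offset > 0 else ConsequenceCategory.SPLICE_ACCEPTOR
            )
            return Consequence(category)
        if magnitude <= INTRONIC_REGION_OFFSET_MAX:
            return Consequence(ConsequenceCategory.SPLICE_REGION_INTRONIC)
        return Consequence(ConsequenceCategory.INTRONIC)

    # exonic substitution: transcript must cover the position
    transcript.exon_containing(parsed.position)
    near_boundary = transcript.near_exon_end(
        parsed.position, EXONIC_REGION_WINDOW
    ) or transcript.near_exon_start(parsed.position, EXONIC_REGION_WINDOW)

    if protein_change is None or not protein_change.is_missense:
        if near_boundary:
            return Consequence(ConsequenceCategory.SPLICE_REGION_EXONIC)
        return Consequence(ConsequenceCategory.SYNONYMOUS)
    return Consequence(ConsequenceCategory.MISSENSE, secondary_splice=near_boundary)
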