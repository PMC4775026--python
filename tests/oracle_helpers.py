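"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results by enumeration rather than calling
into the package logic they check.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence


def deletion_length_by_enumeration(
    start_pos: int, start_off: int, end_pos: int, end_off: int
) -> int:
    """Count written bases one by one over a span that skips no intron.

    Anchored to one exon and its flanks, the written coordinates map to
    consecutive integers position+offset; the oracle walks them.
    """
    first = start_pos + start_off
    last = end_pos + end_off
    count = 0
    cursor = first
    while cursor <= last:
        count += 1
        cursor += 1
    return count


def segregation_oracle(
    members: Sequence[tuple[str, str, int]],
    x_linked: bool,
    penetrance_tolerant: bool = False,
    require_affected_carrier: bool = True,
) -> bool:
    """Rule-table re-implementation of the exclusive-segregation test.

    ``members`` holds (sex, affection, allele_count) triples with sex in
    {"male", "female"} and affection in {"affected", "unaffected",
    "unknown"}.  Written as an explicit per-case table, independent of
    the package implementation.
    """
    any_affected_carrier = False
    for sex, affection, count in members:
        if affection == "unknown":
            continue
        carrier = count > 0
        if affection == "affected" and carrier:
            any_affected_carrier = True
        if x_linked:
            if sex == "male" and affection == "affected" and not carrier:
                return False
            if sex == "male" and affection == "unaffected" and carrier:
                return False
            if sex == "female" and affection == "affected" and not carrier:
                return False
            # unaffected female carriers tolerated
        else:
            if affection == "unaffected" and carrier and not penetrance_tolerant:
                return False
            # affected non-carriers tolerated (compound-het families)
    if require_affected_carrier and not any_affected_carrier:
        return False
    return True


def enumerate_member_states(n: int, x_linked: bool, sexes: Sequence[str]):
    """All (affection, allele_count) assignments for n members of given sexes."""
    per_member = []
    for sex in sexes:
        max_alleles = 1 if (x_linked and sex == "male") else 2
        states = [
            (affection, count)
            for affection in ("affected", "unaffected", "unknown")
            for count in range(max_alleles + 1)
        ]
        per_member.append(states)
    return itertools.product(*per_member)


def hardy_weinberg_expected(n_individuals: int, allele_freq: float):
    """Expected diploid genotype counts (0, 1, 2 mutant alleles) under HWE."""
    p = allele_freq
    q = 1.0 - p
    return (n_individuals * q * q, n_individuals * 2 * p * q, n_individuals * p * p)
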