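"""Locate the bZIP basic/hinge/zipper region and set up its numbering.

A bZIP basic region carries an invariant N-x7-R/K motif; nine residues
after the basic Arg/Lys the leucine zipper begins.  Family convention
numbers the anchor Asn -18, the basic Arg/Lys -10, and the first zipper
Leu +1; there is no position 0.  The zipper runs from +1 to the residue
before the first alpha-helix breaker (default proline), or to the end
of the sequence.

Anchor scanning is tolerant of the family's characterized substitutions
(Lys at -18, Ile at -10) via the rule table's substitute sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .binding_groups import RuleTable
from .sequence_io import ProteinRecord

#: span of the basic+hinge region in residues (-18..-1)
BASIC_HINGE_LEN = 18
#: offset from the anchor Asn (-18) to the basic residue (-10)
ASN_TO_BASIC = 8
#: offset from the anchor Asn (-18) to the first zipper residue (+1)
ASN_TO_ZIPPER = 18

AnchorTriple = tuple[int, int, int]


@dataclass(frozen=True)
class BzipDomain:
    """An anchored bZIP domain with the signed position numbering.

    ``asn_index``/``basic_residue_index``/``first_leu_index`` are 0-based
    sequence indices of the residues at positions -18, -10 and +1.
    ``zipper_end_index`` is the last residue included in the zipper.
    """

    protein_id: str
    asn_index: int
    basic_residue_index: int
    first_leu_index: int
    zipper_end_index: int

    def __post_init__(self) -> None:
        if self.basic_residue_index - self.asn_index != ASN_TO_BASIC:
            raise ValueError("basic residue must sit 8 residues after the anchor Asn")
        if self.first_leu_index - self.basic_residue_index != 10:
            raise ValueError("zipper must start 10 residues after the basic residue")
        if self.zipper_end_index < self.first_leu_index:
            raise ValueError("zipper end precedes zipper start")

    @property
    def zipper_length(self) -> int:
        return self.zipper_end_index - self.first_leu_index + 1

    def position_of(self, index: int) -> int:
        """Signed domain position of a sequence index (no position 0)."""
        if self.asn_index <= index < self.first_leu_index:
            return index - self.first_leu_index  # -18..-1
        if self.first_leu_index <= index <= self.zipper_end_index:
            return index - self.first_leu_index + 1  # +1..
        raise ValueError(f"index {index} outside the numbered domain span")

    def index_of(self, position: int) -> int:
        """Sequence index of a signed domain position."""
        if position == 0:
            raise ValueError("position 0 does not exist in the numbering")
        if position < 0:
            index = self.first_leu_index + position
            if index < self.asn_index:
                raise ValueError(f"position {position} precedes the domain")
        else:
            index = self.first_leu_index + position - 1
            if index > self.zipper_end_index:
                raise ValueError(f"position {position} beyond the zipper end")
        return index

    @property
    def numbering(self) -> dict[int, int]:
        """Mapping sequence index -> signed position over the covered span."""
        return {
            i: self.position_of(i)
            for i in range(self.asn_index, self.zipper_end_index + 1)
        }


def scan_basic_anchor(
    protein: ProteinRecord, rules: RuleTable
) -> list[AnchorTriple]:
    """Find all N-x7-R/K-x9-L style anchor candidates, left to right.

    Allowed letters at each anchor slot come from the rule table:
    -18 is {N} plus ``neg18_substitutes``, -10 is {R,K} plus
    ``neg10_substitutes``, and the zipper start must be in
    ``initiators`` (default {L}).
    """
    seq = protein.sequence
    neg18 = frozenset("N") | rules.class_("neg18_substitutes")
    neg10 = frozenset("RK") | rules.class_("neg10_substitutes")
    initiators = rules.class_("initiators")
    candidates: list[AnchorTriple] = []
    for i in range(len(seq) - ASN_TO_ZIPPER):
        if (
            seq[i] in neg18
            and seq[i + ASN_TO_BASIC] in neg10
            and seq[i + ASN_TO_ZIPPER] in initiators
        ):
            candidates.append((i, i + ASN_TO_BASIC, i + ASN_TO_ZIPPER))
    return candidates


def build_domain(
    protein: ProteinRecord,
    candidate: AnchorTriple,
    breakers: Iterable[str] = frozenset("P"),
) -> BzipDomain:
    """Extend an anchor candidate into a full domain.

    The zipper runs from the initiator (+1) up to, but not including,
    the first breaker residue at or after +1; with no breaker downstream
    it extends to the sequence end.
    """
    asn_index, basic_index, first_leu = candidate
    seq = protein.sequence
    if not (0 <= asn_index and first_leu < len(seq)):
        raise ValueError(f"candidate indices {candidate} out of range")
    breakers = frozenset(breakers)
    zipper_end = len(seq) - 1
    for j in range(first_leu, len(seq)):
        if seq[j] in breakers:
            zipper_end = j - 1
            break
    return BzipDomain(
        protein_id=protein.id,
        asn_index=asn_index,
        basic_residue_index=basic_index,
        first_leu_index=first_leu,
        zipper_end_index=zipper_end,
    )


def select_domain(candidates: list[BzipDomain]) -> Optional[BzipDomain]:
    """Pick the domain with the longest zipper; ties go to the leftmost anchor.

    Returns ``None`` (a "no bZIP domain" result, not an error) for an
    empty candidate list.
    """
    if not candidates:
        return None
    return min(candidates, key=lambda d: (-d.zipper_length, d.asn_index))


def find_domain(
    protein: ProteinRecord,
    rules: RuleTable,
    breakers: Optional[Iterable[str]] = None,
) -> Optional[BzipDomain]:
    """Scan, build and select in one call (breakers default from the table)."""
    if breakers is None:
        breakers = rules.class_("breakers")
    built = [
        build_domain(protein, cand, breakers)
        for cand in scan_basic_anchor(protein, rules)
    ]
    return select_domain(built)
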