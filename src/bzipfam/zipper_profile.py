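"""Heptad register assignment and g<->e' electrostatic pair classes.

A coiled-coil leucine zipper repeats every seven residues with registers
a-g; the canonical zipper leucines occupy d.  With the default register
phase the first zipper residue (+1) is a d, so positions advance
d,e,f,g,a,b,c within each heptad and the g of heptad *n* sits five
residues before the e of heptad *n+1* — the classic inter-helical
g<->e' (i, i+5) electrostatic pair.

A g<->e' pair is *complete* when both residues are charged, *incomplete*
when exactly one is, and *uncharged* otherwise.  Complete pairs fall
into four classes: acidic repulsive (both acidic), basic repulsive
(both basic), +/- attractive (acidic g, basic e') and -/+ attractive
(basic g, acidic e').  Attractive first-heptad pairs favour
homodimerization; repulsive pairs favour heterodimer partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .domain_anchor import BzipDomain
from .sequence_io import ProteinRecord

#: register cycle starting at zipper position +1 under the default phase
REGISTER_CYCLE = "defgabc"

COMPLETENESS = ("complete", "incomplete", "uncharged")
PAIR_CLASSES = ("acidic_repulsive", "basic_repulsive", "attract_ge", "attract_eg")

DEFAULT_CLASSES: dict[str, frozenset[str]] = {
    "acidic": frozenset("DE"),
    "basic": frozenset("KR"),
}


@dataclass(frozen=True)
class Heptad:
    """One heptad of the zipper; a truncated final heptad has absent registers."""

    index: int
    registers: Mapping[str, str]

    def get(self, register: str) -> Optional[str]:
        return self.registers.get(register)


@dataclass(frozen=True)
class GePair:
    """The g residue of one heptad paired with the e of the next."""

    heptad_index: int
    g_residue: str
    e_residue: str
    completeness: str
    pair_class: Optional[str]


def register_for_position(position: int, register_offset: int = 0) -> str:
    """Register letter of a 1-based zipper position (+1, +2, ...).

    ``register_offset`` rotates the phase: with the default 0 the +1
    residue is a d; offset 1 makes it an e, and so on.
    """
    if position < 1:
        raise ValueError("zipper positions start at +1")
    return REGISTER_CYCLE[(position - 1 + register_offset) % 7]


def assign_registers(
    domain: BzipDomain,
    protein: ProteinRecord,
    register_offset: int = 0,
) -> list[Heptad]:
    """Assign a-g registers across the zipper.

    Heptad *n* covers zipper positions 7(n-1)+1 .. 7n; the final heptad
    may be partial and is retained with only the registers it contains.
    """
    seq = protein.sequence
    length = domain.zipper_length
    heptads: list[Heptad] = []
    for n in range(1, (length + 6) // 7 + 1):
        registers: dict[str, str] = {}
        for p in range(7 * (n - 1) + 1, min(7 * n, length) + 1):
            registers[register_for_position(p, register_offset)] = seq[
                domain.first_leu_index + p - 1
            ]
        heptads.append(Heptad(index=n, registers=registers))
    return heptads


def classify_ge_pair(
    g_residue: str,
    e_residue: str,
    classes: Mapping[str, frozenset[str]] = DEFAULT_CLASSES,
) -> tuple[str, Optional[str]]:
    """Classify one g/e' residue pair -> (completeness, pair class).

    ``classes`` supplies the acidic and basic sets; charged is their
    union.  Unknown residues (X) are never charged.
    """
    acidic = classes["acidic"]
    basic = classes["basic"]
    g_charged = g_residue in acidic or g_residue in basic
    e_charged = e_residue in acidic or e_residue in basic
    if g_charged and e_charged:
        if g_residue in acidic and e_residue in acidic:
            return "complete", "acidic_repulsive"
        if g_residue in basic and e_residue in basic:
            return "complete", "basic_repulsive"
        if g_residue in acidic:
            return "complete", "attract_ge"
        return "complete", "attract_eg"
    if g_charged or e_charged:
        return "incomplete", None
    return "uncharged", None


def extract_ge_pairs(
    heptads: list[Heptad],
    classes: Mapping[str, frozenset[str]] = DEFAULT_CLASSES,
) -> list[GePair]:
    """Pair each heptad's g with the following heptad's e residue.

    A heptad contributes a pair only when it has a g residue *and* its
    successor has an e residue (a trailing g with no following e is not
    counted in any category).
    """
    by_index = {h.index: h for h in heptads}
    pairs: list[GePair] = []
    for h in sorted(heptads, key=lambda h: h.index):
        nxt = by_index.get(h.index + 1)
        g = h.get("g")
        e = nxt.get("e") if nxt is not None else None
        if g is None or e is None:
            continue
        completeness, pair_class = classify_ge_pair(g, e, classes)
        pairs.append(
            GePair(
                heptad_index=h.index,
                g_residue=g,
                e_residue=e,
                completeness=completeness,
                pair_class=pair_class,
            )
        )
    return pairs
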