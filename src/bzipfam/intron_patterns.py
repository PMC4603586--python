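"""Intron patterns a-f within the basic/hinge window of the bZIP domain.

Intron positions and splicing phases inside the basic and hinge coding
region (-18..-1 in the domain numbering) are strongly conserved across
plant bZIP families and define six signature patterns:

* ``a`` — one P0 intron in the basic sub-window (default -18..-11);
* ``b`` — one P0 intron in the hinge sub-window (default -10..-1);
* ``c`` — two introns, both phase P0;
* ``d`` — one P2 intron interrupting a Gln codon;
* ``e`` — one P2 intron interrupting an Arg codon;
* ``f`` — no intron inside the window (the gene may be intronless, or
  carry introns only outside the basic/hinge region).

Anything else (e.g. a P1 intron in the window) is reported as
``unclassified`` with explicit reasons rather than forced into a
pattern.  The a/b positional split is configurable data: the exact
boundary is a documented default, not a family constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .domain_anchor import BzipDomain
from .sequence_io import GeneModel, IntronRecord

PATTERNS = ("a", "b", "c", "d", "e", "f")

#: default positional sub-windows for the single-P0 patterns, inclusive
DEFAULT_PATTERN_TABLE: dict[str, tuple[int, int]] = {
    "a": (-18, -11),  # basic sub-window
    "b": (-10, -1),   # hinge sub-window
}


@dataclass(frozen=True)
class IntronPatternCall:
    gene_id: str
    pattern: str  # a-f or "unclassified"
    window_introns: tuple[IntronRecord, ...]
    intronless_gene: bool
    reasons: tuple[str, ...] = ()


def window_position(domain: BzipDomain, intron: IntronRecord) -> Optional[int]:
    """Signed basic/hinge position of an intron, or None if outside -18..-1.

    An intron maps to the codon it interrupts (P1/P2) or the codon
    immediately following the splice (P0); it counts as inside the
    window when that codon's signed position lies in -18..-1.  The +1
    codon is excluded.
    """
    index = intron.protein_position - 1
    if domain.asn_index <= index < domain.first_leu_index:
        return domain.position_of(index)
    return None


def classify_intron_pattern(
    gene: GeneModel,
    domain: BzipDomain,
    introns: list[IntronRecord],
    pattern_table: Mapping[str, tuple[int, int]] = DEFAULT_PATTERN_TABLE,
) -> IntronPatternCall:
    """Classify a gene's basic/hinge-window introns into patterns a-f."""
    if gene.protein_id != domain.protein_id:
        raise ValueError(
            f"gene {gene.gene_id!r} references protein {gene.protein_id!r}, "
            f"domain belongs to {domain.protein_id!r}"
        )
    in_window = [
        (iv, pos)
        for iv in introns
        if (pos := window_position(domain, iv)) is not None
    ]
    window_introns = tuple(iv for iv, _ in in_window)
    intronless = len(introns) == 0

    def call(pattern: str, reasons: tuple[str, ...] = ()) -> IntronPatternCall:
        return IntronPatternCall(
            gene_id=gene.gene_id,
            pattern=pattern,
            window_introns=window_introns,
            intronless_gene=intronless,
            reasons=reasons,
        )

    if not in_window:
        return call("f")
    if len(in_window) == 2:
        if all(iv.phase == "P0" for iv, _ in in_window):
            return call("c")
        return call(
            "unclassified",
            ("two window introns with phases "
             + ",".join(iv.phase for iv, _ in in_window)
             + " (pattern c requires P0,P0)",),
        )
    if len(in_window) == 1:
        iv, pos = in_window[0]
        if iv.phase == "P2":
            if iv.interrupted_residue == "Q":
                return call("d")
            if iv.interrupted_residue == "R":
                return call("e")
            return call(
                "unclassified",
                (f"P2 intron interrupts {iv.interrupted_residue} "
                 "(patterns d/e require Gln/Arg)",),
            )
        if iv.phase == "P0":
            for pattern in ("a", "b"):
                lo, hi = pattern_table[pattern]
                if lo <= pos <= hi:
                    return call(pattern)
            return call(
                "unclassified",
                (f"P0 intron at position {pos} outside the a/b sub-windows",),
            )
        return call("unclassified", ("phase P1 not in pattern table",))
    return call(
        "unclassified",
        (f"{len(in_window)} window introns do not match any pattern",),
    )


def pattern_census(calls: list[IntronPatternCall]) -> pd.DataFrame:
    """Counts per pattern plus the intronless-gene count.

    The intronless count is reported separately from pattern f because
    f also contains genes whose introns all fall outside the window.
    """
    if not calls:
        raise ValueError("pattern census of an empty call list")
    counts = {p: 0 for p in PATTERNS}
    counts["unclassified"] = 0
    intronless = 0
    for c in calls:
        counts[c.pattern] += 1
        if c.intronless_gene:
            intronless += 1
    rows = [{"pattern": p, "n_genes": n} for p, n in counts.items()]
    rows.append({"pattern": "intronless", "n_genes": intronless})
    return pd.DataFrame(rows)
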