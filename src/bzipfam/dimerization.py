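"""Dimerization propensity calls and dimerization subfamilies.

The rules follow the standard coiled-coil electrostatics argument:

* **homodimer** — an attractive g<->e' pair in the first heptad and no
  repulsive pair anywhere (a stabilizing inter-helical salt bridge at
  the dimerization-initiating heptad, nothing destabilizing it);
* **heterodimer** — at least one complete pair and every complete pair
  repulsive (like charges disfavour self-pairing; complementation in a
  heterodimer can resolve them);
* **both** — everything else.

Incomplete pairs are neutral for the call: single-charged g<->e'
interactions contribute little to homodimer stability.

Proteins sharing an identical zipper signature — heptad count plus the
ordered per-heptad pair classes — form a dimerization subfamily,
labelled BZ1, BZ2, ... deterministically (signatures sorted
lexicographically).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

from .domain_anchor import BzipDomain
from .sequence_io import ProteinRecord
from .zipper_profile import (
    DEFAULT_CLASSES,
    GePair,
    Heptad,
    assign_registers,
    extract_ge_pairs,
)

ATTRACTIVE = frozenset({"attract_ge", "attract_eg"})
REPULSIVE = frozenset({"acidic_repulsive", "basic_repulsive"})

#: one-letter codes for pair classes used in subfamily signatures
_CLASS_CODE = {
    "attract_ge": "A",
    "attract_eg": "B",
    "acidic_repulsive": "R",
    "basic_repulsive": "S",
}


@dataclass
class DimerProfile:
    """Zipper-derived dimerization features for one protein."""

    protein_id: str
    zipper_heptads: int
    asn_at_a: frozenset[int]
    leu_at_d_fraction: float
    pairs: list[GePair]
    dimer_call: str
    signature: str
    heptads: list[Heptad] = field(default_factory=list, repr=False)
    subfamily: Optional[str] = None


def call_dimerization(pairs: list[GePair]) -> str:
    """homodimer / heterodimer / both from the g<->e' pair classes."""
    attractive_first = any(
        p.heptad_index == 1 and p.pair_class in ATTRACTIVE for p in pairs
    )
    any_repulsive = any(p.pair_class in REPULSIVE for p in pairs)
    complete = [p for p in pairs if p.completeness == "complete"]
    if attractive_first and not any_repulsive:
        return "homodimer"
    if complete and all(p.pair_class in REPULSIVE for p in complete):
        return "heterodimer"
    return "both"


def pair_signature(pairs: list[GePair], n_heptads: int) -> str:
    """Canonical signature: heptad count + ordered pair-class codes.

    Incomplete pairs code ``i``, uncharged ``u``; complete pairs use
    their class letter.  Deterministic given the pairs and heptad count.
    """
    codes = []
    for p in sorted(pairs, key=lambda p: p.heptad_index):
        if p.completeness == "complete":
            codes.append(f"{p.heptad_index}{_CLASS_CODE[p.pair_class]}")
        elif p.completeness == "incomplete":
            codes.append(f"{p.heptad_index}i")
        else:
            codes.append(f"{p.heptad_index}u")
    return f"H{n_heptads}|" + ".".join(codes)


def build_profile(
    domain: BzipDomain,
    protein: ProteinRecord,
    classes: Mapping[str, frozenset[str]] = DEFAULT_CLASSES,
    register_offset: int = 0,
) -> DimerProfile:
    """Compose register assignment, pair extraction and the dimer call."""
    heptads = assign_registers(domain, protein, register_offset)
    pairs = extract_ge_pairs(heptads, classes)
    asn_at_a = frozenset(h.index for h in heptads if h.get("a") == "N")
    d_residues = [h.get("d") for h in heptads if h.get("d") is not None]
    leu_frac = (
        sum(1 for r in d_residues if r == "L") / len(d_residues) if d_residues else 0.0
    )
    return DimerProfile(
        protein_id=protein.id,
        zipper_heptads=len(heptads),
        asn_at_a=asn_at_a,
        leu_at_d_fraction=leu_frac,
        pairs=pairs,
        dimer_call=call_dimerization(pairs),
        signature=pair_signature(pairs, len(heptads)),
        heptads=heptads,
    )


def assign_subfamilies(profiles: list[DimerProfile]) -> list[DimerProfile]:
    """Partition profiles into subfamilies by identical signature.

    Labels BZ1, BZ2, ... follow the lexicographic order of the distinct
    signatures, so the labelling is identical across runs for the same
    inputs.  Returns new profiles; the input list is not mutated.
    """
    if not profiles:
        return []
    signatures = sorted({p.signature for p in profiles})
    label_of = {sig: f"BZ{i}" for i, sig in enumerate(signatures, start=1)}
    return [replace(p, subfamily=label_of[p.signature]) for p in profiles]
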