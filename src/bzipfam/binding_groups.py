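"""DNA-binding specificity groups I-XI from basic/hinge residues.

The binding specificity of a bZIP factor is determined by the residues
of its basic and hinge regions (the signed positions -18..-1 in the family's
numbering, where the anchor Asn is -18, the invariant Arg/Lys is -10 and
the first zipper Leu is +1).  Groups are defined by a configurable rule
table: an ordered list of (position, allowed residue set) constraints
per group.  The first rule whose constraints are all satisfied wins, so
groups defined by characteristic deviations (e.g. Ile at -10, Lys at
-18) are listed before the generic Asn/Arg fallback.

The rule table is data, not code: the shipped default covers the two
deviations that are well characterized in tomato (group XI: hydrophobic
Ile at -10 instead of Arg/Lys; group IX: Lys substitution at -18) and
fills the remaining nine groups with documented stand-in rules keyed on
a hinge position.  Users studying other families load their own table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Optional

import yaml

from .sequence_io import CANONICAL_AA, ProteinRecord

if TYPE_CHECKING:
    from .domain_anchor import BzipDomain

GROUP_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI")

#: residue classes every rule table must name
REQUIRED_CLASSES = (
    "hydrophobic",
    "acidic",
    "basic",
    "breakers",
    "initiators",
    "neg18_substitutes",
    "neg10_substitutes",
)


@dataclass(frozen=True)
class GroupRule:
    label: str
    constraints: tuple[tuple[int, frozenset[str]], ...]


@dataclass
class RuleTable:
    """Ordered binding-group rules plus the named residue classes."""

    group_rules: list[GroupRule]
    residue_classes: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [r.label for r in self.group_rules]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate group labels: {dupes}")
        for rule in self.group_rules:
            for pos, allowed in rule.constraints:
                if not -18 <= pos <= -1:
                    raise ValueError(
                        f"group {rule.label}: rule position {pos} outside -18..-1"
                    )
                bad = sorted(set(allowed) - CANONICAL_AA)
                if bad:
                    raise ValueError(
                        f"group {rule.label}: unknown residue letters {bad}"
                    )
        for name in REQUIRED_CLASSES:
            if not self.residue_classes.get(name):
                raise ValueError(f"residue class {name!r} missing or empty")
            bad = sorted(set(self.residue_classes[name]) - CANONICAL_AA)
            if bad:
                raise ValueError(f"residue class {name!r}: unknown letters {bad}")

    @property
    def charged(self) -> frozenset[str]:
        return self.residue_classes["acidic"] | self.residue_classes["basic"]

    def class_(self, name: str) -> frozenset[str]:
        return self.residue_classes[name]


@dataclass(frozen=True)
class BindingCall:
    """Group assignment for one protein, with anchor anomalies.

    ``anomalies`` lists (position, expected set, observed residue) for
    the -18 and -10 anchor positions whenever they deviate from the
    canonical Asn and Arg/Lys.
    """

    protein_id: str
    group: str
    matched_rule: Optional[str]
    anomalies: tuple[tuple[int, frozenset[str], str], ...] = ()


def _table_from_dict(data: dict) -> RuleTable:
    rules = []
    for entry in data["groups"]:
        constraints = tuple(
            (int(pos), frozenset(str(res).upper()))
            for pos, res in entry["rules"].items()
        )
        rules.append(GroupRule(label=str(entry["label"]), constraints=constraints))
    classes = {
        name: frozenset(str(letters).upper())
        for name, letters in data["residue_classes"].items()
    }
    return RuleTable(group_rules=rules, residue_classes=classes)


def load_rule_table(path: str | Path) -> RuleTable:
    """Load and validate a rule table from a YAML file."""
    with open(path) as handle:
        data = yaml.safe_load(handle)
    return _table_from_dict(data)


def save_rule_table(table: RuleTable, path: str | Path) -> None:
    data = {
        "groups": [
            {"label": r.label, "rules": {pos: "".join(sorted(allowed))
                                         for pos, allowed in r.constraints}}
            for r in table.group_rules
        ],
        "residue_classes": {
            name: "".join(sorted(letters))
            for name, letters in table.residue_classes.items()
        },
    }
    with open(path, "wt") as handle:
        yaml.safe_dump(data, handle, sort_keys=False)


def default_rule_table() -> RuleTable:
    """The rule table shipped with the package."""
    ref = resources.files("bzipfam.data").joinpath("binding_rules.yaml")
    with ref.open() as handle:
        return _table_from_dict(yaml.safe_load(handle))


def classify_binding_group(
    domain: "BzipDomain", protein: ProteinRecord, rules: RuleTable
) -> BindingCall:
    """Assign a binding group to an anchored domain.

    Rules are tried in table order; the first rule whose every
    (position, allowed set) constraint matches the protein wins.
    Deviations of the -18 and -10 residues from {N} and {R,K} are
    always reported as anomalies, whichever rule matched.
    """
    seq = protein.sequence

    def residue(pos: int) -> str:
        return seq[domain.index_of(pos)]

    anomalies = []
    if residue(-18) not in {"N"}:
        anomalies.append((-18, frozenset("N"), residue(-18)))
    if residue(-10) not in {"R", "K"}:
        anomalies.append((-10, frozenset("RK"), residue(-10)))

    for rule in rules.group_rules:
        if all(residue(pos) in allowed for pos, allowed in rule.constraints):
            return BindingCall(
                protein_id=protein.id,
                group=rule.label,
                matched_rule=rule.label,
                anomalies=tuple(anomalies),
            )
    return BindingCall(
        protein_id=protein.id,
        group="unassigned",
        matched_rule=None,
        anomalies=tuple(anomalies),
    )
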