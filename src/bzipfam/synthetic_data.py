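"""Synthetic bZIP families with planted ground truth.

Every downstream stage is testable without downloads: the generator
emits proteins carrying exactly one planted N-x7-R/K-x9 anchor followed
by a heptad-periodic leucine zipper with controlled register
composition, matched gene models realizing introns at planted positions
and phases, a qRT-PCR Ct table with planted log2 fold-change effects,
and a truth object recording every planted label.

Design choices favour reproducibility over realism: back-translation
uses one fixed codon per amino acid, background residues are drawn from
an alphabet that cannot seed a second anchor (no N/K/R/I and no charged
residues), and a rejection loop re-draws any protein whose sequence
still scans to more than the single planted anchor.  A given seed
produces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .binding_groups import default_rule_table
from .domain_anchor import ASN_TO_ZIPPER, scan_basic_anchor
from .sequence_io import (
    GeneModel,
    ProteinRecord,
    write_fasta,
    write_gff3,
)

GROUP_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI")

#: residue planted at hinge position -4 per group (the default rule table's key)
GROUP_KEY_AT_MINUS4 = {
    "I": "C", "II": "Q", "III": "S", "IV": "T", "V": "A",
    "VI": "G", "VII": "V", "VIII": "M", "IX": "C", "X": "W", "XI": "C",
}

#: background alphabet: uncharged, cannot form any part of an anchor motif
BACKGROUND = "ASTQGVFYWHCM"
#: zipper b/c/f register fillers (kept small and uncharged)
ZIP_FILLER = "ASTQ"

PAIR_PLAN_CLASSES = (
    "attract_ge",
    "attract_eg",
    "acidic_repulsive",
    "basic_repulsive",
    "incomplete_g",
    "incomplete_e",
    "uncharged",
)

#: (g residue, e' residue) realizing each planned pair class
_PAIR_RESIDUES = {
    "attract_ge": ("E", "K"),
    "attract_eg": ("K", "E"),
    "acidic_repulsive": ("E", "D"),
    "basic_repulsive": ("K", "R"),
    "incomplete_g": ("E", "S"),
    "incomplete_e": ("A", "K"),
    "uncharged": ("S", "T"),
}

#: signature code per planned class, matching dimerization.pair_signature
_PLAN_CODE = {
    "attract_ge": "A",
    "attract_eg": "B",
    "acidic_repulsive": "R",
    "basic_repulsive": "S",
    "incomplete_g": "i",
    "incomplete_e": "i",
    "uncharged": "u",
}

_ATTRACTIVE = {"attract_ge", "attract_eg"}
_REPULSIVE = {"acidic_repulsive", "basic_repulsive"}
_COMPLETE = _ATTRACTIVE | _REPULSIVE

#: one fixed codon per amino acid (reproducibility over codon-usage realism)
FIXED_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "X": "NNN",
}

PATTERN_CHOICES = ("a", "b", "c", "d", "e", "f_intronless", "f_outside")

CT_SAMPLES = ("mock_0h", "treat_6h", "treat_24h", "cold_6h", "salt_6h")
CT_CALIBRATOR = "mock_0h"
CT_REFERENCE = "SlActin"
CT_REPLICATES = 3
#: qPCR replicate noise, cycles (typical technical spread)
CT_NOISE_SD = 0.15


class SyntheticPlanError(ValueError):
    """An internally inconsistent protein plan."""


@dataclass(frozen=True)
class IntronPlan:
    """One planned intron: signed window position (or None for a tail
    intron), phase, and the residue the split codon must encode."""

    window_position: Optional[int]
    phase: str
    residue: Optional[str] = None


@dataclass
class ProteinPlan:
    protein_id: str
    gene_id: str
    group: str
    n_heptads: int
    pair_classes: tuple[str, ...]
    asn_a_heptads: frozenset[int] = frozenset()
    partial_extra: int = 0  # 0 or 1 extra zipper residue beyond the last full heptad
    met_d_heptads: frozenset[int] = frozenset()  # heptads with Met instead of Leu at d
    pad_len: int = 12
    tail_len: int = 10
    pattern: str = "f_intronless"
    intron_entries: tuple[IntronPlan, ...] = ()
    extra_tail_intron: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise SyntheticPlanError(f"unknown group {self.group!r}")
        if not 1 <= self.n_heptads:
            raise SyntheticPlanError("need at least one heptad")
        if len(self.pair_classes) != self.n_heptads - 1:
            raise SyntheticPlanError(
                f"{self.protein_id}: {self.n_heptads} heptads need "
                f"{self.n_heptads - 1} pair classes, got {len(self.pair_classes)}"
            )
        for c in self.pair_classes:
            if c not in PAIR_PLAN_CLASSES:
                raise SyntheticPlanError(f"unknown pair class {c!r}")
        if self.partial_extra not in (0, 1):
            raise SyntheticPlanError("partial_extra must be 0 or 1")
        if 1 in self.met_d_heptads:
            raise SyntheticPlanError("heptad 1 d must stay Leu (the +1 initiator)")

    # ---- planted truth, derived from the plan alone -------------------

    @property
    def n_heptads_total(self) -> int:
        return self.n_heptads + (1 if self.partial_extra else 0)

    @property
    def signature_key(self) -> tuple:
        return (
            self.n_heptads_total,
            tuple(_PLAN_CODE[c] for c in self.pair_classes),
        )

    @property
    def true_dimer_call(self) -> str:
        first_attractive = (
            len(self.pair_classes) > 0 and self.pair_classes[0] in _ATTRACTIVE
        )
        any_repulsive = any(c in _REPULSIVE for c in self.pair_classes)
        complete = [c for c in self.pair_classes if c in _COMPLETE]
        if first_attractive and not any_repulsive:
            return "homodimer"
        if complete and all(c in _REPULSIVE for c in complete):
            return "heterodimer"
        return "both"

    @property
    def true_pattern(self) -> str:
        if self.pattern in ("f_intronless", "f_outside"):
            return "f"
        if self.pattern == "p1":
            return "unclassified"
        return self.pattern


@dataclass
class SyntheticSpec:
    n_proteins: int
    seed: int
    plans: list[ProteinPlan] = field(default_factory=list)


@dataclass
class ProteinTruth:
    protein_id: str
    gene_id: str
    anchor: tuple[int, int, int]
    zipper_end_index: int
    group: str
    n_heptads: int
    asn_a_heptads: frozenset[int]
    pair_classes: tuple[tuple[int, str, Optional[str]], ...]  # (heptad, completeness, class)
    dimer_call: str
    signature_key: tuple
    pattern: str
    intronless: bool
    intron_phases: tuple[str, ...]
    cluster_id: Optional[str]


@dataclass
class SyntheticTruth:
    proteins: dict[str, ProteinTruth]
    expression: pd.DataFrame  # gene_id, sample_id, true_log2_fold
    clusters: dict[str, tuple[str, ...]]


@dataclass
class SyntheticFamily:
    proteins: list[ProteinRecord]
    models: list[GeneModel]
    ct_table: pd.DataFrame
    truth: SyntheticTruth


# ----------------------------------------------------------------------
# plan construction


def default_spec(n_proteins: int = 200, seed: int = 0) -> SyntheticSpec:
    """Mixed plans emulating the family's observed spread: groups cycle
    through I-XI, zippers span three to nine heptads, all six intron
    patterns occur, and roughly one plan in seventeen carries a
    degenerate P1 window intron (expected to be flagged, not forced
    into a pattern)."""
    rng = np.random.default_rng(seed)
    plans = []
    for i in range(n_proteins):
        group = GROUP_LABELS[i % len(GROUP_LABELS)]
        n_heptads = int(rng.integers(3, 10))
        pair_classes = tuple(
            PAIR_PLAN_CLASSES[int(rng.integers(len(PAIR_PLAN_CLASSES)))]
            for _ in range(n_heptads - 1)
        )
        asn_a = frozenset(
            int(h) for h in range(1, n_heptads + 1) if rng.random() < 0.3
        )
        met_d = frozenset(
            int(h) for h in range(2, n_heptads + 1) if rng.random() < 0.1
        )
        if i % 17 == 16:
            pattern = "p1"
        else:
            pattern = PATTERN_CHOICES[i % len(PATTERN_CHOICES)]
        plans.append(
            make_plan(
                protein_id=f"SYN{i + 1:03d}",
                gene_id=f"SYNG{i + 1:03d}",
                group=group,
                n_heptads=n_heptads,
                pair_classes=pair_classes,
                asn_a_heptads=asn_a,
                met_d_heptads=met_d,
                partial_extra=1 if rng.random() < 0.2 else 0,
                pattern=pattern,
                pad_len=int(rng.integers(5, 30)),
                tail_len=int(rng.integers(4, 25)),
                extra_tail_intron=bool(rng.random() < 0.3),
                rng=rng,
            )
        )
    return SyntheticSpec(n_proteins=n_proteins, seed=seed, plans=plans)


def spec_with_signatures(
    n_proteins: int, n_signatures: int, seed: int = 0
) -> SyntheticSpec:
    """A family drawn from exactly ``n_signatures`` distinct planted
    zipper signatures (for subfamily-partition tests)."""
    rng = np.random.default_rng(seed)
    keys: list[tuple[int, tuple[str, ...]]] = []
    seen = set()
    while len(keys) < n_signatures:
        n_heptads = int(rng.integers(3, 10))
        classes = tuple(
            PAIR_PLAN_CLASSES[int(rng.integers(len(PAIR_PLAN_CLASSES)))]
            for _ in range(n_heptads - 1)
        )
        key = (n_heptads, tuple(_PLAN_CODE[c] for c in classes))
        if key not in seen:
            seen.add(key)
            keys.append((n_heptads, classes))
    plans = []
    for i in range(n_proteins):
        n_heptads, classes = keys[i % n_signatures]
        plans.append(
            make_plan(
                protein_id=f"SYN{i + 1:03d}",
                gene_id=f"SYNG{i + 1:03d}",
                group=GROUP_LABELS[i % len(GROUP_LABELS)],
                n_heptads=n_heptads,
                pair_classes=classes,
                pattern=PATTERN_CHOICES[i % len(PATTERN_CHOICES)],
                rng=rng,
            )
        )
    return SyntheticSpec(n_proteins=n_proteins, seed=seed, plans=plans)


def make_plan(
    protein_id: str,
    gene_id: str,
    group: str,
    n_heptads: int,
    pair_classes: tuple[str, ...],
    pattern: str = "f_intronless",
    rng: Optional[np.random.Generator] = None,
    **kwargs,
) -> ProteinPlan:
    """Build a plan, deriving intron entries from the target pattern."""
    rng = rng if rng is not None else np.random.default_rng(0)
    entries: tuple[IntronPlan, ...] = ()
    # positions -18, -10 and -4 carry anchor/group residues, so P2 plans
    # (which overwrite the interrupted residue) avoid them
    free_window = [q for q in range(-18, 0) if q not in (-18, -10, -4)]
    if pattern == "a":
        q = int(rng.choice([q for q in range(-18, -10)]))
        entries = (IntronPlan(q, "P0"),)
    elif pattern == "b":
        q = int(rng.choice([q for q in range(-10, 0)]))
        entries = (IntronPlan(q, "P0"),)
    elif pattern == "c":
        q1, q2 = sorted(
            int(q) for q in rng.choice(range(-18, 0), size=2, replace=False)
        )
        entries = (IntronPlan(q1, "P0"), IntronPlan(q2, "P0"))
    elif pattern == "d":
        q = int(rng.choice(free_window))
        entries = (IntronPlan(q, "P2", "Q"),)
    elif pattern == "e":
        q = int(rng.choice(free_window))
        entries = (IntronPlan(q, "P2", "R"),)
    elif pattern == "p1":
        q = int(rng.choice(free_window))
        entries = (IntronPlan(q, "P1", "S"),)
    elif pattern == "f_outside":
        entries = (IntronPlan(None, "P0"),)
    elif pattern != "f_intronless":
        raise SyntheticPlanError(f"unknown pattern request {pattern!r}")
    return ProteinPlan(
        protein_id=protein_id,
        gene_id=gene_id,
        group=group,
        n_heptads=n_heptads,
        pair_classes=pair_classes,
        pattern=pattern,
        intron_entries=entries,
        **kwargs,
    )


# ----------------------------------------------------------------------
# sequence realization


def _bg(rng: np.random.Generator, n: int, alphabet: str = BACKGROUND) -> list[str]:
    return [alphabet[int(i)] for i in rng.integers(0, len(alphabet), size=n)]


def _build_sequence(plan: ProteinPlan, rng: np.random.Generator) -> tuple[str, int]:
    """Realize one protein; returns (sequence, asn_index)."""
    pad = _bg(rng, plan.pad_len)
    basic = _bg(rng, 18)
    planted: dict[int, str] = {0: "K" if plan.group == "IX" else "N"}
    planted[8] = "I" if plan.group == "XI" else "R"
    planted[14] = GROUP_KEY_AT_MINUS4[plan.group]  # position -4
    for entry in plan.intron_entries:
        if entry.window_position is None or entry.residue is None:
            continue
        idx = entry.window_position + 18  # 0-based within the basic/hinge block
        if idx in planted and planted[idx] != entry.residue:
            raise SyntheticPlanError(
                f"{plan.protein_id}: intron plan wants {entry.residue} at "
                f"position {entry.window_position} but {planted[idx]} is planted there"
            )
        planted[idx] = entry.residue
    for idx, res in planted.items():
        basic[idx] = res

    zipper: list[str] = []
    n = plan.n_heptads
    for h in range(1, n + 1):
        hept = {reg: None for reg in "defgabc"}
        hept["d"] = "M" if h in plan.met_d_heptads else "L"
        hept["a"] = "N" if h in plan.asn_a_heptads else "V"
        for reg in ("b", "c", "f"):
            hept[reg] = ZIP_FILLER[int(rng.integers(len(ZIP_FILLER)))]
        if h == 1:
            hept["e"] = "Q"
        else:
            hept["e"] = _PAIR_RESIDUES[plan.pair_classes[h - 2]][1]
        if h == n:
            hept["g"] = "S"
        else:
            hept["g"] = _PAIR_RESIDUES[plan.pair_classes[h - 1]][0]
        zipper.extend(hept[reg] for reg in "defgabc")
    if plan.partial_extra:
        zipper.append("L")  # lone d of the trailing partial heptad
    zipper[0] = "L"  # +1 initiator, always Leu

    parts = pad + basic + zipper
    if plan.tail_len > 0:
        parts.append("P")  # helix breaker terminates the zipper
        parts.extend(_bg(rng, plan.tail_len))
    return "".join(parts), plan.pad_len


def _realize_protein(
    plan: ProteinPlan, rng: np.random.Generator, max_attempts: int = 50
) -> tuple[ProteinRecord, int]:
    """Build the sequence, rejecting drafts with accidental anchors."""
    rules = default_rule_table()
    for _ in range(max_attempts):
        seq, asn_index = _build_sequence(plan, rng)
        record = ProteinRecord(
            id=plan.protein_id, sequence=seq, description=f"synthetic group {plan.group}"
        )
        candidates = scan_basic_anchor(record, rules)
        want = (asn_index, asn_index + 8, asn_index + ASN_TO_ZIPPER)
        if candidates == [want]:
            return record, asn_index
    raise SyntheticPlanError(
        f"{plan.protein_id}: could not realize a single-anchor sequence "
        f"in {max_attempts} attempts"
    )


# ----------------------------------------------------------------------
# gene model realization


def _intron_cuts(plan: ProteinPlan, asn_index: int, protein_len: int) -> list[int]:
    """Cumulative CDS nucleotide counts at which introns interrupt."""
    cuts = []
    first_leu = asn_index + ASN_TO_ZIPPER
    for entry in plan.intron_entries:
        if entry.window_position is not None:
            pp = asn_index + 19 + entry.window_position  # 1-based codon
        else:
            pp = min(first_leu + 3, protein_len)  # inside the zipper: outside window
        offset = {"P0": 0, "P1": 1, "P2": 2}[entry.phase]
        cuts.append(3 * (pp - 1) + offset)
    if plan.extra_tail_intron:
        pp = max(first_leu + 6, protein_len - 2)
        pp = min(pp, protein_len)
        cut = 3 * (pp - 1)
        if cut not in cuts:
            cuts.append(cut)
    cuts = sorted(set(cuts))
    total = 3 * protein_len
    if any(c <= 0 or c >= total for c in cuts):
        raise SyntheticPlanError(f"{plan.protein_id}: intron cut outside the CDS")
    return cuts


def _make_gene_model(
    plan: ProteinPlan,
    protein: ProteinRecord,
    asn_index: int,
    chromosome: str,
    gene_start: int,
    strand: str,
    rng: np.random.Generator,
) -> tuple[GeneModel, int]:
    """Place the gene on the chromosome; returns (model, genomic end)."""
    cuts = _intron_cuts(plan, asn_index, len(protein))
    bounds = [0] + cuts + [3 * len(protein)]
    piece_lens = [b - a for a, b in zip(bounds, bounds[1:])]
    intron_lens = [int(rng.integers(80, 500)) for _ in cuts]

    gene_len = sum(piece_lens) + sum(intron_lens)
    gene_end = gene_start + gene_len - 1
    segments_plus: list[tuple[int, int]] = []
    cursor = gene_start
    for i, plen in enumerate(piece_lens):
        segments_plus.append((cursor, cursor + plen - 1))
        cursor += plen
        if i < len(intron_lens):
            cursor += intron_lens[i]
    if strand == "+":
        segments = segments_plus
    else:
        # transcript 5'->3' runs high-to-low: mirror the layout so the
        # first coding piece is the highest-coordinate segment
        segments = []
        for s, e in segments_plus:
            segments.append((gene_start + gene_end - e, gene_start + gene_end - s))
    model = GeneModel(
        gene_id=plan.gene_id,
        protein_id=plan.protein_id,
        chromosome=chromosome,
        strand=strand,
        cds_segments=segments,
    )
    return model, gene_end


# ----------------------------------------------------------------------
# family generation


def generate_family(spec: SyntheticSpec) -> SyntheticFamily:
    """Generate proteins, gene models, a Ct table and the truth bundle."""
    if not spec.plans:
        spec = default_spec(spec.n_proteins, spec.seed)
    rng = np.random.default_rng(spec.seed)

    # tandem layout: ~12% of genes open a cluster of 2-3 consecutive genes
    cluster_of: dict[str, str] = {}
    clusters: dict[str, tuple[str, ...]] = {}
    i = 0
    cluster_n = 0
    while i < len(spec.plans):
        if i + 1 < len(spec.plans) and rng.random() < 0.12:
            size = int(rng.integers(2, 4))
            members = [p.gene_id for p in spec.plans[i:i + size]]
            if len(members) >= 2:
                cluster_n += 1
                label = f"T{cluster_n}"
                clusters[label] = tuple(members)
                for g in members:
                    cluster_of[g] = label
            i += size
        else:
            i += 1

    proteins: list[ProteinRecord] = []
    models: list[GeneModel] = []
    truths: dict[str, ProteinTruth] = {}
    chrom_idx = 0
    cursors = {f"ch{c:02d}": 1_000_000 for c in range(1, 13)}
    prev_cluster: Optional[str] = None

    for plan in spec.plans:
        protein, asn_index = _realize_protein(plan, rng)
        proteins.append(protein)

        this_cluster = cluster_of.get(plan.gene_id)
        same_cluster = this_cluster is not None and this_cluster == prev_cluster
        if not same_cluster and rng.random() < 0.15:
            chrom_idx = (chrom_idx + 1) % 12
        chrom = f"ch{chrom_idx + 1:02d}"
        gap = (
            int(rng.integers(2_000, 20_000))
            if same_cluster
            else int(rng.integers(150_000, 300_000))
        )
        start = cursors[chrom] + gap
        strand = "+" if rng.random() < 0.5 else "-"
        model, gene_end = _make_gene_model(
            plan, protein, asn_index, chrom, start, strand, rng
        )
        cursors[chrom] = gene_end
        models.append(model)
        prev_cluster = this_cluster

        pair_truth = []
        for h, cls in enumerate(plan.pair_classes, start=1):
            if cls in _COMPLETE:
                pair_truth.append((h, "complete", cls))
            elif cls == "uncharged":
                pair_truth.append((h, "uncharged", None))
            else:
                pair_truth.append((h, "incomplete", None))
        first_leu = asn_index + ASN_TO_ZIPPER
        truths[plan.protein_id] = ProteinTruth(
            protein_id=plan.protein_id,
            gene_id=plan.gene_id,
            anchor=(asn_index, asn_index + 8, first_leu),
            zipper_end_index=first_leu + 7 * plan.n_heptads + plan.partial_extra - 1,
            group=plan.group,
            n_heptads=plan.n_heptads_total,
            asn_a_heptads=plan.asn_a_heptads,
            pair_classes=tuple(pair_truth),
            dimer_call=plan.true_dimer_call,
            signature_key=plan.signature_key,
            pattern=plan.true_pattern,
            intronless=len(plan.intron_entries) == 0 and not plan.extra_tail_intron,
            intron_phases=tuple(e.phase for e in plan.intron_entries),
            cluster_id=this_cluster,
        )

    ct_table, expression_truth = _generate_ct(spec, rng)
    truth = SyntheticTruth(
        proteins=truths, expression=expression_truth, clusters=clusters
    )
    return SyntheticFamily(
        proteins=proteins, models=models, ct_table=ct_table, truth=truth
    )


def _generate_ct(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    truth_rows = []
    base_ref = 18.5
    for plan in spec.plans:
        base = float(rng.uniform(22.0, 30.0))
        for sample in CT_SAMPLES:
            l2f = 0.0 if sample == CT_CALIBRATOR else float(rng.normal(0.0, 2.0))
            truth_rows.append(
                {"gene_id": plan.gene_id, "sample_id": sample, "true_log2_fold": l2f}
            )
            for rep in range(1, CT_REPLICATES + 1):
                rows.append(
                    {
                        "gene_id": plan.gene_id,
                        "sample_id": sample,
                        "replicate": rep,
                        "ct": base - l2f + float(rng.normal(0.0, CT_NOISE_SD)),
                    }
                )
    for sample in CT_SAMPLES:
        for rep in range(1, CT_REPLICATES + 1):
            rows.append(
                {
                    "gene_id": CT_REFERENCE,
                    "sample_id": sample,
                    "replicate": rep,
                    "ct": base_ref + float(rng.normal(0.0, CT_NOISE_SD)),
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def generate_decoys(n: int, seed: int = 0) -> list[ProteinRecord]:
    """Non-bZIP proteins guaranteed to contain no anchor motif.

    The alphabet omits every residue the anchor scan accepts at -18
    (N/K/R), so no candidate can exist; the scan itself is still run as
    a post-check.
    """
    rng = np.random.default_rng(seed)
    rules = default_rule_table()
    alphabet = "ASTQGVFYWHCMLDEP"
    decoys = []
    for i in range(n):
        length = int(rng.integers(50, 300))
        seq = "".join(
            alphabet[int(j)] for j in rng.integers(0, len(alphabet), size=length)
        )
        record = ProteinRecord(id=f"DECOY{i + 1:03d}", sequence=seq)
        if scan_basic_anchor(record, rules):
            raise SyntheticPlanError(f"decoy {record.id} scans to an anchor")
        decoys.append(record)
    return decoys


# ----------------------------------------------------------------------
# writers


def write_family(family: SyntheticFamily, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, GFF3, Ct TSV and truth TSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "gff3": outdir / "genes.gff3",
        "ct": outdir / "ct_values.tsv",
        "truth": outdir / "truth.tsv",
        "truth_expression": outdir / "truth_expression.tsv",
    }
    write_fasta(family.proteins, paths["fasta"])
    write_gff3(family.models, paths["gff3"])
    family.ct_table.to_csv(paths["ct"], sep="\t", index=False, float_format="%.6f")
    truth_rows = []
    for t in family.truth.proteins.values():
        truth_rows.append(
            {
                "protein_id": t.protein_id,
                "gene_id": t.gene_id,
                "asn_index": t.anchor[0],
                "basic_index": t.anchor[1],
                "first_leu_index": t.anchor[2],
                "zipper_end_index": t.zipper_end_index,
                "group": t.group,
                "n_heptads": t.n_heptads,
                "asn_a_heptads": ",".join(map(str, sorted(t.asn_a_heptads))),
                "dimer_call": t.dimer_call,
                "pattern": t.pattern,
                "intronless": t.intronless,
                "intron_phases": ",".join(t.intron_phases),
                "cluster_id": t.cluster_id or "",
            }
        )
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    family.truth.expression.to_csv(
        paths["truth_expression"], sep="\t", index=False, float_format="%.6f"
    )
    return paths
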