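"""End-to-end run: scan -> classify -> zipper -> dimer -> introns -> summarize.

A run is a pure function of its inputs and configuration.  The manifest
written next to the reports records a hash of the canonical config, the
package version and the SHA-256 of every input file, so identical
reruns are verifiable byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .binding_groups import RuleTable, classify_binding_group, default_rule_table, load_rule_table
from .dimerization import assign_subfamilies, build_profile
from .domain_anchor import find_domain
from .family_stats import (
    composition,
    detect_tandem_clusters,
    genes_in_blocks,
    join_report,
)
from .intron_patterns import (
    DEFAULT_PATTERN_TABLE,
    classify_intron_pattern,
    pattern_census,
)
from .sequence_io import collapse_transcripts, introns_from_model, read_fasta, read_gff3

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    fasta: str
    gff3: Optional[str] = None
    rules: Optional[str] = None
    blocks: Optional[str] = None
    out_dir: str = "bzipfam_out"
    register_offset: int = 0
    denominator_mode: str = "all_members"
    histidine_basic: bool = False
    max_intervening: int = 1
    max_gap_bp: int = 100_000
    pattern_table: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_PATTERN_TABLE.items()}
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def validate(self) -> None:
        for label, p in (("fasta", self.fasta), ("gff3", self.gff3),
                         ("rules", self.rules), ("blocks", self.blocks)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config {label} path does not exist: {p}")
        if self.denominator_mode not in ("all_members", "members_with_heptad"):
            raise ValueError(f"unknown denominator_mode {self.denominator_mode!r}")

    def canonical(self) -> str:
        # out_dir is where results land, not an analysis parameter: two
        # runs differing only in destination are the same analysis
        data = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return json.dumps(data, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()


def _charge_classes(rules: RuleTable, histidine_basic: bool) -> dict[str, frozenset[str]]:
    basic = rules.class_("basic")
    if histidine_basic:
        basic = basic | frozenset("H")
    return {"acidic": rules.class_("acidic"), "basic": basic}


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write TSV reports plus a run manifest."""
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    rules = load_rule_table(config.rules) if config.rules else default_rule_table()
    classes = _charge_classes(rules, config.histidine_basic)
    pattern_table = {k: tuple(v) for k, v in config.pattern_table.items()}

    def stage(name):
        logger.info("stage: %s", name)

    stage("scan")
    proteins = read_fasta(config.fasta)
    domains = {}
    scan_rows = []
    for protein in proteins:
        domain = find_domain(protein, rules)
        if domain is None:
            scan_rows.append(
                {"protein_id": protein.id, "status": "no_bzip_domain",
                 "asn_index": "", "basic_index": "", "first_leu_index": "",
                 "zipper_length": ""}
            )
            continue
        domains[protein.id] = domain
        scan_rows.append(
            {"protein_id": protein.id, "status": "ok",
             "asn_index": domain.asn_index,
             "basic_index": domain.basic_residue_index,
             "first_leu_index": domain.first_leu_index,
             "zipper_length": domain.zipper_length}
        )
    pd.DataFrame(scan_rows).to_csv(outdir / "scan.tsv", sep="\t", index=False)

    stage("classify")
    proteins_by_id = {p.id: p for p in proteins}
    binding = {
        pid: classify_binding_group(domain, proteins_by_id[pid], rules)
        for pid, domain in domains.items()
    }
    pd.DataFrame(
        [
            {"protein_id": pid, "group": call.group,
             "anomalies": ";".join(
                 f"{pos}:{obs}" for pos, _, obs in call.anomalies)}
            for pid, call in binding.items()
        ]
    ).to_csv(outdir / "groups.tsv", sep="\t", index=False)

    stage("zipper/dimer")
    profiles = [
        build_profile(domains[pid], proteins_by_id[pid], classes,
                      config.register_offset)
        for pid in domains
    ]
    profiles = assign_subfamilies(profiles)
    profile_of = {p.protein_id: p for p in profiles}
    pd.DataFrame(
        [
            {"protein_id": p.protein_id, "zipper_heptads": p.zipper_heptads,
             "dimer_call": p.dimer_call, "subfamily": p.subfamily,
             "signature": p.signature,
             "leu_at_d_fraction": round(p.leu_at_d_fraction, 4)}
            for p in profiles
        ]
    ).to_csv(outdir / "dimer.tsv", sep="\t", index=False)

    comp = composition(profiles, config.denominator_mode) if profiles else None
    if comp is not None:
        pd.DataFrame(
            [
                {"heptad": h, "asn_at_a": round(f, 4),
                 **{k: round(v, 4) for k, v in
                    comp.pair_freq_per_heptad.get(h, {}).items()}}
                for h, f in sorted(comp.asn_at_a_per_heptad.items())
            ]
        ).to_csv(outdir / "composition_per_heptad.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"register": r, "residue": res, "frequency": round(f, 4)}
                for r, freqs in comp.register_freq.items()
                for res, f in freqs.items()
            ]
        ).to_csv(outdir / "composition_registers.tsv", sep="\t", index=False)

    stage("introns")
    pattern_calls = {}
    gene_of_protein = {}
    models = []
    if config.gff3:
        models = collapse_transcripts(read_gff3(config.gff3))
        intron_rows = []
        for model in models:
            gene_of_protein[model.protein_id] = model.gene_id
            protein = proteins_by_id.get(model.protein_id)
            domain = domains.get(model.protein_id)
            if protein is None or domain is None:
                continue
            introns = introns_from_model(model, protein)
            call = classify_intron_pattern(model, domain, introns, pattern_table)
            pattern_calls[model.gene_id] = call
            intron_rows.append(
                {"gene_id": model.gene_id, "pattern": call.pattern,
                 "intronless": call.intronless_gene,
                 "phases": ",".join(i.phase for i in introns),
                 "positions": ",".join(str(i.protein_position) for i in introns),
                 "reasons": ";".join(call.reasons)}
            )
        pd.DataFrame(intron_rows).to_csv(outdir / "introns.tsv", sep="\t", index=False)
        if pattern_calls:
            pattern_census(list(pattern_calls.values())).to_csv(
                outdir / "pattern_census.tsv", sep="\t", index=False
            )

    stage("summarize")
    clusters = []
    if models:
        family_ids = {m.gene_id for m in models}
        clusters = detect_tandem_clusters(
            models, family_ids, config.max_intervening, config.max_gap_bp
        )
        pd.DataFrame(
            [
                {"cluster": f"cluster{i}", "chromosome": c.chromosome,
                 "members": ",".join(c.members),
                 "start": c.span[0], "end": c.span[1]}
                for i, c in enumerate(clusters, start=1)
            ]
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    blocks_membership = None
    if config.blocks and models:
        blocks = pd.read_csv(config.blocks, sep="\t")
        blocks_membership = genes_in_blocks(models, blocks)
    report = join_report(
        [p.id for p in proteins],
        {pid: call.group for pid, call in binding.items()},
        profile_of,
        pattern_calls,
        gene_of_protein,
        clusters,
        blocks_membership,
    )
    report.to_csv(outdir / "report.tsv", sep="\t", index=False)

    manifest = {
        "config_hash": config.config_hash,
        "bzipfam_version": __version__,
        "inputs": {
            label: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for label, p in (("fasta", config.fasta), ("gff3", config.gff3),
                             ("rules", config.rules), ("blocks", config.blocks))
            if p is not None
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir
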