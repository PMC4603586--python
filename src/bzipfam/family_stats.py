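"""Family-level composition statistics, tandem clusters and the joined report.

Composition tables summarize the zipper interface across the family:
residue frequencies at the g, e, a and d registers, the per-heptad
frequency of Asn at a (the a<->a' N-N interaction marks homodimerizing
heptads), and per-heptad complete/incomplete/uncharged and
attractive/repulsive g<->e' pair frequencies.

Tandem clusters — runs of family members adjacent on a chromosome — are
the footprint of tandem duplication.  Two family genes chain when at
most ``max_intervening`` annotated non-family genes separate them (when
a full gene census is supplied) or when their genomic gap is at most
``max_gap_bp`` (family-only input); clusters are maximal chains of two
or more genes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .dimerization import ATTRACTIVE, REPULSIVE, DimerProfile
from .intron_patterns import IntronPatternCall
from .sequence_io import GeneModel

logger = logging.getLogger(__name__)

INTERFACE_REGISTERS = ("g", "e", "a", "d")

DENOMINATOR_MODES = ("all_members", "members_with_heptad")


@dataclass
class CompositionTable:
    """Family-level interface composition.

    ``register_freq`` maps register -> residue -> frequency (summing to
    1 over the residues observed at that register).  The per-heptad
    tables are indexed by heptad number; frequencies use the chosen
    denominator mode.
    """

    register_freq: dict[str, dict[str, float]]
    asn_at_a_per_heptad: dict[int, float]
    pair_freq_per_heptad: dict[int, dict[str, float]]
    denominator_mode: str


@dataclass(frozen=True)
class TandemCluster:
    chromosome: str
    members: tuple[str, ...]
    span: tuple[int, int]


def composition(
    profiles: list[DimerProfile],
    denominator_mode: str = "all_members",
) -> CompositionTable:
    """Compute the family composition table from dimer profiles.

    Under ``all_members`` every protein counts in each per-heptad
    denominator whether or not it reaches that heptad; under
    ``members_with_heptad`` only proteins possessing the relevant
    register (or pair) do, so frequencies can only grow.
    """
    if not profiles:
        raise ValueError("composition of an empty profile list")
    if denominator_mode not in DENOMINATOR_MODES:
        raise ValueError(f"unknown denominator mode {denominator_mode!r}")
    n_total = len(profiles)

    register_counts: dict[str, Counter] = {r: Counter() for r in INTERFACE_REGISTERS}
    max_heptad = 0
    for p in profiles:
        for h in p.heptads:
            max_heptad = max(max_heptad, h.index)
            for r in INTERFACE_REGISTERS:
                res = h.get(r)
                if res is not None:
                    register_counts[r][res] += 1
    register_freq = {
        r: {res: cnt / total for res, cnt in sorted(counts.items())}
        for r, counts in register_counts.items()
        if (total := sum(counts.values()))
    }

    asn_at_a: dict[int, float] = {}
    for n in range(1, max_heptad + 1):
        with_a = [p for p in profiles if any(
            h.index == n and h.get("a") is not None for h in p.heptads
        )]
        denom = n_total if denominator_mode == "all_members" else len(with_a)
        hits = sum(1 for p in with_a if n in p.asn_at_a)
        asn_at_a[n] = hits / denom if denom else 0.0

    pair_freq: dict[int, dict[str, float]] = {}
    max_pair_heptad = max(
        (pr.heptad_index for p in profiles for pr in p.pairs), default=0
    )
    for n in range(1, max_pair_heptad + 1):
        pairs_n = [
            pr for p in profiles for pr in p.pairs if pr.heptad_index == n
        ]
        denom = n_total if denominator_mode == "all_members" else len(pairs_n)
        counts = {
            "complete": sum(1 for pr in pairs_n if pr.completeness == "complete"),
            "incomplete": sum(1 for pr in pairs_n if pr.completeness == "incomplete"),
            "uncharged": sum(1 for pr in pairs_n if pr.completeness == "uncharged"),
            "attractive": sum(1 for pr in pairs_n if pr.pair_class in ATTRACTIVE),
            "repulsive": sum(1 for pr in pairs_n if pr.pair_class in REPULSIVE),
        }
        pair_freq[n] = {
            k: (v / denom if denom else 0.0) for k, v in counts.items()
        }

    return CompositionTable(
        register_freq=register_freq,
        asn_at_a_per_heptad=asn_at_a,
        pair_freq_per_heptad=pair_freq,
        denominator_mode=denominator_mode,
    )


def detect_tandem_clusters(
    models: list[GeneModel],
    family_ids: set[str],
    max_intervening: int = 1,
    max_gap_bp: int = 100_000,
) -> list[TandemCluster]:
    """Maximal chains of family genes adjacent on a chromosome.

    If ``models`` contains non-family genes it is treated as a full
    gene census and the intervening-gene rule applies; otherwise the
    base-pair gap rule applies.  Missing coordinates raise with the
    offending gene names.
    """
    missing = [m.gene_id for m in models if not m.cds_segments]
    if missing:
        raise ValueError(f"genes without coordinates: {missing}")
    unknown = family_ids - {m.gene_id for m in models}
    if unknown:
        raise ValueError(f"family ids without gene models: {sorted(unknown)}")
    census_mode = any(m.gene_id not in family_ids for m in models)

    clusters: list[TandemCluster] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append(m)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda m: m.span)
        chain: list[GeneModel] = []
        prev_family_pos: Optional[int] = None
        for pos, m in enumerate(ordered):
            if m.gene_id not in family_ids:
                continue
            linked = False
            if chain:
                prev = chain[-1]
                if census_mode:
                    intervening = pos - prev_family_pos - 1
                    linked = intervening <= max_intervening
                else:
                    linked = m.span[0] - prev.span[1] <= max_gap_bp
            if linked:
                chain.append(m)
            else:
                if len(chain) >= 2:
                    clusters.append(_finish_cluster(chrom, chain))
                chain = [m]
            prev_family_pos = pos
        if len(chain) >= 2:
            clusters.append(_finish_cluster(chrom, chain))
    return clusters


def _finish_cluster(chrom: str, chain: list[GeneModel]) -> TandemCluster:
    return TandemCluster(
        chromosome=chrom,
        members=tuple(m.gene_id for m in chain),
        span=(min(m.span[0] for m in chain), max(m.span[1] for m in chain)),
    )


def genes_in_blocks(
    models: Iterable[GeneModel], blocks: pd.DataFrame
) -> dict[str, list[str]]:
    """Map genes into externally supplied duplicated-segment blocks.

    ``blocks`` is a 4-column table (block_id, chrom, start, end) from an
    external synteny tool; a gene belongs to a block when its span lies
    within the block interval.  Membership only — no synteny is computed.
    """
    required = {"block_id", "chrom", "start", "end"}
    if not required.issubset(blocks.columns):
        raise ValueError(f"blocks table needs columns {sorted(required)}")
    result: dict[str, list[str]] = {}
    for m in models:
        start, end = m.span
        hits = blocks[
            (blocks["chrom"] == m.chromosome)
            & (blocks["start"] <= start)
            & (blocks["end"] >= end)
        ]
        result[m.gene_id] = sorted(hits["block_id"].astype(str))
    return result


def join_report(
    proteins: Iterable[str],
    binding_calls: Mapping[str, str],
    profiles: Mapping[str, DimerProfile],
    pattern_calls: Mapping[str, IntronPatternCall],
    gene_of_protein: Mapping[str, str],
    clusters: list[TandemCluster] | None = None,
    blocks_membership: Mapping[str, list[str]] | None = None,
) -> pd.DataFrame:
    """One row per protein joining every per-protein/per-gene call.

    Ids present in one table but absent elsewhere produce rows with
    explicit missing markers (``NA``) and a logged warning; the row
    count always equals the protein count.
    """
    cluster_of: dict[str, str] = {}
    for i, cl in enumerate(clusters or [], start=1):
        for g in cl.members:
            cluster_of[g] = f"cluster{i}"
    rows = []
    for pid in proteins:
        gene = gene_of_protein.get(pid)
        profile = profiles.get(pid)
        pattern = pattern_calls.get(gene) if gene else None
        for name, val in (
            ("gene model", gene),
            ("dimer profile", profile),
            ("intron pattern", pattern),
        ):
            if val is None:
                logger.warning("protein %s: missing %s", pid, name)
        rows.append(
            {
                "protein_id": pid,
                "gene_id": gene if gene else "NA",
                "group": binding_calls.get(pid, "NA"),
                "dimer_call": profile.dimer_call if profile else "NA",
                "subfamily": (profile.subfamily or "NA") if profile else "NA",
                "zipper_heptads": profile.zipper_heptads if profile else "NA",
                "intron_pattern": pattern.pattern if pattern else "NA",
                "cluster": cluster_of.get(gene, "") if gene else "NA",
                "blocks": ",".join(blocks_membership.get(gene, []))
                if (blocks_membership and gene)
                else "",
            }
        )
    return pd.DataFrame(rows)
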