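"""Independent oracles used by the unit and acceptance tests.

Each oracle recomputes an expectation by a different route than the
implementation it checks: brute-force enumeration, base-by-base walks,
regular-expression scans or naive O(n^3) agglomeration.
"""

from __future__ import annotations

import re

import numpy as np


def codon_walk_junctions(segment_lengths: list[int]) -> list[tuple[str, int]]:
    """Base-by-base codon walk: (phase, codon position) per CDS junction.

    Every coding base is assigned a (codon, slot) label by enumeration;
    a junction's phase is the slot of the first base after the splice
    and its protein position that base's codon.
    """
    total = sum(segment_lengths)
    slots = [(i // 3 + 1, i % 3) for i in range(total)]
    out = []
    cum = 0
    for length in segment_lengths[:-1]:
        cum += length
        codon, slot = slots[cum]
        out.append((f"P{slot}", codon))
    return out


def regex_anchor_scan(sequence: str, neg18: set, neg10: set, initiators: set):
    """Overlapping regular-expression scan for the anchor motif."""
    pattern = (
        f"(?=([{''.join(sorted(neg18))}])"
        f".{{7}}([{''.join(sorted(neg10))}])"
        f".{{9}}([{''.join(sorted(initiators))}]))"
    )
    return [
        (m.start(), m.start() + 8, m.start() + 18)
        for m in re.finditer(pattern, sequence)
    ]


def ge_pair_oracle(g: str, e: str, acidic: set, basic: set):
    """Truth-table classification of a g/e' pair from the charge sets."""
    kinds = []
    for r in (g, e):
        if r in acidic:
            kinds.append("-")
        elif r in basic:
            kinds.append("+")
        else:
            kinds.append(".")
    key = "".join(kinds)
    table = {
        "--": ("complete", "acidic_repulsive"),
        "++": ("complete", "basic_repulsive"),
        "-+": ("complete", "attract_ge"),
        "+-": ("complete", "attract_eg"),
        "..": ("uncharged", None),
    }
    if key in table:
        return table[key]
    return ("incomplete", None)


def dimer_call_oracle(pair_specs: list[tuple[int, str, str | None]]) -> str:
    """Re-derivation of the dimerization rule from (heptad, completeness,
    class) triples, structured as explicit case analysis."""
    classes_at_1 = {c for h, _, c in pair_specs if h == 1 and c is not None}
    all_classes = [c for _, _, c in pair_specs if c is not None]
    n_complete = sum(1 for _, comp, _ in pair_specs if comp == "complete")
    has_attract_1 = bool(classes_at_1 & {"attract_ge", "attract_eg"})
    n_repulsive = sum(
        1 for c in all_classes if c in ("acidic_repulsive", "basic_repulsive")
    )
    if has_attract_1 and n_repulsive == 0:
        return "homodimer"
    if n_complete >= 1 and n_repulsive == n_complete:
        return "heterodimer"
    return "both"


def naive_average_linkage_cophenetic(dist: np.ndarray) -> np.ndarray:
    """O(n^3) agglomeration; returns the cophenetic distance matrix.

    Clusters merge at the mean of their member-pair leaf distances; the
    cophenetic distance of two leaves is the height of the merge that
    first unites them.
    """
    n = dist.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        for a in clusters[i]:
            for b in clusters[j]:
                coph[a, b] = coph[b, a] = d
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return coph


def chain_clusters_oracle(layout, family, max_intervening=None, max_gap=None):
    """Brute-force tandem chaining on a toy layout.

    ``layout`` is a list of (gene_id, chrom, start, end) sorted any way;
    linked pairs become edges, clusters are connected components with
    at least two members.
    """
    by_chrom: dict[str, list] = {}
    for g in layout:
        by_chrom.setdefault(g[1], []).append(g)
    edges = []
    for chrom, genes in by_chrom.items():
        genes = sorted(genes, key=lambda g: g[2])
        fam = [g for g in genes if g[0] in family]
        for a, b in zip(fam, fam[1:]):
            if max_intervening is not None:
                between = [
                    g for g in genes
                    if a[2] < g[2] < b[2] and g[0] not in family
                ]
                if len(between) <= max_intervening:
                    edges.append((a[0], b[0]))
            else:
                if b[2] - a[3] <= max_gap:
                    edges.append((a[0], b[0]))
    parent = {g[0]: g[0] for g in layout}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    comps: dict[str, set] = {}
    for g in layout:
        if g[0] in family:
            comps.setdefault(find(g[0]), set()).add(g[0])
    return sorted(tuple(sorted(c)) for c in comps.values() if len(c) >= 2)


def ddct_oracle(rows, reference, calibrator):
    """Spreadsheet-style 2^-ΔΔCt recomputation with explicit loops.

    ``rows`` are (gene, sample, ct) tuples (replicates repeated).
    Returns {(gene, sample): fold}.
    """
    cts: dict[tuple[str, str], list[float]] = {}
    for gene, sample, ct in rows:
        cts.setdefault((gene, sample), []).append(ct)
    mean = {k: sum(v) / len(v) for k, v in cts.items()}
    genes = sorted({g for g, _ in mean} - {reference})
    samples = sorted({s for _, s in mean})
    out = {}
    for g in genes:
        dct_cal = mean[(g, calibrator)] - mean[(reference, calibrator)]
        for s in samples:
            dct = mean[(g, s)] - mean[(reference, s)]
            out[(g, s)] = 2.0 ** (-(dct - dct_cal))
    return out
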