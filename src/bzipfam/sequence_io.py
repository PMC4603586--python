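"""Read/write the standard formats the pipeline touches.

Proteins come in as FASTA, gene structures as GFF3.  The one non-trivial
computation here is mapping CDS segment junctions to intron splicing
phases and protein positions: an intron falling between two codons is
phase P0, after the first nucleotide of a codon P1, and between the
second and third nucleotides P2.  P1/P2 introns interrupt a codon, so
they interrupt a specific amino-acid residue.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

PHASES = ("P0", "P1", "P2")


def _normalize_sequence(seq: str) -> str:
    """Uppercase, strip whitespace, map non-canonical letters to X."""
    seq = "".join(seq.split()).upper()
    return "".join(c if c in CANONICAL_AA else "X" for c in seq)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a stable identifier.

    The sequence is normalized on construction: uppercase, whitespace
    removed, any letter outside the 20 canonical amino acids replaced
    by X.  X never matches any residue class downstream.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        norm = _normalize_sequence(self.sequence)
        if len(norm) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", norm)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A protein-coding gene model.

    ``cds_segments`` are (start, end) pairs in 1-based inclusive genomic
    coordinates, ordered 5'->3' in *transcript* orientation (descending
    genomic coordinates on the minus strand).  A total CDS length not
    divisible by 3 is flagged via ``length_ok``, never silently fixed.
    """

    gene_id: str
    protein_id: str
    chromosome: str
    strand: str
    cds_segments: list[tuple[int, int]]
    length_ok: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        for start, end in self.cds_segments:
            if start > end:
                raise ValueError(
                    f"gene {self.gene_id!r}: CDS segment {start}..{end} inverted"
                )
        spans = sorted((s, e) for s, e in self.cds_segments)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.gene_id!r}: overlapping CDS segments")
        self.length_ok = self.cds_length % 3 == 0

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent (min start, max end) over all CDS segments."""
        return (
            min(s for s, _ in self.cds_segments),
            max(e for _, e in self.cds_segments),
        )


@dataclass(frozen=True)
class IntronRecord:
    """One intron of a gene model, located on the protein.

    ``protein_position`` is the 1-based index of the codon containing
    (P1/P2) or immediately following (P0) the splice site.
    ``interrupted_residue`` is the amino acid encoded by the split codon
    for P1/P2 introns and ``None`` for P0.
    """

    intron_index: int
    protein_position: int
    phase: str
    interrupted_residue: Optional[str] = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if (self.phase == "P0") != (self.interrupted_residue is None):
            raise ValueError("P0 introns and only P0 introns lack an interrupted residue")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly gzipped) protein FASTA into ProteinRecords.

    A trailing stop-codon symbol ``*`` is stripped from the 3' end only;
    duplicate ids or an empty file raise ``ValueError``.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            seen.add(rec.id)
            seq = str(rec.seq)
            if seq.endswith("*"):
                seq = seq[:-1]
            desc = rec.description[len(rec.id):].strip()
            records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "wt") as handle:
        SeqIO.write(seqrecords, handle, "fasta")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from a (possibly gzipped) GFF3 file.

    One GeneModel per mRNA; mRNAs without CDS children are excluded and
    logged.  Minus-strand CDS segments are re-ordered into transcript
    orientation.  A CDS row without a Parent attribute is an error.
    """
    import gffutils

    with _open_text(path) as handle:
        text = handle.read()
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    for cds in db.features_of_type("CDS"):
        if "Parent" not in cds.attributes:
            raise ValueError(f"CDS at {cds.seqid}:{cds.start}-{cds.end} lacks a Parent")
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        cds_feats = list(db.children(mrna, featuretype="CDS"))
        if not cds_feats:
            logger.warning("mRNA %s has no CDS features; excluded", mrna.id)
            continue
        segments = sorted((c.start, c.end) for c in cds_feats)
        if mrna.strand == "-":
            segments = segments[::-1]
        parents = mrna.attributes.get("Parent", [mrna.id])
        protein_id = mrna.attributes.get("protein_id", [mrna.id])[0]
        model = GeneModel(
            gene_id=parents[0],
            protein_id=protein_id,
            chromosome=mrna.seqid,
            strand=mrna.strand,
            cds_segments=segments,
        )
        if not model.length_ok:
            logger.warning(
                "gene %s: CDS length %d not divisible by 3 (flagged)",
                model.gene_id,
                model.cds_length,
            )
        models.append(model)
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/CDS rows for the given models (plus-strand sorted)."""
    lines = ["##gff-version 3"]
    for m in models:
        start, end = m.span
        mrna_id = f"{m.gene_id}.1"
        lines.append(
            "\t".join(
                [m.chromosome, "bzipfam", "gene", str(start), str(end), ".",
                 m.strand, ".", f"ID={m.gene_id}"]
            )
        )
        lines.append(
            "\t".join(
                [m.chromosome, "bzipfam", "mRNA", str(start), str(end), ".",
                 m.strand, ".",
                 f"ID={mrna_id};Parent={m.gene_id};protein_id={m.protein_id}"]
            )
        )
        for s, e in sorted(m.cds_segments):
            lines.append(
                "\t".join(
                    [m.chromosome, "bzipfam", "CDS", str(s), str(e), ".",
                     m.strand, "0", f"ID=cds-{mrna_id};Parent={mrna_id}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def collapse_transcripts(models: list[GeneModel]) -> list[GeneModel]:
    """Keep the longest-CDS model per gene (alternative-transcript collapse)."""
    best: dict[str, GeneModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if cur is None or m.cds_length > cur.cds_length:
            best[m.gene_id] = m
    return [best[g] for g in sorted(best)]


def introns_from_model(
    model: GeneModel, protein: Optional[ProteinRecord] = None
) -> list[IntronRecord]:
    """Derive intron phase and protein position from CDS segment junctions.

    The phase of the junction after segment *k* is the cumulative CDS
    nucleotide count so far mod 3 (0 -> P0, 1 -> P1, 2 -> P2); the protein
    position is the codon containing (P1/P2) or following (P0) the
    splice.  ``protein`` supplies the interrupted residue letter for
    P1/P2 introns when given.
    """
    if not model.cds_segments:
        raise ValueError(f"gene {model.gene_id!r}: no CDS segments")
    if not model.length_ok:
        raise ValueError(
            f"gene {model.gene_id!r}: CDS length {model.cds_length} not divisible by 3"
        )
    introns: list[IntronRecord] = []
    cumulative = 0
    for idx, (start, end) in enumerate(model.cds_segments[:-1], start=1):
        cumulative += end - start + 1
        phase = PHASES[cumulative % 3]
        position = ceil((cumulative + 1) / 3)
        residue: Optional[str] = None
        if phase != "P0":
            if protein is not None:
                if position > len(protein):
                    raise ValueError(
                        f"gene {model.gene_id!r}: intron codon {position} beyond "
                        f"protein {protein.id!r} length {len(protein)}"
                    )
                residue = protein.sequence[position - 1]
            else:
                residue = "X"
        introns.append(
            IntronRecord(
                intron_index=idx,
                protein_position=position,
                phase=phase,
                interrupted_residue=residue,
            )
        )
    return introns
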