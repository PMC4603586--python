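import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bzipfam as bz
from bzipfam.sequence_io import collapse_transcripts, write_fasta, write_gff3

from helpers import codon_walk_junctions


class TestReadFasta:
    def test_two_records_with_description_and_case(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(
            ">bZIP01 basic leucine zipper 1\nmnarsk\n>bZIP02\nMKLV*\n"
        )
        records = bz.read_fasta(path)
        assert [r.id for r in records] == ["bZIP01", "bZIP02"]
        assert records[0].description == "basic leucine zipper 1"
        assert records[0].sequence == "MNARSK"  # uppercased
        assert records[1].sequence == "MKLV"  # trailing stop stripped

    def test_unknown_letters_become_x(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">p1\nMKB1U\n")
        (rec,) = bz.read_fasta(path)
        assert rec.sequence == "MKXXX"

    def test_duplicate_ids_error_names_the_id(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">dup\nMK\n>dup\nMV\n")
        with pytest.raises(ValueError, match="dup"):
            bz.read_fasta(path)

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text("")
        with pytest.raises(ValueError):
            bz.read_fasta(path)

    def test_roundtrip_and_gzip(self, tmp_path):
        records = [
            bz.ProteinRecord("a", "MKLVNNA", "first"),
            bz.ProteinRecord("b", "MSSA"),
        ]
        plain = tmp_path / "p.fasta"
        write_fasta(records, plain)
        assert bz.read_fasta(plain) == records
        gz = tmp_path / "p.fasta.gz"
        gz.write_bytes(gzip.compress(plain.read_bytes()))
        assert bz.read_fasta(gz) == records


GFF_HEADER = "##gff-version 3\n"


def _gff(rows):
    return GFF_HEADER + "\n".join("\t".join(map(str, r)) for r in rows) + "\n"


class TestReadGff3:
    def test_single_exon_plus_strand(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(_gff([
            ("ch1", ".", "gene", 1, 300, ".", "+", ".", "ID=g1"),
            ("ch1", ".", "mRNA", 1, 300, ".", "+", ".", "ID=m1;Parent=g1;protein_id=p1"),
            ("ch1", ".", "CDS", 1, 300, ".", "+", "0", "ID=c1;Parent=m1"),
        ]))
        (model,) = bz.read_gff3(path)
        assert model.gene_id == "g1"
        assert model.protein_id == "p1"
        assert model.cds_segments == [(1, 300)]
        assert model.cds_length == 300
        assert model.length_ok

    def test_minus_strand_transcript_order(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(_gff([
            ("ch1", ".", "gene", 100, 600, ".", "-", ".", "ID=g1"),
            ("ch1", ".", "mRNA", 100, 600, ".", "-", ".", "ID=m1;Parent=g1"),
            ("ch1", ".", "CDS", 100, 219, ".", "-", "0", "ID=c1;Parent=m1"),
            ("ch1", ".", "CDS", 400, 600, ".", "-", "0", "ID=c2;Parent=m1"),
        ]))
        (model,) = bz.read_gff3(path)
        # 5'->3' of a minus-strand transcript: descending genomic coords
        assert model.cds_segments == [(400, 600), (100, 219)]
        # oracle: reversing recovers the sorted layout, total length is the sum
        assert sorted(model.cds_segments) == [(100, 219), (400, 600)]
        assert model.cds_length == 120 + 201

    def test_mrna_without_cds_excluded(self, tmp_path, caplog):
        path = tmp_path / "g.gff3"
        path.write_text(_gff([
            ("ch1", ".", "gene", 1, 90, ".", "+", ".", "ID=g1"),
            ("ch1", ".", "mRNA", 1, 90, ".", "+", ".", "ID=m1;Parent=g1"),
        ]))
        assert bz.read_gff3(path) == []

    def test_cds_without_parent_errors(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(_gff([
            ("ch1", ".", "gene", 1, 90, ".", "+", ".", "ID=g1"),
            ("ch1", ".", "mRNA", 1, 90, ".", "+", ".", "ID=m1;Parent=g1"),
            ("ch1", ".", "CDS", 1, 90, ".", "+", "0", "ID=c1"),
        ]))
        with pytest.raises(ValueError, match="Parent"):
            bz.read_gff3(path)

    def test_length_not_divisible_by_three_flagged(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(_gff([
            ("ch1", ".", "gene", 1, 100, ".", "+", ".", "ID=g1"),
            ("ch1", ".", "mRNA", 1, 100, ".", "+", ".", "ID=m1;Parent=g1"),
            ("ch1", ".", "CDS", 1, 100, ".", "+", "0", "ID=c1;Parent=m1"),
        ]))
        (model,) = bz.read_gff3(path)
        assert not model.length_ok

    def test_roundtrip_write_read(self, tmp_path):
        models = [
            bz.GeneModel("g1", "p1", "ch1", "+", [(10, 39), (100, 159)]),
            bz.GeneModel("g2", "p2", "ch2", "-", [(900, 959), (500, 532)]),
        ]
        path = tmp_path / "g.gff3"
        write_gff3(models, path)
        back = bz.read_gff3(path)
        assert {m.gene_id: m.cds_segments for m in back} == {
            "g1": [(10, 39), (100, 159)],
            "g2": [(900, 959), (500, 532)],
        }

    def test_collapse_keeps_longest_cds_per_gene(self):
        short = bz.GeneModel("g1", "p1a", "ch1", "+", [(1, 30)])
        long = bz.GeneModel("g1", "p1b", "ch1", "+", [(1, 90)])
        assert collapse_transcripts([short, long]) == [long]


def _model_from_lengths(lengths, strand="+"):
    """Lay ``lengths`` (transcript 5'->3') onto the genome with 50 bp introns."""
    genomic = lengths if strand == "+" else lengths[::-1]
    segments = []
    cursor = 1
    for length in genomic:
        segments.append((cursor, cursor + length - 1))
        cursor += length + 50
    if strand == "-":
        segments = segments[::-1]  # transcript order: descending coords
    return bz.GeneModel("g", "p", "ch1", strand, segments)


class TestIntronsFromModel:
    def test_p0_between_codons(self):
        model = _model_from_lengths([30, 60])
        (intron,) = bz.introns_from_model(model)
        assert intron.phase == "P0"
        assert intron.protein_position == 11
        assert intron.interrupted_residue is None

    def test_p2_interrupts_codon_11(self):
        protein = bz.ProteinRecord("p", "A" * 10 + "Q" + "A" * 19)
        model = _model_from_lengths([32, 58])
        (intron,) = bz.introns_from_model(model, protein)
        assert intron.phase == "P2"
        assert intron.protein_position == 11
        assert intron.interrupted_residue == "Q"

    def test_three_segments_p1_then_p0(self):
        model = _model_from_lengths([10, 20, 30])
        introns = bz.introns_from_model(model)
        assert [i.phase for i in introns] == ["P1", "P0"]
        assert [i.intron_index for i in introns] == [1, 2]

    def test_intron_count_is_segments_minus_one(self):
        for k in range(1, 6):
            model = _model_from_lengths([6] * k)
            assert len(bz.introns_from_model(model)) == k - 1

    def test_non_divisible_length_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            bz.introns_from_model(_model_from_lengths([10, 6]))

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(st.lists(st.integers(1, 60), min_size=2, max_size=8))
    def test_phase_equals_codon_walk_for_any_segmentation(self, lengths):
        lengths[-1] += (-sum(lengths)) % 3  # make the CDS translate cleanly
        model = _model_from_lengths(lengths)
        got = [(i.phase, i.protein_position) for i in bz.introns_from_model(model)]
        assert got == codon_walk_junctions(lengths)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_codon_walk_oracle_on_random_models(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            n_codons = int(rng.integers(10, 80))
            total = 3 * n_codons
            k = int(rng.integers(1, 6))
            cuts = sorted(rng.choice(range(1, total), size=k, replace=False))
            lengths = [b - a for a, b in zip([0] + list(cuts), list(cuts) + [total])]
            strand = "+" if rng.random() < 0.5 else "-"
            model = _model_from_lengths(lengths, strand)
            got = [
                (i.phase, i.protein_position)
                for i in bz.introns_from_model(model)
            ]
            assert got == codon_walk_junctions(lengths)
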