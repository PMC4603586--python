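import numpy as np
import pytest

import bzipfam as bz
from bzipfam.domain_anchor import BzipDomain
from bzipfam.family_stats import genes_in_blocks

import pandas as pd

from helpers import chain_clusters_oracle


def _profile_from_zipper(pid, zipper, pad=20):
    protein = bz.ProteinRecord(pid, "A" * pad + zipper)
    domain = BzipDomain(pid, pad - 18, pad - 10, pad, pad + len(zipper) - 1)
    return bz.build_profile(domain, protein)


class TestComposition:
    def test_asn_at_a_frequency_half(self):
        # a of heptad 2 is zipper position +12; N planted in 5 of 10 zippers
        with_n = "LASTQVY" + "LASTNVY" + "LASTQVY"
        without = "LASTQVY" * 3
        profiles = [
            _profile_from_zipper(f"p{i}", with_n if i < 5 else without)
            for i in range(10)
        ]
        table = bz.composition(profiles, "all_members")
        assert table.asn_at_a_per_heptad[2] == pytest.approx(0.5)

    def test_all_leucine_d_gives_fraction_one(self):
        profile = _profile_from_zipper("p", "LASTQVY" * 4)
        assert profile.leu_at_d_fraction == 1.0
        table = bz.composition([profile])
        assert table.register_freq["d"] == {"L": 1.0}

    def test_pair_fractions_sum_to_one_with_heptad_denominator(self):
        profiles = [
            _profile_from_zipper("p1", "LQAEAAA" + "LKAEAAA" + "LDAAAAA"),
            _profile_from_zipper("p2", "LASTQVY" * 2),
        ]
        table = bz.composition(profiles, "members_with_heptad")
        for freqs in table.pair_freq_per_heptad.values():
            total = freqs["complete"] + freqs["incomplete"] + freqs["uncharged"]
            assert total == pytest.approx(1.0)

    def test_register_frequencies_sum_to_one(self, small_family, rules):
        profiles = [
            bz.build_profile(bz.find_domain(p, rules), p)
            for p in small_family.proteins
        ]
        table = bz.composition(profiles)
        for register, freqs in table.register_freq.items():
            assert sum(freqs.values()) == pytest.approx(1.0)

    def test_members_with_heptad_never_below_all_members(self, small_family, rules):
        profiles = [
            bz.build_profile(bz.find_domain(p, rules), p)
            for p in small_family.proteins
        ]
        broad = bz.composition(profiles, "all_members")
        narrow = bz.composition(profiles, "members_with_heptad")
        for heptad, freq in broad.asn_at_a_per_heptad.items():
            assert narrow.asn_at_a_per_heptad[heptad] >= freq - 1e-12

    def test_empty_profiles_error(self):
        with pytest.raises(ValueError):
            bz.composition([])


def _gene(gid, chrom, start, end):
    return bz.GeneModel(gid, gid, chrom, "+", [(start, end)])


class TestTandemClusters:
    def test_two_adjacent_family_genes_cluster(self):
        models = [_gene("a", "ch1", 1000, 2000), _gene("b", "ch1", 5000, 6000)]
        (cluster,) = bz.detect_tandem_clusters(models, {"a", "b"})
        assert cluster.members == ("a", "b")
        assert cluster.span == (1000, 6000)

    def test_one_intervening_nonfamily_gene_allowed(self):
        models = [
            _gene("a", "ch1", 1000, 2000),
            _gene("x", "ch1", 3000, 4000),
            _gene("c", "ch1", 5000, 6000),
        ]
        (cluster,) = bz.detect_tandem_clusters(models, {"a", "c"}, max_intervening=1)
        assert cluster.members == ("a", "c")
        assert bz.detect_tandem_clusters(models, {"a", "c"}, max_intervening=0) == []

    def test_different_chromosomes_never_cluster(self):
        models = [_gene("a", "ch1", 1000, 2000), _gene("b", "ch2", 2500, 3500)]
        assert bz.detect_tandem_clusters(models, {"a", "b"}) == []

    def test_gap_rule_when_no_census(self):
        models = [_gene("a", "ch1", 1000, 2000), _gene("b", "ch1", 300_000, 301_000)]
        assert bz.detect_tandem_clusters(models, {"a", "b"}, max_gap_bp=100_000) == []
        (cluster,) = bz.detect_tandem_clusters(models, {"a", "b"}, max_gap_bp=500_000)
        assert cluster.members == ("a", "b")

    def test_unknown_family_id_errors(self):
        models = [_gene("a", "ch1", 1, 100)]
        with pytest.raises(ValueError, match="ghost"):
            bz.detect_tandem_clusters(models, {"a", "ghost"})

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_chaining_oracle_on_random_layouts(self, seed):
        rng = np.random.default_rng(seed)
        layout = []
        cursor = {c: 1000 for c in ("ch1", "ch2")}
        family = set()
        for i in range(20):
            chrom = "ch1" if rng.random() < 0.6 else "ch2"
            start = cursor[chrom] + int(rng.integers(500, 5000))
            end = start + 900
            cursor[chrom] = end
            gid = f"g{i}"
            layout.append((gid, chrom, start, end))
            if rng.random() < 0.6:
                family.add(gid)
        models = [_gene(g, c, s, e) for g, c, s, e in layout]
        clusters = bz.detect_tandem_clusters(models, family, max_intervening=1)
        got = sorted(tuple(sorted(c.members)) for c in clusters)
        assert got == chain_clusters_oracle(layout, family, max_intervening=1)

    def test_invariance_under_translation_and_relabeling(self):
        models = [
            _gene("a", "ch1", 1000, 2000),
            _gene("b", "ch1", 4000, 5000),
            _gene("c", "ch1", 400_000, 401_000),
        ]
        base = bz.detect_tandem_clusters(models, {"a", "b", "c"})
        shifted = [
            bz.GeneModel(m.gene_id, m.gene_id, m.chromosome, "+",
                         [(s + 7_000_000, e + 7_000_000) for s, e in m.cds_segments])
            for m in models
        ]
        moved = bz.detect_tandem_clusters(shifted, {"a", "b", "c"})
        assert [c.members for c in moved] == [c.members for c in base]


class TestJoinReport:
    def test_fully_annotated_proteins_give_complete_rows(self, small_family, rules):
        proteins = small_family.proteins[:3]
        profiles = {
            p.id: bz.build_profile(bz.find_domain(p, rules), p) for p in proteins
        }
        report = bz.join_report(
            [p.id for p in proteins],
            {p.id: "I" for p in proteins},
            profiles,
            {},
            {p.id: small_family.truth.proteins[p.id].gene_id for p in proteins},
        )
        assert len(report) == 3
        assert (report["group"] == "I").all()

    def test_missing_tables_marked_na_but_rows_kept(self):
        report = bz.join_report(["p1", "p2"], {"p1": "I"}, {}, {}, {})
        assert len(report) == 2
        assert report.loc[report.protein_id == "p2", "group"].item() == "NA"
        assert (report["intron_pattern"] == "NA").all()

    @pytest.mark.parametrize("n", [1, 5, 13])
    def test_row_count_equals_protein_count(self, n):
        ids = [f"p{i}" for i in range(n)]
        report = bz.join_report(ids, {}, {}, {}, {})
        assert len(report) == n


def test_genes_in_blocks_membership():
    models = [_gene("a", "ch1", 1000, 2000), _gene("b", "ch2", 1000, 2000)]
    blocks = pd.DataFrame(
        [
            {"block_id": "B1", "chrom": "ch1", "start": 500, "end": 5000},
            {"block_id": "B2", "chrom": "ch2", "start": 1500, "end": 9000},
        ]
    )
    membership = genes_in_blocks(models, blocks)
    assert membership == {"a": ["B1"], "b": []}
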