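import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

import bzipfam as bz
from bzipfam.expression_tools import pearson_distance_matrix

from helpers import ddct_oracle, naive_average_linkage_cophenetic


def _table(rows, reference="actin", calibrator="t0"):
    data = pd.DataFrame(
        [{"gene_id": g, "sample_id": s, "replicate": r, "ct": ct}
         for g, s, r, ct in rows]
    )
    return bz.CtTable(data, reference, calibrator)


class TestDdct:
    def test_textbook_fold_change(self):
        # treated: Ct(gene)=25, Ct(ref)=20; calibrator: 24/20 -> ddCt=1, fold 0.5
        table = _table([
            ("gene", "t0", 1, 24.0), ("actin", "t0", 1, 20.0),
            ("gene", "t1", 1, 25.0), ("actin", "t1", 1, 20.0),
        ], calibrator="t0")
        folds = bz.ddct(table)
        t1 = folds[(folds.gene_id == "gene") & (folds.sample_id == "t1")].iloc[0]
        assert t1.delta_delta_ct == pytest.approx(1.0)
        assert t1.fold == pytest.approx(0.5)

    def test_calibrator_fold_exactly_one_for_every_gene(self):
        rng = np.random.default_rng(0)
        rows = []
        for g in ("g1", "g2", "g3", "actin"):
            for s in ("t0", "t1", "t2"):
                for r in (1, 2, 3):
                    rows.append((g, s, r, float(rng.uniform(18, 32))))
        folds = bz.ddct(_table(rows))
        cal = folds[folds.sample_id == "t0"]
        assert (cal.fold == 1.0).all()

    def test_gene_tracking_reference_has_fold_one_everywhere(self):
        rows = []
        for s, base in (("t0", 20.0), ("t1", 23.0), ("t2", 19.0)):
            rows.append(("gene", s, 1, base + 4.0))
            rows.append(("actin", s, 1, base))
        folds = bz.ddct(_table(rows))
        assert folds.fold.values == pytest.approx(np.ones(3))

    def test_replicates_averaged_on_ct_scale(self):
        table = _table([
            ("gene", "t0", 1, 24.0), ("gene", "t0", 2, 26.0),
            ("actin", "t0", 1, 20.0),
            ("gene", "t1", 1, 26.0), ("actin", "t1", 1, 20.0),
        ])
        t1 = bz.ddct(table)
        row = t1[t1.sample_id == "t1"].iloc[0]
        assert row.delta_delta_ct == pytest.approx(1.0)  # mean(24,26)=25

    @pytest.mark.parametrize("seed", range(3))
    def test_random_tables_match_spreadsheet_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for g in [f"g{i}" for i in range(6)] + ["actin"]:
            for s in ("t0", "t1", "t2", "t3"):
                for r in (1, 2, 3):
                    rows.append((g, s, r, float(rng.uniform(16, 34))))
        folds = bz.ddct(_table(rows))
        expected = ddct_oracle(
            [(g, s, ct) for g, s, _, ct in rows], "actin", "t0"
        )
        for _, row in folds.iterrows():
            assert row.fold == pytest.approx(expected[(row.gene_id, row.sample_id)])

    def test_missing_reference_in_sample_errors_with_sample_name(self):
        data = pd.DataFrame([
            {"gene_id": "gene", "sample_id": "t0", "replicate": 1, "ct": 24.0},
            {"gene_id": "actin", "sample_id": "t0", "replicate": 1, "ct": 20.0},
            {"gene_id": "gene", "sample_id": "late", "replicate": 1, "ct": 25.0},
        ])
        with pytest.raises(ValueError, match="late"):
            bz.CtTable(data, "actin", "t0")


class TestClusterGenes:
    def test_perfectly_correlated_profiles_merge_first_at_zero(self):
        matrix = pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [5.0, 1.0, 2.0]],
            index=["a", "b", "c"], columns=["s1", "s2", "s3"],
        )
        order, linkage, _ = bz.cluster_genes(matrix)
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        first = {int(linkage[0, 0]), int(linkage[0, 1])}
        assert first == {0, 1}  # rows a and b after lexicographic sort

    def test_anticorrelated_profiles_at_distance_two(self):
        matrix = pd.DataFrame(
            [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], index=["a", "b"],
            columns=["s1", "s2", "s3"],
        )
        dist = pearson_distance_matrix(matrix)
        assert dist[0, 1] == pytest.approx(2.0)

    def test_constant_rows_at_maximum_distance(self):
        matrix = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [2.0, 1.0, 3.0]],
            index=["flat", "g1", "g2"], columns=["s1", "s2", "s3"],
        )
        dist = pearson_distance_matrix(matrix)
        assert dist[0, 1] == dist[0, 2] == 2.0

    def test_too_few_genes_or_constant_matrix_errors(self):
        one = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["s1", "s2"])
        with pytest.raises(ValueError):
            bz.cluster_genes(one)
        flat = pd.DataFrame(
            [[1.0, 1.0], [2.0, 2.0], [1.0, 3.0]],
            index=["a", "b", "c"], columns=["s1", "s2"],
        )
        with pytest.raises(ValueError, match="non-constant"):
            bz.cluster_genes(flat)

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_tree_matches_naive_agglomeration(self, seed):
        rng = np.random.default_rng(seed)
        matrix = pd.DataFrame(
            rng.normal(size=(10, 6)),
            index=[f"g{i:02d}" for i in range(10)],
            columns=[f"s{j}" for j in range(6)],
        )
        _, linkage, _ = bz.cluster_genes(matrix)
        dist = pearson_distance_matrix(matrix)
        expected = naive_average_linkage_cophenetic(dist)
        from scipy.spatial.distance import squareform

        got = squareform(hierarchy.cophenet(linkage))
        assert np.allclose(got, expected)

    def test_invariant_to_per_gene_affine_rescaling(self):
        rng = np.random.default_rng(42)
        matrix = pd.DataFrame(
            rng.normal(size=(8, 5)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"s{j}" for j in range(5)],
        )
        scaled = matrix.mul(
            pd.Series([2.0, 0.5, 3.0, 1.0, 7.0, 0.1, 4.0, 9.0], index=matrix.index),
            axis=0,
        ).add(
            pd.Series(np.arange(8.0), index=matrix.index), axis=0
        )
        o1, l1, n1 = bz.cluster_genes(matrix)
        o2, l2, n2 = bz.cluster_genes(scaled)
        assert o1 == o2
        assert np.allclose(l1, l2)
        assert n1 == n2

    def test_newick_contains_all_genes(self):
        rng = np.random.default_rng(1)
        matrix = pd.DataFrame(
            rng.normal(size=(5, 4)), index=[f"g{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(4)],
        )
        _, _, newick = bz.cluster_genes(matrix)
        assert newick.endswith(";")
        for g in matrix.index:
            assert g in newick
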