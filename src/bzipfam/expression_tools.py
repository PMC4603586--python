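"""Relative qRT-PCR expression (2^-ΔΔCt) and expression clustering.

ΔCt normalizes a gene's cycle threshold to a reference gene within a
sample; ΔΔCt subtracts the calibrator sample's ΔCt, so the calibrator's
fold change is 1 by construction.  Replicates are averaged on the Ct
scale before any differencing.

Genes are clustered on their log2 fold-change profiles by agglomerative
average linkage on the Pearson correlation distance (1 - r), the
combination classically used for expression heatmaps.  Zero-variance
profiles have no defined correlation; they are placed at the maximum
distance (2.0) from every other profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

CT_COLUMNS = ("gene_id", "sample_id", "replicate", "ct")


@dataclass
class CtTable:
    """Long-format Ct measurements plus the normalization anchors."""

    data: pd.DataFrame
    reference_gene_id: str
    calibrator_sample_id: str

    def __post_init__(self) -> None:
        missing = set(CT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns {sorted(missing)}")
        samples = set(self.data["sample_id"].unique())
        if self.calibrator_sample_id not in samples:
            raise ValueError(
                f"calibrator sample {self.calibrator_sample_id!r} absent"
            )
        ref_samples = set(
            self.data.loc[
                self.data["gene_id"] == self.reference_gene_id, "sample_id"
            ].unique()
        )
        lacking = sorted(samples - ref_samples)
        if lacking:
            raise ValueError(
                f"reference gene {self.reference_gene_id!r} missing in "
                f"samples {lacking}"
            )

    @classmethod
    def read_tsv(
        cls, path: str | Path, reference_gene_id: str, calibrator_sample_id: str
    ) -> "CtTable":
        data = pd.read_csv(path, sep="\t")
        return cls(data, reference_gene_id, calibrator_sample_id)


def ddct(table: CtTable) -> pd.DataFrame:
    """Per (gene, sample) ΔCt, ΔΔCt, fold change and log2 fold change.

    ΔCt = mean Ct(gene) - mean Ct(reference) within each sample;
    ΔΔCt = ΔCt(sample) - ΔCt(calibrator); fold = 2^-ΔΔCt.
    """
    means = (
        table.data.groupby(["gene_id", "sample_id"])["ct"].mean().unstack()
    )
    ref = means.loc[table.reference_gene_id]
    delta = means.subtract(ref, axis=1)
    delta = delta.drop(index=table.reference_gene_id)
    ddelta = delta.subtract(delta[table.calibrator_sample_id], axis=0)
    out = ddelta.stack().rename("delta_delta_ct").reset_index()
    out = out.merge(
        delta.stack().rename("delta_ct").reset_index(), on=["gene_id", "sample_id"]
    )
    out["log2_fold"] = -out["delta_delta_ct"]
    out["fold"] = 2.0 ** out["log2_fold"]
    return out[["gene_id", "sample_id", "delta_ct", "delta_delta_ct", "fold", "log2_fold"]]


def fold_matrix(folds: pd.DataFrame, value: str = "log2_fold") -> pd.DataFrame:
    """Pivot the ddct output into a genes x samples matrix."""
    return folds.pivot(index="gene_id", columns="sample_id", values=value)


def pearson_distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Pairwise 1 - Pearson correlation; constant rows sit at distance 2."""
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    sd = values.std(axis=1)
    constant = sd == 0
    dist = np.full((n, n), 2.0)
    np.fill_diagonal(dist, 0.0)
    ok = ~constant
    if ok.sum() >= 2:
        corr = np.corrcoef(values[ok])
        idx = np.where(ok)[0]
        dist[np.ix_(idx, idx)] = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
    # numerical guard: corrcoef can drift a hair outside [-1, 1]
    return np.clip(dist, 0.0, 2.0)


def cluster_genes(
    matrix: pd.DataFrame,
) -> tuple[list[str], np.ndarray, str]:
    """Average-linkage clustering of gene profiles on Pearson distance.

    Rows are sorted by gene id before clustering so tie-breaking is
    lexicographic and the result deterministic.  Returns (leaf order,
    scipy linkage matrix, newick string with merge heights).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    matrix = matrix.sort_index()
    values = matrix.to_numpy(dtype=float)
    non_constant = (values.std(axis=1) > 0).sum()
    if non_constant < 2:
        raise ValueError("need at least 2 non-constant gene profiles")
    dist = pearson_distance_matrix(matrix)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [matrix.index[i] for i in hierarchy.leaves_list(linkage)]
    newick = _to_newick(linkage, list(matrix.index))
    return order, linkage, newick


def _to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
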