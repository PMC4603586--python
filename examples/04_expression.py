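"""2^-ΔΔCt relative expression and expression-profile clustering.

Builds a small qRT-PCR Ct table (three replicates per gene and sample,
normalized to an actin reference, calibrated on the untreated sample),
computes fold changes and clusters the genes on their log2 profiles.
"""

import pandas as pd

import bzipfam as bz
from bzipfam.synthetic_data import CT_CALIBRATOR, CT_REFERENCE

family = bz.generate_family(bz.default_spec(10, seed=8))
table = bz.CtTable(family.ct_table, CT_REFERENCE, CT_CALIBRATOR)

folds = bz.ddct(table)
print("fold changes (first gene):")
first = folds[folds.gene_id == folds.gene_id.iloc[0]]
print(first.round(3).to_string(index=False))

matrix = bz.fold_matrix(folds)  # genes x samples, log2 scale
order, linkage, newick = bz.cluster_genes(matrix)
print("\nleaf order after Pearson-distance average-linkage clustering:")
print(" ".join(order))
print("\nmerge tree:", newick)

# The calibrator sample's fold is exactly 1 by construction; a fold of
# 0.5 means one ΔΔCt cycle less template than the calibrator.  Genes
# adjacent in the leaf order have the most similar (correlation-wise)
# expression profiles, as in a clustered heatmap.
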