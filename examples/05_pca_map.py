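"""Project a featurized ligand pool onto its 2-component PCA map.

The map places ligands of the same backbone family near each other; its
stored loadings let new candidates be embedded into the same coordinates
later (for, e.g., coloring by EI score).
"""

from chelate import FeatureTable, featurize_ligand, pca_map
from chelate.electronics import ElectronicRecord
from chelate.synth import make_ligand_pool

pool = make_ligand_pool(30, seed=8)
table = FeatureTable.from_vectors({
    s.ligand_id: featurize_ligand(s, bo, ElectronicRecord(s.ligand_id, el))
    for s, bo, el in pool
})
pm = pca_map(table)
print(f"kept {len(pm.columns)} non-constant features; explained variance "
      f"PC1={pm.explained_variance_ratio[0]:.1%} PC2={pm.explained_variance_ratio[1]:.1%}")
for backbone in ("en", "pn", "chxn", "bipy", "dad"):
    rows = pm.scores[[i.startswith(backbone + "_") for i in pm.scores.index]]
    if len(rows):
        print(f"  {backbone:5s} family centroid: PC1={rows['PC1'].mean():+7.2f} "
              f"PC2={rows['PC2'].mean():+7.2f}  ({len(rows)} ligands)")
# Distinct family centroids show the 232 descriptors organize ligand space
# chemically, the prerequisite for transferring models across families.
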