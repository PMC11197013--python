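"""Select and fit a sparse BRR model of enantioselectivity.

Featurizes a 25-ligand synthetic pool, plants a known 2-feature linear
relationship for ddG (converted to/from enantiomeric excess through the
Eyring relation) and runs capped forward selection over all 232 features.
The top models recover the planted steric + topological signal — note
that with strongly correlated descriptors (an octant vs the quadrant that
contains it) the selected feature may be a near-proxy of the planted one,
which is exactly how such models behave on real screening data.
"""

from chelate import FeatureTable, featurize_ligand, forward_select
from chelate.electronics import ElectronicRecord
from chelate.synth import SyntheticLigandSpec, SyntheticScreenSpec, make_ligand_pool, make_screen

pool = make_ligand_pool(25, seed=11)
table = FeatureTable.from_vectors({
    s.ligand_id: featurize_ligand(s, bo, ElectronicRecord(s.ligand_id, el))
    for s, bo, el in pool
})

spec = SyntheticScreenSpec(
    planted_features=("vbur_Q4_px_ny", "kappa2a_norm"),
    weights=(1.0, -0.6),      # kcal/mol per standardized unit
    noise_sd=0.1,             # kcal/mol of experimental scatter
    seed=2,
)
records, truth = make_screen(spec, table)
print(f"screen of {len(records)} ligands, ee in "
      f"[{records['ee'].min():+.3f}, {records['ee'].max():+.3f}]")

best = forward_select(table, records["ddg"].to_numpy(), top_k=3)
for rank, rep in enumerate(best, 1):
    print(f"#{rank}: {rep.features}  adjR2_LOO={rep.r2_adj_loo:.3f} "
          f"MAE_LOO={rep.mae_loo:.3f} kcal/mol")
top = best[0]
print("normalized weights:", dict(zip(top.features, top.normalized_weights.round(3))))
# adjR2_LOO near 1 and MAE_LOO near the planted 0.1 kcal/mol noise floor
# indicate the pipeline found the planted relationship, not an artifact.
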