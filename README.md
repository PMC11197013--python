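# chelate

Featurization, sparse Bayesian modeling and pool-based Bayesian
optimization of **bidentate ligands** for enantioselective catalysis.

Choosing the ligand is often the decisive step in developing an
asymmetric metal-catalyzed reaction, and screening campaigns are slow and
expensive. `chelate` is for computational and experimental chemists who
want to (1) describe any bidentate ligand with a fixed, reaction-agnostic
descriptor vector, (2) fit small interpretable models of
enantioselectivity from the handful of results a real campaign produces,
and (3) let those models decide which ligand to try next.

## What it computes

**Featurization.** Each ligand (XYZ or SDF geometry, with the two donor
atoms found from a bound metal or an annotation) is placed in a canonical
frame — donors on the x axis, the sterically smaller half at x < 0 — and
described by exactly **232 features** in three categories:

- *steric*: total and buried volumes (Bondi radii × 1.17; 3.5 Å probe
  sphere) split into halves, quadrants and octants, with/without
  hydrogens, plus normalized, fractional and mirror-asymmetry variants;
- *topological*: Wiener, Hosoya *Z*, Balaban *J*, Kier–Hall ⁰χ–⁵χ (simple
  and valence), ¹κ–³κ (plain and α-modified), path counts, a
  rotatable-bond flexibility index, and explicit-bond-order summaries on
  the covalent-radius molecular graph;
- *electronic*: ingested donor lone-pair energies and partial charges,
  resolved by steric half.

**Modeling.** Enantiomeric excesses become free-energy differences via the
Eyring relation, ΔΔG‡ = RT ln((1+ee)/(1−ee)). Models are Bayesian ridge
regressions (evidence-maximized prior/noise precisions, predictive μ ± σ)
over at most **three features**, found by beam forward selection and
ranked by the adjusted R² of pooled leave-one-out predictions.

**Screening.** Pool-based Bayesian optimization acquires the untested
ligand with the highest expected improvement,
EI = (μ−μ⁺)Φ(z) + σφ(z), z = (μ−μ⁺)/σ, refitting the whole selection
pipeline after every acquisition, until no ligand promises improvement.
A replay mode benchmarks BO against a historical screening order.

See `docs/methods.md` for conventions, numerical choices and limitations.

## Worked example

`examples/` holds one narrative script per capability. Featurizing a
synthetic ethylenediamine ligand with one *tert*-butyl arm
(`python examples/01_featurize_a_ligand.py`):

```
ligand en_h_tbu_s1: 232 features
  vol_total                =   179.5600  [steric]
  vbur_Q4_px_ny            =    37.9985  [steric]
  asym_vol_neg_pos         =   -84.0720  [steric]
  wiener_hs                =    71.0000  [topological]
  kappa2a_norm             =     0.3759  [topological]
  flexibility              =     0.4286  [topological]
  lp_energy_smaller_half   =    -0.4487  [electronic]
```

The negative half-volume asymmetry (−84 Å³) confirms the bare arm sits in
the smaller x < 0 half and the *tert*-butyl arm at x > 0; 38.0% of the
south-east quadrant of the probe sphere is buried by the ligand.

Screening a 40-ligand pool with a planted selectivity truth
(`python examples/03_screen_with_bo.py`):

```
initial batch: {'en_ph_tbu_s4': 1.99, 'bipy_ipr_ipr_s4': 3.03, 'en_h_me_s4': -0.49}
best ligand in pool: chxn_et_tbu_s4 (ddG=4.20 kcal/mol)
 step 1: bipy_ph_ph_s4      mu=+4.44 sigma=0.00 EI=1.412 observed=+1.21
 step 2: bipy_et_ph_s4      mu=+4.21 sigma=0.00 EI=1.183 observed=+4.15
 step 3: chxn_et_tbu_s4     mu=+4.31 sigma=0.00 EI=0.167 observed=+4.20  <-- optimum
stopped: converged after 3 acquisitions (pool of 40)
```

Starting from three random observations, EI-guided acquisition reaches the
best of 40 ligands in three experiments and then stops, because no
remaining candidate promises improvement.

The same workflow is exposed as a thin CLI
(`chelate fixtures | featurize | fit | screen`), e.g.

```bash
chelate fixtures --out fix/ --n 12 --seed 0
chelate featurize --structures fix/ --donors fix/donors.tsv \
    --bond-orders fix/bond_orders.tsv --electronic fix/electronic.tsv \
    --out features.tsv
chelate fit --features features.tsv --screen results.csv --out model.json
```

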