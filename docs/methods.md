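# Methods

`chelate` models the enantioselectivity imparted by bidentate ligands in
asymmetric catalysis from structure-derived descriptors, and uses the
fitted models to decide which ligand to test next. This note documents the
science and the numerical choices; the README covers installation and a
worked example.

## Scope and assumptions

The unit of description is the free (metal-stripped) ligand binding a metal
through two donor atoms. Substrate and reaction-condition effects are not
modeled: a model is fitted per reaction dataset, with the ligand as the only
variable. Electronic-structure quantities (donor lone-pair orbital energies,
donor partial charges) are **ingested** from an external quantum-chemistry
workflow via a sidecar table; the package never runs quantum chemistry.
Bond orders, likewise, must be supplied explicitly (a convenience reader
extracts them from SDF bond blocks); no feature silently derives bond
orders from geometry.

## Canonical alignment

All steric features require one reproducible frame per ligand:

1. the donor–donor midpoint is translated to the origin and the donor axis
   rotated onto x, with the lower-index donor initially at −x;
2. the ligand spins about x until the component of the heavy-atom centroid
   orthogonal to x points along +z (for centroids collinear with the donor
   axis, the fallback is the principal axis of inertia orthogonal to x);
3. the structure is reflected through the yz plane if needed so that the
   half with the smaller **hydrogen-free** volume lies at x < 0. Ties
   (within 0.1% of the total) keep the lower-index donor at −x.

The transform is distance-preserving, and aligning an aligned ligand is the
identity to 1e-8 Å. Half/quadrant/octant labels then follow coordinate
signs: Q1 (+x,+y) NE, Q2 (−x,+y) NW, Q3 (−x,−y) SW, Q4 (+x,−y) SE; octants
1–4 are the quadrants at z > 0 and 5–8 the same at z < 0 (feature names
carry the sign pattern, e.g. `vbur_O8_px_ny_nz`, so the numbering is purely
internal).

## Descriptors (the 232-entry registry)

The registry (`chelate.features.registry()`, version 1.0) is the single
source of truth consulted by the library, the CLI and the tests. Entries
carry a category, an extensivity flag and, for normalized variants, the
base entry they divide by the heavy-atom count (making an extensive
quantity intensive).

**Steric (146).** Union volumes of Bondi vdW spheres scaled by 1.17,
integrated on a cubic grid (default spacing 0.1 Å), and buried-volume
percentages inside a 3.5 Å probe sphere centered at the recorded metal
position (or, for metal-free inputs, 2.1 Å down the −z axis from the donor
midpoint — the metal side of the frame). Both are resolved over the total,
2 halves, 4 quadrants and 8 octants, with and without hydrogens; volumes
additionally get normalized variants, sector fractions of the total, and
mirror (−x minus +x) asymmetries of the 7 sector pairs. The grid is
cell-centered and symmetric about the coordinate planes, so no point lies
on a sector boundary, octants sum to the total exactly, and mirror images
swap sector values exactly on the same grid. Grid integration is the
canonical (deterministic) evaluator; Monte-Carlo integration appears only
as an independent oracle in tests. Halving the spacing moves volumes by
less than 1% for molecular-sized spheres.

**Topological (74).** Wiener, Hosoya Z and Balaban J on both the full and
hydrogen-suppressed graphs; Kier–Hall connectivity χ (orders 0–5, simple
and valence) and shape κ (orders 1–3, plain and α-modified) on the
hydrogen-suppressed graph; simple-path counts P1–P6; the cyclomatic
number; a flexibility index; explicit-bond-order summaries (global
sum/mean/max/min and donor-local sums/means with their combinations); atom
counts; plus normalized variants of the extensive entries. Conventions:
the valence delta is (Zv−h)/(Z−Zv−1); κ³ uses the published alternate
numerator for even heavy-atom counts; α = Σ(r_cov/r(Csp3) − 1) over heavy
atoms from the Cordero radius table (elements missing from the table
contribute 0 with a warning). The molecular graph itself comes from
covalent-radius bond perception: edge (i,j) iff d(i,j) ≤ 1.15 × (r_i+r_j),
the scale factor being configurable in [1.0, 1.4].

The flexibility index is this package's own bond-rotatability score:
terminal heavy-heavy bonds contribute 0, π character attenuates a bond's
contribution linearly to 0 at bond order 2, ring bonds are damped by 0.3,
and the score is the mean over heavy-heavy bonds — rigid fused-ring systems
score below equally sized chains, and branched isomers below their linear
counterparts.

**Electronic (12).** Donor lone-pair energies (hartree; eV inputs are
converted) and partial charges (e), resolved by steric half — the donor in
the smaller (−x) half supplies the `smaller_half` entries, reusing the
alignment's half assignment as the single source of truth — plus absolute
difference, mean, min and max per property.

A full supplementary enumeration of the original 232-descriptor list was
not available when this registry was fixed; the registry keeps every
published descriptor family and figure-level feature name and fills the
count with the systematic families above. The count, names and tags are
frozen under `REGISTRY_VERSION` and asserted at import time.

## Enantioselectivity scale

Measured enantiomeric excesses are converted to activation free-energy
differences between the diastereomeric transition states,
ΔΔG‡ = RT ln((1+ee)/(1−ee)) with R = 1.98720425×10⁻³ kcal·mol⁻¹·K⁻¹, and
models are fitted on the ΔΔG‡ scale (kcal/mol); the inverse map is
ee = tanh(ΔΔG‡/2RT). Higher ΔΔG‡ is better throughout.

## Regression and model selection

The regression model is Bayesian ridge: standardized predictors, a
zero-mean isotropic Gaussian prior N(0, α⁻¹) on the weights, Gaussian
noise of precision β and an unpenalized intercept. α and β are set by
evidence (type-II likelihood) maximization with MacKay fixed-point
updates, relative tolerance 1e-6 on both precisions and at most 300
iterations; the updates are geometrically damped (the damped iteration has
the same fixed point but suppresses a period-2 oscillation that the raw
updates exhibit on irrelevant-predictor problems). With both precisions
frozen the posterior mean equals the ridge closed form, which the tests
check against direct linear algebra. Predictions carry
σ² = β⁻¹ + zᵀSz with S the weight posterior covariance (the intercept is
treated as fixed, as is conventional; its neglected variance is one reason
1σ coverage runs a few points below the nominal 68% at n ≈ 20–30).

Model complexity is capped at three features. Forward selection scores
every single feature, then extends the top-10 (configurable beam)
survivors by one unseen feature per stage; candidates of every size are
retained and the final ranking is by the adjusted R² of pooled
leave-one-out predictions, with ties broken by fewer features, lower LOO
MAE, then name order. A feature correlated above |r| = 0.999 with an
already-selected one is never added. Standardization is refit inside every
LOO fold (no leakage); the per-fold refits are exact but vectorized —
fold moments come from rank-one downdates of the full-data moments and the
evidence iterations run batched over folds and candidates.

Because supersets of a true feature pair are retained in the ranking, the
top model on noisy data may carry a genuinely LOO-improving third feature
(with a small normalized weight); on noise-free data the exact planted
subset wins. This is a property of LOO-ranked selection over many
correlated candidates, not an implementation artifact, and the tests
encode it accordingly.

## Screening by expected improvement

Pool-based Bayesian optimization treats the fitted model's prediction for
each untested ligand as Gaussian and acquires the argmax of
EI = (μ−μ⁺)Φ(z) + σφ(z), z = (μ−μ⁺)/σ (EI = max(μ−μ⁺, 0) at σ = 0),
where μ⁺ is the best observed ΔΔG‡ so far. Ties go to higher μ, then
ligand id. By default the **entire** selection pipeline (forward selection
+ BRR) is refitted after every acquisition; a mode that freezes the
initially selected features and refits only weights is available. The loop
starts from at least three observed ligands; while n < 6 the model size is
capped at n−2 so the small-sample refits stay well-posed.

Stopping: the default rule stops when the maximum EI over untested ligands
falls below 1e-6 (the truncation used when reporting EI scores); the
literal alternative — below the smallest EI at which any acquisition was
made — is available as `stop_mode="below_seen"`. Known limitation: at
n = 4–6 an almost-exact fit can drive the evidence-maximized β very high,
collapsing σ and triggering the EI stop prematurely; acquisition-efficiency
studies therefore run with `stop_epsilon=0` and an explicit step budget,
and users screening from very small seeds should do the same.

## Synthetic data

The generator stands in for DFT-optimized ligand sets and experimental
screens so the whole pipeline is testable offline. Ligand geometries come
from seeded ETKDG embedding plus MMFF relaxation of template SMILES — five
N,N-donor backbones (ethylenediamine, 1,3-propanediamine,
cyclohexane-1,2-diamine, 2,2'-bipyridine, 1,4-diaza-1,3-diene) decorated
with arms of graded bulk (H, Me, Et, iPr, tBu, Ph). These are idealized
force-field conformers, not stationary points of any quantum method: they
provide genuine steric/topological variation but no conformer ensembles,
no counterions and only approximate symmetry (a "symmetric" spec embeds to
slightly unequal halves). Electronic sidecar values are drawn from seeded
normal distributions around chemically plausible magnitudes
(lp ≈ −0.45 hartree, q ≈ −0.56 e) with mild arm-bulk and aromaticity
shifts — trends, not physics. Every generator is a pure function of its
seed.

Synthetic screens plant a linear truth in chosen registry features,
ΔΔG‡ = b₀ + Σwₖzₖ + N(0, σ) with σ = 0.1 kcal/mol by default (a realistic
experimental scatter), at 298.15 K, sized like real campaigns (n ≈ 19–30,
pools of ~60). Recovery and screening studies in the tests and the
acceptance script use these sizes with 50–100 replicates; the BO studies
restrict the candidate features to a fixed 16-descriptor subset spanning
all three categories so that a full study completes in minutes on one
core. Consequently, passing tests demonstrate that the pipeline recovers
planted structure–selectivity relationships and screens efficiently under
these idealized conditions; they do not validate DFT-level descriptors or
any particular reaction chemistry.

## Degenerate inputs and tie-breaks

Disconnected metal-free graphs are an error (components listed); Balaban J
is undefined for disconnected or edgeless graphs; χ rejects zero or
negative deltas; κ orders need at least m+1 heavy atoms and a nonzero path
count; Hosoya Z guards exact counting at 64 edges. Boundary grid points
cannot occur (half-offset lattice); sector ties in alignment and EI ties
in acquisition break deterministically as described above, so every
pipeline output is bit-reproducible for a fixed seed.
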