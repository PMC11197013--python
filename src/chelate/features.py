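"""The 232-entry bidentate-ligand feature vector and its registry.

The registry is the single source of truth for the feature list: name,
category (electronic / steric / topological), extensivity and whether the
entry is a normalized variant (an extensive base feature divided by the
heavy-atom count, which makes it intensive).  Docs, CLI output and tests
all consult this registry; its length is exactly 232 for every ligand.

Families
--------
steric (146)
    union volumes and buried-volume percentages of the aligned ligand for
    the total, the two halves, four quadrants and eight octants, each with
    and without hydrogens; normalized volume variants; sector fractions of
    the total volume; and mirror (x<0 minus x>0) asymmetries of paired
    sectors.
topological (74)
    Wiener, Hosoya Z and Balaban J on the full and hydrogen-suppressed
    graphs; Kier-Hall chi (orders 0-5, simple and valence) and kappa
    (orders 1-3, plain and alpha-modified); simple-path counts P1-P6;
    cyclomatic number; the flexibility index; explicit-bond-order
    summaries (global and donor-local); atom counts; plus normalized
    variants of the extensive entries.
electronic (12)
    donor lone-pair energies and partial charges resolved by steric half
    (smaller/larger), their absolute difference, mean, min and max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import sterics, topology
from .electronics import ElectronicRecord, derive_electronic_features
from .structures import (
    LigandStructure,
    MolecularGraph,
    align_ligand,
    perceive_bonds,
    smaller_half_donor,
)

__all__ = [
    "REGISTRY_VERSION",
    "registry",
    "feature_names",
    "build_feature_vector",
    "featurize_ligand",
    "FeatureTable",
    "pca_map",
    "PCAMap",
]

REGISTRY_VERSION = "1.0"

_REGIONS = ("total",) + sterics.HALF_LABELS + sterics.QUADRANT_LABELS + sterics.OCTANT_LABELS
#: mirror pairs (x<0 sector, x>0 sector) for the asymmetry features
_MIRROR_PAIRS = (
    ("neg_x", "pos_x"),
    ("Q2_nx_py", "Q1_px_py"),
    ("Q3_nx_ny", "Q4_px_ny"),
    ("O2_nx_py_pz", "O1_px_py_pz"),
    ("O3_nx_ny_pz", "O4_px_ny_pz"),
    ("O6_nx_py_nz", "O5_px_py_nz"),
    ("O7_nx_ny_nz", "O8_px_ny_nz"),
)


def _build_registry() -> pd.DataFrame:
    rows: list[tuple[str, str, bool, bool, str | None]] = []

    def add(name, category, extensive=False, normalized=False, base=None):
        rows.append((name, category, extensive, normalized, base))

    def add_with_norm(name, category):
        add(name, category, extensive=True)
        add(name + "_norm", category, normalized=True, base=name)

    # --- steric -----------------------------------------------------------
    for h_tag in ("", "_noH"):
        for region in _REGIONS:
            add_with_norm(f"vol_{region}{h_tag}", "steric")
        for region in _REGIONS:
            add(f"vbur_{region}{h_tag}", "steric")
        for region in _REGIONS[1:]:
            add(f"frac_{region}{h_tag}", "steric")
        for neg, pos in _MIRROR_PAIRS:
            add(f"asym_vol_{neg.split('_')[0]}_{pos.split('_')[0]}{h_tag}", "steric",
                extensive=True)
            add(f"asym_vbur_{neg.split('_')[0]}_{pos.split('_')[0]}{h_tag}", "steric")

    # --- topological ------------------------------------------------------
    for g_tag in ("full", "hs"):
        add_with_norm(f"wiener_{g_tag}", "topological")
        add_with_norm(f"hosoya_{g_tag}", "topological")
        add(f"balaban_{g_tag}", "topological")
    for m in range(6):
        add_with_norm(f"chi{m}", "topological")
        add_with_norm(f"chi{m}v", "topological")
    for m in (1, 2, 3):
        add_with_norm(f"kappa{m}", "topological")
        add_with_norm(f"kappa{m}a", "topological")
    for m in range(1, 7):
        add_with_norm(f"npath_{m}", "topological")
    add_with_norm("cyclomatic", "topological")
    add("flexibility", "topological")
    add("bo_global_sum", "topological", extensive=True)
    add("bo_global_sum_norm", "topological", normalized=True, base="bo_global_sum")
    for nm in ("bo_global_mean", "bo_global_max", "bo_global_min"):
        add(nm, "topological")
    for nm in ("bo_donor_smaller_sum", "bo_donor_smaller_mean",
               "bo_donor_larger_sum", "bo_donor_larger_mean",
               "bo_donor_abs_diff", "bo_donor_mean"):
        add(nm, "topological")
    add("n_heavy", "topological", extensive=True)
    add("n_atoms", "topological", extensive=True)

    # --- electronic -------------------------------------------------------
    for prop in ("lp_energy", "charge"):
        for stat in ("smaller_half", "larger_half", "abs_diff", "mean", "min", "max"):
            add(f"{prop}_{stat}", "electronic")

    df = pd.DataFrame(rows, columns=["name", "category", "extensive", "normalized", "base"])
    if df["name"].duplicated().any():
        raise RuntimeError("duplicate feature names in registry")
    if len(df) != 232:
        raise RuntimeError(f"registry has {len(df)} entries, expected 232")
    return df.set_index("name", drop=False)


_REGISTRY = _build_registry()


def registry() -> pd.DataFrame:
    """The versioned 232-entry feature registry (copy)."""
    return _REGISTRY.copy()


def feature_names() -> list[str]:
    return list(_REGISTRY["name"])


def write_registry(path: str | Path) -> None:
    """Write the machine-readable registry with its version."""
    with open(path, "w") as fh:
        fh.write(f"# chelate feature registry version {REGISTRY_VERSION}\n")
        _REGISTRY.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# assembly


def build_feature_vector(
    aligned: LigandStructure,
    graph: MolecularGraph,
    steric: sterics.StericDescriptorSet,
    electronic: ElectronicRecord,
) -> pd.Series:
    """Assemble the 232-entry vector from precomputed descriptor sets."""
    vals: dict[str, float] = {}
    n_heavy = len(aligned.heavy_atom_indices())

    # steric
    for include_h, h_tag in ((True, ""), (False, "_noH")):
        vol = steric.volume[include_h]
        bur = steric.buried[include_h]
        flat_v = {"total": vol.total, **vol.halves, **vol.quadrants, **vol.octants}
        flat_b = {"total": bur.total, **bur.halves, **bur.quadrants, **bur.octants}
        for region in _REGIONS:
            vals[f"vol_{region}{h_tag}"] = flat_v[region]
            vals[f"vbur_{region}{h_tag}"] = flat_b[region]
        for region in _REGIONS[1:]:
            vals[f"frac_{region}{h_tag}"] = (
                flat_v[region] / flat_v["total"] if flat_v["total"] > 0 else 0.0
            )
        for neg, pos in _MIRROR_PAIRS:
            tag = f"{neg.split('_')[0]}_{pos.split('_')[0]}{h_tag}"
            vals[f"asym_vol_{tag}"] = flat_v[neg] - flat_v[pos]
            vals[f"asym_vbur_{tag}"] = flat_b[neg] - flat_b[pos]

    # topological
    for g_tag, hs in (("full", False), ("hs", True)):
        vals[f"wiener_{g_tag}"] = float(topology.wiener_index(graph, hydrogen_suppressed=hs))
        vals[f"hosoya_{g_tag}"] = float(topology.hosoya_z(graph, hydrogen_suppressed=hs))
        vals[f"balaban_{g_tag}"] = topology.balaban_j(graph, hydrogen_suppressed=hs)
    for m in range(6):
        vals[f"chi{m}"] = topology.chi_index(graph, m, valence=False)
        vals[f"chi{m}v"] = topology.chi_index(graph, m, valence=True)
    for m in (1, 2, 3):
        vals[f"kappa{m}"] = topology.kappa_index(graph, m, alpha=False)
        vals[f"kappa{m}a"] = topology.kappa_index(graph, m, alpha=True)
    for m in range(1, 7):
        vals[f"npath_{m}"] = float(topology.path_count(graph, m))
    hsg = graph.hydrogen_suppressed
    vals["cyclomatic"] = float(hsg.number_of_edges() - hsg.number_of_nodes() + 1)
    vals["flexibility"] = topology.flexibility_index(graph)

    small = smaller_half_donor(aligned)
    da, db = aligned.donor_indices
    large = db if small == da else da
    bo = topology.simple_bond_indices(graph, donors=(small, large))
    vals["bo_global_sum"] = bo["bo_global_sum"]
    vals["bo_global_mean"] = bo["bo_global_mean"]
    vals["bo_global_max"] = bo["bo_global_max"]
    vals["bo_global_min"] = bo["bo_global_min"]
    vals["bo_donor_smaller_sum"] = bo["bo_donor_a_sum"]
    vals["bo_donor_smaller_mean"] = bo["bo_donor_a_mean"]
    vals["bo_donor_larger_sum"] = bo["bo_donor_b_sum"]
    vals["bo_donor_larger_mean"] = bo["bo_donor_b_mean"]
    vals["bo_donor_abs_diff"] = abs(bo["bo_donor_a_mean"] - bo["bo_donor_b_mean"])
    vals["bo_donor_mean"] = 0.5 * (bo["bo_donor_a_mean"] + bo["bo_donor_b_mean"])
    vals["n_heavy"] = float(n_heavy)
    vals["n_atoms"] = float(len(aligned.ligand_atom_indices()))

    # electronic
    vals.update(derive_electronic_features(electronic, aligned))

    # normalized variants
    for name, row in _REGISTRY.iterrows():
        if row["normalized"]:
            vals[name] = vals[row["base"]] / n_heavy

    out = pd.Series([vals[n] for n in _REGISTRY["name"]], index=list(_REGISTRY["name"]), dtype=float)
    bad = out.index[~np.isfinite(out.to_numpy())]
    if len(bad):
        raise ValueError(f"{aligned.ligand_id}: non-finite feature values: {list(bad)}")
    return out


def featurize_ligand(
    structure: LigandStructure,
    bond_orders: dict[frozenset, float],
    electronic: ElectronicRecord,
    donors: tuple[int, int] | None = None,
    tolerance: float = 1.15,
    radii_scale: float = sterics.RADII_SCALE,
    spacing: float = sterics.GRID_SPACING,
    sphere_radius: float = sterics.SPHERE_RADIUS,
) -> pd.Series:
    """Full featurization pipeline for one ligand.

    Perceives bonds, aligns the ligand into the canonical frame, computes
    all steric / topological / electronic descriptors and assembles the
    232-entry vector.
    """
    aligned = align_ligand(structure, donors=donors)
    graph = perceive_bonds(aligned, tolerance=tolerance, bond_orders=bond_orders)
    steric = sterics.steric_descriptor_set(
        aligned, radii_scale=radii_scale, spacing=spacing, sphere_radius=sphere_radius
    )
    return build_feature_vector(aligned, graph, steric, electronic)


# ---------------------------------------------------------------------------
# tables and the PCA map


@dataclass
class FeatureTable:
    """Ligands x features matrix with standardization bookkeeping."""

    frame: pd.DataFrame

    def __post_init__(self):
        if self.frame.isna().any().any():
            missing = self.frame.columns[self.frame.isna().any()].tolist()
            raise ValueError(f"feature table has missing values in {missing}")

    @classmethod
    def from_vectors(cls, vectors: dict[str, pd.Series]) -> "FeatureTable":
        return cls(pd.DataFrame(vectors).T)

    @property
    def ligand_ids(self) -> list[str]:
        return list(self.frame.index)

    def standardized(self) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
        """(Z, mean, std) with constant columns left centered but unscaled."""
        mean = self.frame.mean(axis=0)
        std = self.frame.std(axis=0, ddof=0)
        safe = std.replace(0.0, 1.0)
        return (self.frame - mean) / safe, mean, std

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# chelate feature table, registry version {REGISTRY_VERSION}\n")
            self.frame.to_csv(fh, sep="\t", index_label="ligand_id")

    @classmethod
    def read(cls, path: str | Path) -> "FeatureTable":
        return cls(pd.read_csv(path, sep="\t", comment="#", index_col="ligand_id"))


@dataclass
class PCAMap:
    """A fitted 2-component PCA of standardized features.

    Stores the column subset, means, stds and loadings so new ligands can be
    embedded into the same map later.
    """

    columns: list[str]
    mean: pd.Series
    std: pd.Series
    components: np.ndarray  # (2, n_kept)
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame

    def transform(self, vectors: pd.DataFrame) -> pd.DataFrame:
        z = (vectors[self.columns] - self.mean) / self.std
        proj = z.to_numpy() @ self.components.T
        return pd.DataFrame(proj, index=vectors.index, columns=["PC1", "PC2"])


def pca_map(table: FeatureTable, n_components: int = 2) -> PCAMap:
    """Project the standardized feature table onto its top variance directions."""
    from sklearn.decomposition import PCA

    if len(table.frame) < 3:
        raise ValueError("PCA map needs at least 3 ligands")
    std = table.frame.std(axis=0, ddof=0)
    keep = std[std > 0].index.tolist()
    dropped = [c for c in table.frame.columns if c not in keep]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant feature columns from PCA")
    sub = table.frame[keep]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    z = (sub - mean) / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    return PCAMap(
        columns=keep,
        mean=mean,
        std=sd,
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=pd.DataFrame(scores, index=table.frame.index, columns=["PC1", "PC2"]),
    )
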