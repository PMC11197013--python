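"""Synthetic bidentate ligands, sidecars and screening datasets.

Everything here is a pure function of its seed and stands in for the
DFT-optimized structures, NBO-derived electronic values and experimental
screening tables a real campaign would provide.  Geometries come from
seeded ETKDG embedding (plus a deterministic MMFF relaxation) of template
SMILES — idealized, not quantum-refined, but with genuine steric and
topological variation across backbones and arm substituents.  Electronic
sidecar values are drawn from seeded distributions with a mild dependence
on arm bulk, mimicking donor-atom trends without any quantum chemistry.

Backbones (all N,N-donors): ``en`` (ethylenediamine-like, sp3),
``pn`` (1,3-propanediamine), ``chxn`` (trans-cyclohexane-1,2-diamine-like),
``bipy`` (2,2'-bipyridine-like, aromatic), ``dad`` (1,4-diaza-1,3-diene).
Arms decorate the donor-adjacent positions: ``h``, ``me``, ``et``, ``ipr``,
``tbu``, ``ph``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .modeling import ddg_to_ee, ee_to_ddg
from .structures import LigandStructure

__all__ = [
    "SyntheticLigandSpec",
    "SyntheticScreenSpec",
    "make_ligand",
    "make_ligand_pool",
    "make_screen",
    "write_fixture_set",
    "BACKBONES",
    "ARMS",
]

#: SMILES templates; {a}/{b} are the two arm attachment points
BACKBONES = {
    "en": "{a}NCCN{b}",
    "pn": "{a}NCCCN{b}",
    "chxn": "{a}NC1CCCCC1N{b}",
    "bipy": "{a_ar}c1cccc(n1)-c1cccc({b_ar})n1",
    "dad": "{a}N=CC=N{b}",
}

#: arm fragments as (prefix SMILES, suffix SMILES, bulk score); prefix forms
#: attach through their last atom, suffix forms through their first, so the
#: same chemical group lands on both sides of a symmetric spec
ARMS = {
    "h": ("", "", 0.0),
    "me": ("C", "C", 1.0),
    "et": ("CC", "CC", 1.5),
    "ipr": ("CC(C)", "C(C)C", 2.0),
    "tbu": ("CC(C)(C)", "C(C)(C)C", 3.0),
    # ring digit 3 avoids clashing with still-open template rings
    "ph": ("c3ccccc3", "c3ccccc3", 2.2),
}

_AR_H_FIX = {"bipy"}  # aromatic templates need [H] spelled out for bare arms

METAL_DONOR_DISTANCE = 2.05


@dataclass(frozen=True)
class SyntheticLigandSpec:
    """Recipe for one synthetic ligand."""

    backbone: str = "en"
    arms: tuple[str, str] = ("h", "h")
    seed: int = 0
    with_metal: bool = False
    metal: str = "Cu"

    @property
    def ligand_id(self) -> str:
        return f"{self.backbone}_{self.arms[0]}_{self.arms[1]}_s{self.seed}"


def _smiles_for(spec: SyntheticLigandSpec) -> str:
    if spec.backbone not in BACKBONES:
        raise ValueError(f"unknown backbone {spec.backbone!r}")
    for a in spec.arms:
        if a not in ARMS:
            raise ValueError(f"unknown arm {a!r}")
    tpl = BACKBONES[spec.backbone]
    fa = ARMS[spec.arms[0]][0]
    fb = ARMS[spec.arms[1]][1]
    if spec.backbone in _AR_H_FIX:
        return tpl.format(a_ar=fa or "[H]", b_ar=fb or "[H]")
    return tpl.format(a=fa, b=fb)


def make_ligand(
    spec: SyntheticLigandSpec,
) -> tuple[LigandStructure, dict[frozenset, float], dict]:
    """Build one synthetic ligand.

    Returns (structure, bond_orders, electronic_values) where
    ``electronic_values`` maps each donor atom index to lone-pair energy
    (hartree) and partial charge (e).  Deterministic for a fixed spec.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    smi = _smiles_for(spec)
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        raise ValueError(f"template/substituent clash: bad SMILES {smi!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(spec.seed % (2**31 - 1)) + 1
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise ValueError(f"{spec.ligand_id}: 3D embedding failed")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=500)

    donors = tuple(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "N")
    if len(donors) != 2:
        raise ValueError(f"{spec.ligand_id}: expected exactly two N donors")
    conf = mol.GetConformer()
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    bond_orders = {
        frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx())): b.GetBondTypeAsDouble()
        for b in mol.GetBonds()
    }

    metal_index = None
    if spec.with_metal:
        p0, p1 = coords[donors[0]], coords[donors[1]]
        mid = 0.5 * (p0 + p1)
        half = 0.5 * np.linalg.norm(p1 - p0)
        heavy = [i for i, s in enumerate(symbols) if s != "H"]
        away = mid - coords[heavy].mean(axis=0)
        nrm = np.linalg.norm(away)
        away = away / nrm if nrm > 1e-6 else np.array([0.0, 0.0, 1.0])
        drop = float(np.sqrt(max(METAL_DONOR_DISTANCE**2 - half**2, 0.25)))
        coords = np.vstack([coords, mid + drop * away])
        symbols = symbols + [spec.metal]
        metal_index = len(symbols) - 1

    struct = LigandStructure(
        ligand_id=spec.ligand_id,
        symbols=symbols,
        coords=coords,
        metal_index=metal_index,
        donor_indices=donors,
    )

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7919]))
    elec = {}
    for d, arm in zip(donors, spec.arms):
        bulk = ARMS[arm][2]
        aromatic = spec.backbone in ("bipy", "dad")
        elec[d] = {
            "lp_energy": float(-0.45 + 0.012 * bulk - 0.04 * aromatic + rng.normal(0, 0.01)),
            "charge": float(-0.56 - 0.015 * bulk + 0.08 * aromatic + rng.normal(0, 0.01)),
        }
    return struct, bond_orders, elec


def make_ligand_pool(
    n: int, seed: int = 0, with_metal: bool = False
) -> list[tuple[LigandStructure, dict[frozenset, float], dict]]:
    """A deterministic pool of n distinct synthetic ligands.

    Cycles through backbone x arm combinations in a seed-shuffled order so
    pools of modest size cover all templates.
    """
    combos = [
        (bb, (a1, a2))
        for bb in BACKBONES
        for a1 in ARMS
        for a2 in ARMS
        if a1 <= a2  # unordered arm pairs; orientation handled by alignment
    ]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    order = rng.permutation(len(combos))
    out = []
    k = 0
    while len(out) < n:
        bb, arms = combos[order[k % len(combos)]]
        out.append(
            make_ligand(
                SyntheticLigandSpec(
                    backbone=bb, arms=arms, seed=seed + k // len(combos), with_metal=with_metal
                )
            )
        )
        k += 1
    return out


@dataclass(frozen=True)
class SyntheticScreenSpec:
    """Recipe for a synthetic screening dataset over a featurized pool."""

    planted_features: tuple[str, ...]
    weights: tuple[float, ...]
    intercept: float = 1.0
    noise_sd: float = 0.1          # kcal/mol
    temperature: float = 298.15    # K
    seed: int = 0

    def __post_init__(self):
        if len(self.planted_features) != len(self.weights):
            raise ValueError("one weight per planted feature")
        if not 1 <= len(self.planted_features) <= 3:
            raise ValueError("planted subset size must be 1..3")


def make_screen(spec: SyntheticScreenSpec, table) -> tuple[pd.DataFrame, dict]:
    """Synthetic screening records over a feature table.

    ddG = intercept + sum_k w_k z_k + Normal(0, noise_sd) on the table's
    standardized planted columns; ee follows by the inverse Eyring relation
    at the spec temperature.  Returns (records, truth): records has columns
    ee, temperature_K, ddg indexed by ligand_id; truth stores the planted
    subset, weights and the noise-free response.
    """
    frame = table.frame if hasattr(table, "frame") else table
    missing = [f for f in spec.planted_features if f not in frame.columns]
    if missing:
        raise ValueError(f"planted features not in the table: {missing}")
    sub = frame[list(spec.planted_features)]
    std = sub.std(axis=0, ddof=0)
    if (std <= 0).any():
        raise ValueError("planted feature is constant over the pool")
    z = (sub - sub.mean(axis=0)) / std
    clean = spec.intercept + z.to_numpy() @ np.asarray(spec.weights, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 15485863]))
    ddg = clean + rng.normal(0.0, spec.noise_sd, size=len(clean))
    ee = ddg_to_ee(ddg, spec.temperature)
    if np.any(np.abs(ee) >= 1.0 - 1e-12):
        raise ValueError(
            "planted ddG saturates |ee| >= 1 at this temperature; "
            "use smaller weights or intercept"
        )
    records = pd.DataFrame(
        {"ee": ee, "temperature_K": spec.temperature, "ddg": ddg},
        index=frame.index.rename("ligand_id"),
    )
    truth = {
        "features": list(spec.planted_features),
        "weights": list(spec.weights),
        "intercept": spec.intercept,
        "noise_sd": spec.noise_sd,
        "clean_ddg": pd.Series(clean, index=frame.index),
        "best_ligand": str(frame.index[int(np.argmax(ddg))]),
    }
    return records, truth


def write_fixture_set(
    out_dir: str | Path, n: int = 12, seed: int = 0, with_metal: bool = False
) -> list[str]:
    """Write XYZ files plus donor/bond-order/electronic sidecars to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pool = make_ligand_pool(n, seed=seed, with_metal=with_metal)
    donor_lines, bo_lines = [], []
    elec_lines = ["# units: lp_energy=hartree charge=e",
                  "ligand_id donor_atom_index lp_energy charge"]
    ids = []
    for struct, bond_orders, elec in pool:
        ids.append(struct.ligand_id)
        lines = [str(struct.n_atoms), struct.ligand_id]
        for s, (x, y, z) in zip(struct.symbols, struct.coords):
            lines.append(f"{s} {x:.6f} {y:.6f} {z:.6f}")
        (out_dir / f"{struct.ligand_id}.xyz").write_text("\n".join(lines) + "\n")
        d0, d1 = struct.donor_indices
        donor_lines.append(f"{struct.ligand_id} {d0} {d1}")
        for edge, order in sorted(bond_orders.items(), key=lambda kv: sorted(kv[0])):
            i, j = sorted(edge)
            bo_lines.append(f"{struct.ligand_id} {i} {j} {order:g}")
        for d, vals in elec.items():
            elec_lines.append(
                f"{struct.ligand_id} {d} {vals['lp_energy']:.6f} {vals['charge']:.6f}"
            )
    (out_dir / "donors.tsv").write_text("\n".join(donor_lines) + "\n")
    (out_dir / "bond_orders.tsv").write_text("\n".join(bo_lines) + "\n")
    (out_dir / "electronic.tsv").write_text("\n".join(elec_lines) + "\n")
    return ids
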