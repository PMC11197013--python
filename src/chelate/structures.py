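"""Ligand geometries, bond perception, donor atoms and the canonical frame.

A bidentate ligand binds a metal through two donor atoms.  Everything
downstream (steric sectors, donor-local electronic features) relies on a
single reproducible placement of the ligand in space:

* the two donor atoms lie on the x axis, symmetric about the origin;
* the ligand body (heavy-atom centroid) points toward +z;
* the half with the smaller hydrogen-free volume lies at x < 0.

Bonds are perceived from interatomic distances against scaled covalent
radii; the metal atom (when present) is used only to locate the donors and
as the buried-volume sphere center — it never enters the molecular graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np

from .elements import covalent_radius, is_transition_metal, known_element

__all__ = [
    "LigandStructure",
    "MolecularGraph",
    "read_structure",
    "read_xyz",
    "read_sdf",
    "read_donor_sidecar",
    "perceive_bonds",
    "identify_donors",
    "align_ligand",
]

#: candidate donor atoms must lie within this distance of the metal (Å)
DONOR_CUTOFF = 3.0

#: default scale factor on the covalent-radius sum for bond perception
BOND_TOLERANCE = 1.15


@dataclass
class LigandStructure:
    """Atoms and coordinates of one ligand, with donor/metal annotations.

    Coordinates are in Å.  ``donor_indices`` and ``metal_index`` refer to
    positions in ``symbols``/``coords``; donors are never the metal.
    """

    ligand_id: str
    symbols: list[str]
    coords: np.ndarray  # (n_atoms, 3), Å
    metal_index: int | None = None
    donor_indices: tuple[int, int] | None = None
    total_charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.symbols), 3):
            raise ValueError(
                f"{self.ligand_id}: coords shape {self.coords.shape} does not match "
                f"{len(self.symbols)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.ligand_id}: non-finite coordinates")
        for s in self.symbols:
            if not known_element(s):
                raise ValueError(f"{self.ligand_id}: unknown element symbol {s!r}")
        if self.metal_index is not None and not 0 <= self.metal_index < self.n_atoms:
            raise ValueError(f"{self.ligand_id}: metal_index out of range")
        if self.donor_indices is not None:
            i, j = self.donor_indices
            if i == j:
                raise ValueError(f"{self.ligand_id}: donor indices must be distinct")
            for k in (i, j):
                if not 0 <= k < self.n_atoms:
                    raise ValueError(f"{self.ligand_id}: donor index {k} out of range")
                if k == self.metal_index:
                    raise ValueError(f"{self.ligand_id}: donor cannot be the metal")
            self.donor_indices = (int(i), int(j))

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def ligand_atom_indices(self) -> np.ndarray:
        """Indices of all non-metal atoms."""
        idx = np.arange(self.n_atoms)
        if self.metal_index is not None:
            idx = idx[idx != self.metal_index]
        return idx

    def heavy_atom_indices(self, include_metal: bool = False) -> np.ndarray:
        idx = np.arange(self.n_atoms) if include_metal else self.ligand_atom_indices()
        return np.array([i for i in idx if self.symbols[i] != "H"], dtype=int)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LigandStructure":
        """Apply x -> R (x + t); R may be a proper rotation or a reflection."""
        new = (self.coords + translation) @ np.asarray(rotation).T
        return replace(self, coords=new)


@dataclass
class MolecularGraph:
    """Simple molecular graph over the non-metal atoms of a ligand.

    ``graph`` nodes are atom indices carrying an ``element`` attribute;
    ``bond_orders`` (optional) maps frozenset edges to positive orders.
    """

    graph: nx.Graph
    bond_orders: dict[frozenset, float] | None = None
    _hs: nx.Graph | None = field(default=None, repr=False, compare=False)

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def hydrogen_suppressed(self) -> nx.Graph:
        """Induced subgraph over the heavy atoms (cached view copy)."""
        if self._hs is None:
            heavy = [n for n, d in self.graph.nodes(data=True) if d["element"] != "H"]
            self._hs = self.graph.subgraph(heavy).copy()
        return self._hs

    def hydrogen_counts(self) -> dict[int, int]:
        """Attached-hydrogen count per heavy atom, from the full graph."""
        out = {}
        for n, d in self.graph.nodes(data=True):
            if d["element"] == "H":
                continue
            out[n] = sum(
                1 for m in self.graph.neighbors(n) if self.graph.nodes[m]["element"] == "H"
            )
        return out

    def order_of(self, i: int, j: int) -> float:
        if self.bond_orders is None:
            raise ValueError("no bond orders attached to this graph")
        try:
            return self.bond_orders[frozenset((i, j))]
        except KeyError:
            raise ValueError(f"missing bond order for edge ({i}, {j})") from None


# ---------------------------------------------------------------------------
# readers


def read_xyz(path: str | Path, ligand_id: str | None = None) -> LigandStructure:
    """Read a standard two-header-line XYZ file (coordinates in Å)."""
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    if len(lines) < 3:
        raise ValueError(f"{path}: malformed XYZ (fewer than 3 lines)")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: first line must be the atom count") from None
    body = lines[2 : 2 + n]
    if len(body) != n:
        raise ValueError(f"{path}: expected {n} atom lines, found {len(body)}")
    symbols, coords = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: malformed atom line {ln!r}")
        symbols.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    return _finalize(ligand_id or path.stem, symbols, np.array(coords))


def read_sdf(path: str | Path, ligand_id: str | None = None) -> LigandStructure:
    """Read the first molecule of an SDF/MOL V2000 file via RDKit."""
    from rdkit import Chem

    path = Path(path)
    mol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=False)
    if mol is None:
        raise ValueError(f"{path}: RDKit could not parse the MOL/SDF block")
    conf = mol.GetConformer()
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    return _finalize(ligand_id or path.stem, symbols, coords)


def sdf_bond_orders(path: str | Path) -> dict[frozenset, float]:
    """Convenience: explicit bond orders from an SDF bond block (aromatic=1.5)."""
    from rdkit import Chem

    mol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=False)
    if mol is None:
        raise ValueError(f"{path}: RDKit could not parse the MOL/SDF block")
    return {
        frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx())): b.GetBondTypeAsDouble()
        for b in mol.GetBonds()
    }


def _finalize(ligand_id: str, symbols: list[str], coords: np.ndarray) -> LigandStructure:
    if len(symbols) < 3:
        raise ValueError(f"{ligand_id}: need at least 3 atoms")
    metals = [i for i, s in enumerate(symbols) if is_transition_metal(s)]
    if len(metals) > 1:
        raise ValueError(f"{ligand_id}: more than one transition metal present")
    return LigandStructure(
        ligand_id=ligand_id,
        symbols=symbols,
        coords=coords,
        metal_index=metals[0] if metals else None,
    )


def read_structure(path: str | Path, fmt: str | None = None) -> LigandStructure:
    """Read a ligand structure; format inferred from the suffix unless given."""
    path = Path(path)
    if fmt is None:
        fmt = {".xyz": "xyz", ".sdf": "sdf", ".mol": "sdf"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix of {path}")
    if fmt == "xyz":
        return read_xyz(path)
    if fmt == "sdf":
        return read_sdf(path)
    raise ValueError(f"unsupported format {fmt!r}")


def read_donor_sidecar(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a donor-annotation table: ligand_id, donor_i, donor_j (0-based)."""
    out: dict[str, tuple[int, int]] = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.replace(",", " ").split()
        if len(parts) != 3:
            raise ValueError(f"malformed donor sidecar line {ln!r}")
        lid, i, j = parts[0], int(parts[1]), int(parts[2])
        if lid in out:
            raise ValueError(f"duplicated ligand id {lid!r} in donor sidecar")
        out[lid] = (i, j)
    return out


# ---------------------------------------------------------------------------
# bond perception


def perceive_bonds(
    s: LigandStructure,
    tolerance: float = BOND_TOLERANCE,
    bond_orders: dict[frozenset, float] | None = None,
) -> MolecularGraph:
    """Assign bonds where dist(i,j) <= tolerance * (r_cov(i) + r_cov(j)).

    The metal atom is excluded.  Raises if the metal-free graph is
    disconnected (listing the components).
    """
    if not 1.0 <= tolerance <= 1.4:
        raise ValueError(f"tolerance {tolerance} outside [1.0, 1.4]")
    idx = s.ligand_atom_indices()
    g = nx.Graph()
    for i in idx:
        g.add_node(int(i), element=s.symbols[i])
    radii = np.array([covalent_radius(s.symbols[i]) for i in idx])
    pos = s.coords[idx]
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    cut = tolerance * (radii[:, None] + radii[None, :])
    ii, jj = np.nonzero(np.triu(d <= cut, k=1))
    for a, b in zip(idx[ii], idx[jj]):
        g.add_edge(int(a), int(b))
    if g.number_of_nodes() and not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise ValueError(
            f"{s.ligand_id}: metal-free molecular graph is disconnected; "
            f"components: {comps}"
        )
    return MolecularGraph(graph=g, bond_orders=bond_orders)


# ---------------------------------------------------------------------------
# donor identification


def identify_donors(s: LigandStructure) -> tuple[int, int]:
    """The two non-metal heavy atoms closest to the metal center.

    If the structure is metal-free but carries a donor annotation, that
    annotation is returned unchanged.  Ties are broken by (distance, index).
    """
    if s.metal_index is None:
        if s.donor_indices is not None:
            return s.donor_indices
        raise ValueError(f"{s.ligand_id}: no metal and no donor annotation")
    m = s.coords[s.metal_index]
    cands = [
        (float(np.linalg.norm(s.coords[i] - m)), int(i))
        for i in s.heavy_atom_indices()
    ]
    cands = [(d, i) for d, i in cands if d <= DONOR_CUTOFF]
    if len(cands) < 2:
        raise ValueError(
            f"{s.ligand_id}: fewer than two heavy atoms within {DONOR_CUTOFF} Å "
            "of the metal"
        )
    cands.sort()
    return (cands[0][1], cands[1][1])


# ---------------------------------------------------------------------------
# alignment


def _rotation_onto(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _default_half_volume(struct: LigandStructure, side: int) -> float:
    from . import sterics

    return sterics.half_volumes(struct, include_h=False, spacing=0.2)[
        "neg_x" if side < 0 else "pos_x"
    ]


def align_ligand(
    s: LigandStructure,
    donors: tuple[int, int] | None = None,
    volume_fn: Callable[[LigandStructure, int], float] | None = None,
) -> LigandStructure:
    """Place the ligand in the canonical steric frame (see module docstring).

    ``volume_fn(struct, side)`` evaluates the hydrogen-free volume of one
    half (side = -1 for x<0, +1 for x>0); by default the grid integrator
    from :mod:`chelate.sterics` at 0.2 Å spacing.  The transform is rigid
    (distance-preserving); the final step may be a reflection through the
    yz plane so that the smaller half sits at x < 0.  Near-equal halves are
    tied-broken by placing the lower-index donor at x < 0.
    """
    if donors is None:
        donors = identify_donors(s)
    d0, d1 = donors
    if d0 > d1:
        d0, d1 = d1, d0
    p0, p1 = s.coords[d0], s.coords[d1]
    axis = p1 - p0
    nrm = float(np.linalg.norm(axis))
    if nrm < 1e-6:
        raise ValueError(f"{s.ligand_id}: coincident donor atoms")
    mid = 0.5 * (p0 + p1)

    # 1. donor midpoint to origin, lower-index donor toward -x
    t = -mid
    r1 = _rotation_onto(axis / nrm, np.array([1.0, 0.0, 0.0]))
    out = replace(s, donor_indices=(d0, d1)).transformed(r1, t)

    # 2. spin about x so the heavy-atom centroid points toward +z
    heavy = [i for i in out.heavy_atom_indices() if i not in (d0, d1)]
    if not heavy:
        raise ValueError(f"{s.ligand_id}: no non-donor heavy atom to orient against")
    cen = out.coords[heavy].mean(axis=0)
    perp = cen - np.array([cen[0], 0.0, 0.0])
    if np.linalg.norm(perp) < 1e-6:
        # degenerate (centroid on the donor axis): use the principal axis of
        # inertia orthogonal to x as the z direction instead
        pts = out.coords[heavy] - out.coords[heavy].mean(axis=0)
        yz = pts[:, 1:]
        if yz.shape[0] < 2 or np.allclose(yz, 0, atol=1e-8):
            perp = np.array([0.0, 0.0, 1.0])
        else:
            _, vecs = np.linalg.eigh(yz.T @ yz)
            v = vecs[:, -1]
            perp = np.array([0.0, v[0], v[1]])
    perp = perp / np.linalg.norm(perp)
    r2 = _rotation_onto(perp, np.array([0.0, 0.0, 1.0]))
    # keep x fixed: rotate only in the yz plane
    ang = np.arctan2(perp[1], perp[2])
    ca, sa = np.cos(ang), np.sin(ang)
    r2 = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]], dtype=float)
    out = out.transformed(r2, np.zeros(3))

    # 3. smaller hydrogen-free half to x<0 (reflection through yz if needed)
    if volume_fn is None:
        volume_fn = _default_half_volume
    v_neg = volume_fn(out, -1)
    v_pos = volume_fn(out, +1)
    tie_tol = 1e-3 * max(v_neg + v_pos, 1.0)
    reflect = False
    if abs(v_neg - v_pos) <= tie_tol:
        # tie: lower-index donor at -x; it currently sits at -x by step 1
        reflect = False
    elif v_neg > v_pos:
        reflect = True
    if reflect:
        refl = np.diag([-1.0, 1.0, 1.0])
        out = out.transformed(refl, np.zeros(3))
    return out


def smaller_half_donor(s: LigandStructure) -> int:
    """Donor index lying in the smaller (x<0) half of an aligned ligand."""
    if s.donor_indices is None:
        raise ValueError("structure has no donor annotation")
    i, j = s.donor_indices
    return i if s.coords[i][0] < s.coords[j][0] else j
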