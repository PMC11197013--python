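"""Steric descriptors: total and buried volumes split into halves, quadrants
and octants of the aligned frame.

Volumes are unions of atomic van der Waals spheres (Bondi radii scaled by
1.17 by default) integrated on a cubic grid.  The grid is cell-centered and
symmetric about the coordinate planes — points sit at (k + 1/2)h — so no
point ever lies exactly on a sector boundary and reflecting a structure
through the yz plane swaps the -x/+x sector values exactly on the same
grid.  Buried volume follows the usual probe-sphere convention: the percent
of a sphere of radius R (default 3.5 Å) around the metal position that is
occupied by ligand spheres; when no metal is recorded the center defaults
to a point 2.1 Å down the -z axis from the donor midpoint (the metal side
of the aligned frame).

The grid integrator is canonical and deterministic; Monte-Carlo integration
appears only as an independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elements import vdw_radius
from .structures import LigandStructure

__all__ = [
    "total_volume",
    "buried_volume",
    "sector_decomposition",
    "half_volumes",
    "steric_descriptor_set",
    "SectorVolumes",
    "RADII_SCALE",
    "SPHERE_RADIUS",
    "GRID_SPACING",
    "OCTANT_LABELS",
    "QUADRANT_LABELS",
    "HALF_LABELS",
]

RADII_SCALE = 1.17
SPHERE_RADIUS = 3.5
GRID_SPACING = 0.10
DUMMY_METAL_DISTANCE = 2.1

HALF_LABELS = ("neg_x", "pos_x")
#: quadrants by (x, y) signs: Q1 NE (+,+), Q2 NW (-,+), Q3 SW (-,-), Q4 SE (+,-)
QUADRANT_LABELS = ("Q1_px_py", "Q2_nx_py", "Q3_nx_ny", "Q4_px_ny")
#: octants: quadrant pattern at z>0 (1-4), then the same at z<0 (5-8)
OCTANT_LABELS = (
    "O1_px_py_pz", "O2_nx_py_pz", "O3_nx_ny_pz", "O4_px_ny_pz",
    "O5_px_py_nz", "O6_nx_py_nz", "O7_nx_ny_nz", "O8_px_ny_nz",
)

_QUAD_SIGNS = {"Q1_px_py": (1, 1), "Q2_nx_py": (-1, 1), "Q3_nx_ny": (-1, -1), "Q4_px_ny": (1, -1)}
_OCT_SIGNS = {
    lab: (_QUAD_SIGNS[QUADRANT_LABELS[k % 4]] + ((1,) if k < 4 else (-1,)))
    for k, lab in enumerate(OCTANT_LABELS)
}


def _atom_selection(s: LigandStructure, include_h: bool) -> tuple[np.ndarray, np.ndarray]:
    idx = s.ligand_atom_indices()
    if not include_h:
        idx = np.array([i for i in idx if s.symbols[i] != "H"], dtype=int)
    if len(idx) == 0:
        return np.zeros((0, 3)), np.zeros(0)
    coords = s.coords[idx]
    radii = np.array([vdw_radius(s.symbols[i]) for i in idx])
    return coords, radii


def _symmetric_axis(extent: float, h: float) -> np.ndarray:
    """Cell centers (k+1/2)h covering [-extent, extent], symmetric about 0."""
    k = int(np.ceil(extent / h + 0.5))
    return (np.arange(-k, k) + 0.5) * h


def _occupancy_grid(
    coords: np.ndarray, radii: np.ndarray, h: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Boolean occupancy over a symmetric cell-centered grid covering all spheres."""
    if len(coords) == 0:
        ax = _symmetric_axis(h, h)
        return np.zeros((len(ax),) * 3, dtype=bool), ax, ax, ax
    ext = np.abs(coords).max(axis=0) + radii.max() + h
    axes = [_symmetric_axis(ext[d], h) for d in range(3)]
    occ = np.zeros((len(axes[0]), len(axes[1]), len(axes[2])), dtype=bool)
    for c, r in zip(coords, radii):
        sl, local = [], []
        for d in range(3):
            ax = axes[d]
            lo = np.searchsorted(ax, c[d] - r)
            hi = np.searchsorted(ax, c[d] + r, side="right")
            sl.append(slice(lo, hi))
            local.append(ax[lo:hi] - c[d])
        dx, dy, dz = np.meshgrid(*local, indexing="ij", sparse=True)
        occ[tuple(sl)] |= dx * dx + dy * dy + dz * dz <= r * r
    return occ, *axes


def total_volume(
    s: LigandStructure,
    include_h: bool = True,
    radii_scale: float = RADII_SCALE,
    spacing: float = GRID_SPACING,
) -> float:
    """Union volume (Å³) of the scaled vdW spheres of the (metal-free) ligand."""
    coords, radii = _atom_selection(s, include_h)
    if len(coords) == 0:
        import warnings

        warnings.warn("empty atom set; volume 0", stacklevel=2)
        return 0.0
    occ, *_ = _occupancy_grid(coords, radii * radii_scale, spacing)
    return float(occ.sum()) * spacing**3


def _sphere_center(s: LigandStructure, center=None) -> np.ndarray:
    if center is not None:
        return np.asarray(center, dtype=float)
    if s.metal_index is not None:
        return s.coords[s.metal_index].astype(float)
    # aligned frame: ligand body at +z, metal side at -z
    return np.array([0.0, 0.0, -DUMMY_METAL_DISTANCE])


def buried_volume(
    s: LigandStructure,
    sphere_radius: float = SPHERE_RADIUS,
    center=None,
    include_h: bool = False,
    radii_scale: float = RADII_SCALE,
    spacing: float = GRID_SPACING,
) -> float:
    """Percent of the probe sphere occupied by ligand vdW spheres."""
    out = _buried_sectors(s, sphere_radius, center, include_h, radii_scale, spacing)
    return out["total"]


def _buried_sectors(
    s: LigandStructure,
    sphere_radius: float,
    center,
    include_h: bool,
    radii_scale: float,
    spacing: float,
) -> dict[str, float]:
    """Buried-volume percent, total and per octant/quadrant/half."""
    c = _sphere_center(s, center)
    coords, radii = _atom_selection(s, include_h)
    radii = radii * radii_scale
    # global lattice at (k+1/2)h so sector planes never cut through points
    axes = []
    for d in range(3):
        lo = int(np.floor((c[d] - sphere_radius) / spacing - 0.5))
        hi = int(np.ceil((c[d] + sphere_radius) / spacing - 0.5)) + 1
        axes.append((np.arange(lo, hi) + 0.5) * spacing)
    gx, gy, gz = np.meshgrid(*axes, indexing="ij", sparse=True)
    inside = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2 <= sphere_radius**2
    occ = np.zeros_like(inside)
    for p, r in zip(coords, radii):
        if np.linalg.norm(p - c) > sphere_radius + r:
            continue
        occ |= (gx - p[0]) ** 2 + (gy - p[1]) ** 2 + (gz - p[2]) ** 2 <= r * r
    occ &= inside
    n_sphere = float(inside.sum())
    out = {"total": 100.0 * float(occ.sum()) / max(n_sphere, 1.0)}
    sx = np.sign(axes[0])[:, None, None]
    sy = np.sign(axes[1])[None, :, None]
    sz = np.sign(axes[2])[None, None, :]
    for lab, (a, b, cc) in _OCT_SIGNS.items():
        sel = (sx == a) & (sy == b) & (sz == cc)
        denom = float((inside & sel).sum())
        out[lab] = 100.0 * float((occ & sel).sum()) / max(denom, 1.0)
    for k, lab in enumerate(QUADRANT_LABELS):
        a, b = _QUAD_SIGNS[lab]
        sel = (sx == a) & (sy == b)
        denom = float((inside & sel).sum())
        out[lab] = 100.0 * float((occ & sel).sum()) / max(denom, 1.0)
    for lab, a in zip(HALF_LABELS, (-1, 1)):
        sel = sx == a
        denom = float((inside & sel).sum())
        out[lab] = 100.0 * float((occ & sel).sum()) / max(denom, 1.0)
    return out


def sector_decomposition(
    s: LigandStructure,
    mode: str = "octants",
    buried: bool = False,
    include_h: bool = True,
    radii_scale: float = RADII_SCALE,
    spacing: float = GRID_SPACING,
    sphere_radius: float = SPHERE_RADIUS,
    center=None,
) -> dict[str, float]:
    """Sector-resolved volumes (Å³) or buried-volume fractions (%).

    ``mode`` is one of ``halves``, ``quadrants``, ``octants``.  Requires an
    aligned structure (donor midpoint at the origin): sectors are defined by
    coordinate signs in that frame.
    """
    if mode not in {"halves", "quadrants", "octants"}:
        raise ValueError(f"unknown mode {mode!r}")
    _check_aligned(s)
    if buried:
        full = _buried_sectors(s, sphere_radius, center, include_h, radii_scale, spacing)
    else:
        full = _volume_sectors(s, include_h, radii_scale, spacing)
    labels = {"halves": HALF_LABELS, "quadrants": QUADRANT_LABELS, "octants": OCTANT_LABELS}[mode]
    return {lab: full[lab] for lab in labels}


def _check_aligned(s: LigandStructure) -> None:
    if s.donor_indices is None:
        raise ValueError("sector decomposition requires an aligned structure")
    i, j = s.donor_indices
    mid = 0.5 * (s.coords[i] + s.coords[j])
    if np.linalg.norm(mid) > 1e-6 or abs(s.coords[i][1]) > 1e-6 or abs(s.coords[i][2]) > 1e-6:
        raise ValueError("structure is not in the aligned frame (run align_ligand first)")


def _volume_sectors(
    s: LigandStructure, include_h: bool, radii_scale: float, spacing: float
) -> dict[str, float]:
    coords, radii = _atom_selection(s, include_h)
    occ, ax, ay, az = _occupancy_grid(coords, radii * radii_scale, spacing)
    v = spacing**3
    out = {"total": float(occ.sum()) * v}
    sx, sy, sz = np.sign(ax), np.sign(ay), np.sign(az)
    for lab, (a, b, c) in _OCT_SIGNS.items():
        out[lab] = float(occ[np.ix_(sx == a, sy == b, sz == c)].sum()) * v
    for lab in QUADRANT_LABELS:
        a, b = _QUAD_SIGNS[lab]
        out[lab] = float(occ[np.ix_(sx == a, sy == b)].sum()) * v
    for lab, a in zip(HALF_LABELS, (-1, 1)):
        out[lab] = float(occ[sx == a].sum()) * v
    return out


def half_volumes(
    s: LigandStructure,
    include_h: bool = False,
    radii_scale: float = RADII_SCALE,
    spacing: float = GRID_SPACING,
) -> dict[str, float]:
    """Volumes of the x<0 and x>0 halves (no alignment check; used by align)."""
    coords, radii = _atom_selection(s, include_h)
    occ, ax, _, _ = _occupancy_grid(coords, radii * radii_scale, spacing)
    v = spacing**3
    sx = np.sign(ax)
    return {
        "neg_x": float(occ[sx == -1].sum()) * v,
        "pos_x": float(occ[sx == 1].sum()) * v,
    }


@dataclass
class SectorVolumes:
    """One consistent set of sector values for a single (buried?, include_h?) pass."""

    total: float
    halves: dict[str, float]
    quadrants: dict[str, float]
    octants: dict[str, float]


@dataclass
class StericDescriptorSet:
    """All steric descriptors of one aligned ligand.

    ``volume`` entries are Å³; ``buried`` entries are percent of the probe
    sphere.  Keys of the inner dicts: ``(include_h: bool)``.
    """

    volume: dict[bool, SectorVolumes]
    buried: dict[bool, SectorVolumes]


def steric_descriptor_set(
    s: LigandStructure,
    radii_scale: float = RADII_SCALE,
    spacing: float = GRID_SPACING,
    sphere_radius: float = SPHERE_RADIUS,
    center=None,
) -> StericDescriptorSet:
    """Compute every steric descriptor in four grid passes (2 volume, 2 buried)."""
    _check_aligned(s)
    vol, bur = {}, {}
    for include_h in (True, False):
        f = _volume_sectors(s, include_h, radii_scale, spacing)
        vol[include_h] = SectorVolumes(
            total=f["total"],
            halves={k: f[k] for k in HALF_LABELS},
            quadrants={k: f[k] for k in QUADRANT_LABELS},
            octants={k: f[k] for k in OCTANT_LABELS},
        )
        b = _buried_sectors(s, sphere_radius, center, include_h, radii_scale, spacing)
        bur[include_h] = SectorVolumes(
            total=b["total"],
            halves={k: b[k] for k in HALF_LABELS},
            quadrants={k: b[k] for k in QUADRANT_LABELS},
            octants={k: b[k] for k in OCTANT_LABELS},
        )
    return StericDescriptorSet(volume=vol, buried=bur)
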