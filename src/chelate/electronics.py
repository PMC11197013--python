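"""Donor-atom electronic descriptors, ingested from precomputed tables.

The package never computes electronic structure itself: lone-pair orbital
energies and atomic partial charges of the two donor atoms come from an
external quantum-chemistry workflow and are read from a sidecar table.
Energies are stored internally in hartree, charges in units of e.

Sidecar format (delimited text, ``#`` comments allowed)::

    # units: lp_energy=hartree charge=e
    ligand_id  donor_atom_index  lp_energy  charge

The unit header must declare lp_energy as ``hartree`` or ``eV``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .structures import LigandStructure, smaller_half_donor

__all__ = ["ElectronicRecord", "read_electronic_table", "derive_electronic_features"]

HARTREE_PER_EV = 1.0 / 27.211386245988


@dataclass(frozen=True)
class ElectronicRecord:
    """Electronic values for the two donor atoms of one ligand (hartree, e)."""

    ligand_id: str
    donor_values: dict  # atom index -> {"lp_energy": float, "charge": float}

    def __post_init__(self):
        if len(self.donor_values) != 2:
            raise ValueError(
                f"{self.ligand_id}: exactly two donor entries required, "
                f"got {len(self.donor_values)}"
            )


def read_electronic_table(path: str | Path) -> dict[str, ElectronicRecord]:
    """Read the electronic sidecar; converts eV energies to hartree."""
    lines = Path(path).read_text().splitlines()
    unit = None
    rows: dict[str, dict[int, dict]] = {}
    for ln in lines:
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            m = re.search(r"lp_energy\s*=\s*(\w+)", ln)
            if m:
                unit = m.group(1).lower()
            continue
        parts = ln.replace(",", " ").split()
        if parts[0] == "ligand_id":
            continue
        if len(parts) != 4:
            raise ValueError(f"malformed electronic sidecar line {ln!r}")
        lid, idx = parts[0], int(parts[1])
        e, q = float(parts[2]), float(parts[3])
        per = rows.setdefault(lid, {})
        if idx in per:
            raise ValueError(f"{lid}: duplicated donor atom {idx} in electronic table")
        per[idx] = {"lp_energy": e, "charge": q}
    if unit is None:
        raise ValueError("electronic sidecar must declare units, e.g. '# units: lp_energy=hartree charge=e'")
    if unit not in {"hartree", "ev"}:
        raise ValueError(f"unsupported lp_energy unit {unit!r}")
    scale = 1.0 if unit == "hartree" else HARTREE_PER_EV
    out = {}
    for lid, per in rows.items():
        if len(per) != 2:
            raise ValueError(f"{lid}: expected two donor rows, got {len(per)}")
        out[lid] = ElectronicRecord(
            ligand_id=lid,
            donor_values={
                i: {"lp_energy": v["lp_energy"] * scale, "charge": v["charge"]}
                for i, v in per.items()
            },
        )
    return out


def derive_electronic_features(
    rec: ElectronicRecord, aligned: LigandStructure
) -> dict[str, float]:
    """Half-resolved donor electronic features of an aligned ligand.

    The donor sitting in the smaller (x<0) half — as fixed by the steric
    alignment — provides the ``smaller`` entries; ties on the x=0 plane are
    already resolved by the alignment's donor-index tie-break.
    """
    if aligned.donor_indices is None:
        raise ValueError("aligned structure with donor annotation required")
    da, db = aligned.donor_indices
    if set(rec.donor_values) != {da, db}:
        raise ValueError(
            f"{rec.ligand_id}: electronic record donors {sorted(rec.donor_values)} "
            f"do not match structure donors {sorted((da, db))}"
        )
    small = smaller_half_donor(aligned)
    large = db if small == da else da
    out: dict[str, float] = {}
    for prop in ("lp_energy", "charge"):
        s = rec.donor_values[small][prop]
        l = rec.donor_values[large][prop]
        out[f"{prop}_smaller_half"] = s
        out[f"{prop}_larger_half"] = l
        out[f"{prop}_abs_diff"] = abs(s - l)
        out[f"{prop}_mean"] = 0.5 * (s + l)
        out[f"{prop}_min"] = min(s, l)
        out[f"{prop}_max"] = max(s, l)
    return out
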