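"""Per-element data tables used across the package.

Covalent radii are the Cordero single-bond consensus values (in Å) and are
used both for bond perception and for the radius-ratio alpha correction of
the kappa shape indices.  Van der Waals radii are Bondi's, extended with the
common later additions for elements Bondi did not list.  Missing vdW entries
fall back to 2.0 Å with a warning.
"""

from __future__ import annotations

import warnings

# fmt: off
_SYMBOLS = [
    "H", "He",
    "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
    "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr",
    "Rb", "Sr", "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd",
    "In", "Sn", "Sb", "Te", "I", "Xe",
    "Cs", "Ba", "La", "Ce", "Pr", "Nd", "Pm", "Sm", "Eu", "Gd", "Tb", "Dy",
    "Ho", "Er", "Tm", "Yb", "Lu",
    "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn",
]
# fmt: on

ATOMIC_NUMBER: dict[str, int] = {s: i + 1 for i, s in enumerate(_SYMBOLS)}

# Cordero et al. single-bond covalent radii, Å (low-spin values for Mn/Fe/Co).
COVALENT_RADIUS: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "Y": 1.90, "Zr": 1.75, "Nb": 1.64, "Mo": 1.54,
    "Tc": 1.47, "Ru": 1.46, "Rh": 1.42, "Pd": 1.39, "Ag": 1.45, "Cd": 1.44,
    "In": 1.42, "Sn": 1.39, "Sb": 1.39, "Te": 1.38, "I": 1.39, "Xe": 1.40,
    "Cs": 2.44, "Ba": 2.15, "La": 2.07,
    "Hf": 1.75, "Ta": 1.70, "W": 1.62, "Re": 1.51, "Os": 1.44, "Ir": 1.41,
    "Pt": 1.36, "Au": 1.36, "Hg": 1.32,
    "Tl": 1.45, "Pb": 1.46, "Bi": 1.48,
}

# Bondi van der Waals radii, Å; starred entries are common extensions.
VDW_RADIUS: dict[str, float] = {
    "H": 1.20, "He": 1.40,
    "Li": 1.82, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Ne": 1.54,
    "Na": 2.27, "Mg": 1.73, "Al": 1.84, "Si": 2.10, "P": 1.80, "S": 1.80,
    "Cl": 1.75, "Ar": 1.88,
    "K": 2.75, "Ca": 2.31, "Ni": 1.63, "Cu": 1.40, "Zn": 1.39,
    "Ga": 1.87, "Ge": 2.11, "As": 1.85, "Se": 1.90, "Br": 1.85, "Kr": 2.02,
    "Pd": 1.63, "Ag": 1.72, "Cd": 1.58,
    "In": 1.93, "Sn": 2.17, "Sb": 2.06, "Te": 2.06, "I": 1.98, "Xe": 2.16,
    "Pt": 1.75, "Au": 1.66, "Hg": 1.55, "Tl": 1.96, "Pb": 2.02, "Bi": 2.07,
}

# Number of valence electrons, used for the Kier-Hall valence delta.
VALENCE_ELECTRONS: dict[str, int] = {
    "H": 1, "Li": 1, "Be": 2, "B": 3, "C": 4, "N": 5, "O": 6, "F": 7,
    "Na": 1, "Mg": 2, "Al": 3, "Si": 4, "P": 5, "S": 6, "Cl": 7,
    "Ga": 3, "Ge": 4, "As": 5, "Se": 6, "Br": 7,
    "In": 3, "Sn": 4, "Sb": 5, "Te": 6, "I": 7,
}

TRANSITION_METALS: frozenset[str] = frozenset(
    {
        "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
        "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd",
        "La", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    }
)

#: sp3 carbon covalent radius, the reference for the kappa alpha correction.
R_CSP3 = COVALENT_RADIUS["C"]


def covalent_radius(symbol: str) -> float:
    try:
        return COVALENT_RADIUS[symbol]
    except KeyError:
        raise KeyError(f"no covalent radius tabulated for element {symbol!r}") from None


def vdw_radius(symbol: str) -> float:
    r = VDW_RADIUS.get(symbol)
    if r is None:
        warnings.warn(
            f"no van der Waals radius tabulated for {symbol!r}; using 2.0 Å",
            stacklevel=2,
        )
        return 2.0
    return r


def kier_alpha(symbol: str) -> float:
    """Radius-ratio alpha contribution r_cov/r(Csp3) - 1; 0 if untabulated."""
    r = COVALENT_RADIUS.get(symbol)
    if r is None:
        warnings.warn(f"no alpha parameter for {symbol!r}; contributing 0", stacklevel=2)
        return 0.0
    return r / R_CSP3 - 1.0


def is_transition_metal(symbol: str) -> bool:
    return symbol in TRANSITION_METALS


def known_element(symbol: str) -> bool:
    return symbol in ATOMIC_NUMBER
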