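"""Element tables: covalent radii, metal classification, van der Waals sums.

Covalent radii follow Cordero et al. (single-bond, low-spin values for the
first-row transition metals). Only elements that can plausibly occur in a
metal-organic complex or a protonated receptor are listed; anything else is
rejected at parse time so typos surface early.
"""
from __future__ import annotations

# single-bond covalent radii, Å
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Na": 1.66, "Mg": 1.41, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02,
    "K": 2.03, "Ca": 1.76, "Se": 1.20, "Br": 1.20, "I": 1.39,
    "V": 1.53, "Cr": 1.39, "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24,
    "Cu": 1.32, "Zn": 1.22, "Mo": 1.54, "Ru": 1.46, "Rh": 1.42, "Pd": 1.39,
    "Ag": 1.45, "Re": 1.51, "Os": 1.44, "Ir": 1.41, "Pt": 1.36, "Au": 1.36,
    # the vacancy marker has no chemistry; radius 0 keeps it out of bond perception
    "DD": 0.0,
}

# metals handled as their own AutoDock-style atom type
METALS: frozenset[str] = frozenset({
    "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Mo", "Ru", "Rh", "Pd", "Ag", "Re", "Os", "Ir", "Pt", "Au",
    "Mg", "Ca", "Na", "K",
})

# like-pair van der Waals distance sums Rii (Å) and well depths (kcal/mol) for the
# organic/protein types, AutoDock4 lineage; pairs combine arithmetically (R) and
# geometrically (ε)
VDW_RII: dict[str, float] = {
    "C": 4.00, "A": 4.00, "N": 3.50, "NA": 3.50, "OA": 3.20,
    "SA": 4.00, "HD": 2.00, "H": 2.00,
}
VDW_EPS: dict[str, float] = {
    "C": 0.150, "A": 0.150, "N": 0.160, "NA": 0.160, "OA": 0.200,
    "SA": 0.200, "HD": 0.020, "H": 0.020,
}

# generic metal like-pair distance sum; per-metal refinement is a user override
METAL_RII_DEFAULT = 2.60

ORGANIC_TYPES = ("C", "A", "N", "NA", "OA", "SA", "HD", "H")
ACCEPTOR_TYPES = ("NA", "OA", "SA")


def is_metal(element: str) -> bool:
    return element in METALS


def covalent_radius(element: str) -> float:
    try:
        return COVALENT_RADII[element]
    except KeyError:
        raise KeyError(f"no covalent radius tabulated for element {element!r}") from None
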