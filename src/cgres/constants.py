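"""Physical constants, unit conventions and per-residue-type tables.

Units used throughout the package: kcal/mol (energy), Å (length),
radians (angles), Kelvin (temperature), amu (mass), fs (time).
"""

from __future__ import annotations

import numpy as np

#: Boltzmann constant, kcal/mol/K.
KB = 1.987204259e-3

#: Gas constant in kcal/mol/K (identical to KB on a per-mole basis).
R_KCAL = KB

#: Conventional RT at 298 K used by the XL-MS statistical potential,
#: kcal/mol.  This is the rounded value the potential was parameterized
#: with; the physical R*298 K is 0.59219 kcal/mol.
RT_298 = 0.591

#: Conversion factor: (kcal/mol/Å)/amu -> Å/fs² (acceleration).
ACCEL_UNIT = 4.184e-4

#: Reference temperature T° of the force-field temperature factors, K.
T0_DEFAULT = 300.0

#: Default MD time step, fs.
DT_DEFAULT = 9.78

AA1 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA1)}

AA3TO1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
AA1TO3 = {v: k for k, v in AA3TO1.items()}

# Side-chain heavy-atom counts (Cβ and beyond).
SC_HEAVY = {
    "A": 1, "C": 2, "D": 4, "E": 5, "F": 7, "G": 0, "H": 6, "I": 4,
    "K": 5, "L": 4, "M": 4, "N": 4, "P": 3, "Q": 5, "R": 7, "S": 2,
    "T": 3, "V": 3, "W": 10, "Y": 8,
}

# Side-chain masses (residue mass minus the 56 amu CO-NH-CαH backbone), amu.
SC_MASS = {
    "A": 15.0, "C": 47.1, "D": 59.0, "E": 73.1, "F": 91.1, "G": 12.0,
    "H": 81.1, "I": 57.1, "K": 72.1, "L": 57.1, "M": 75.1, "N": 58.1,
    "Q": 72.1, "P": 42.1, "R": 100.1, "S": 31.0, "T": 45.1, "V": 43.1,
    "W": 130.2, "Y": 107.1,
}

#: Effective backbone (Cα + united peptide share) site mass, amu.
BACKBONE_MASS = 56.0

# Cα–SC-centroid reference distances, Å (approximate centroid offsets).
B0_SC = {
    "A": 1.53, "C": 2.10, "D": 2.47, "E": 3.00, "F": 3.40, "G": 0.00,
    "H": 3.15, "I": 2.30, "K": 3.50, "L": 2.60, "M": 2.95, "N": 2.47,
    "P": 1.85, "Q": 3.00, "R": 4.10, "S": 1.90, "T": 1.95, "V": 1.95,
    "W": 3.85, "Y": 3.80,
}

# Side-chain pseudo-proton radial pad beyond the SC site, Å.
PROTON_PAD = {
    "A": 1.00, "C": 1.20, "D": 1.10, "E": 1.20, "F": 1.40, "G": 0.80,
    "H": 1.30, "I": 1.30, "K": 1.30, "L": 1.30, "M": 1.30, "N": 1.20,
    "P": 1.10, "Q": 1.20, "R": 1.40, "S": 1.00, "T": 1.10, "V": 1.20,
    "W": 1.50, "Y": 1.40,
}


def stokes_radius(aa: str) -> float:
    """Default per-residue Stokes radius (Å).

    Volume-equivalent sphere of the residue's heavy atoms (4 backbone
    atoms plus the side chain) at ~20 Å³ per heavy atom:
    ρ = (3·20·N/4π)^(1/3) ≈ 1.68·N^(1/3).
    """
    n = 4 + SC_HEAVY[aa]
    return 1.68 * n ** (1.0 / 3.0)


def table(d: dict[str, float]) -> np.ndarray:
    """One-letter-keyed dict -> float64 array in AA1 order."""
    return np.array([d[a] for a in AA1], dtype=np.float64)


def seq_to_idx(sequence: str) -> np.ndarray:
    """Residue one-letter sequence -> int32 indices into the AA1 tables."""
    try:
        return np.array([AA_INDEX[a] for a in sequence], dtype=np.int32)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown residue type {exc} in sequence") from exc
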