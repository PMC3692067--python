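"""Shared amino-acid tables: alphabet, substitution matrix, propensity scales.

All per-residue tables are keyed by the canonical 20-letter alphabet in
``AA_ALPHABET`` order; helper arrays are pre-indexed so that hot loops can
work with integer-encoded sequences.
"""
from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

#: Canonical amino-acid ordering used for all 20-wide arrays in this package.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
N_AA = 20

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
    # common non-standard residues mapped to their parent
    "MSE": "M", "SEC": "C", "PYL": "K",
}
ONE_TO_THREE = {v: k for k, v in reversed(list(THREE_TO_ONE.items()))}

# Amino-acid background frequencies of the BLOSUM62 derivation (Henikoff &
# Henikoff marginals), renormalized to sum exactly to 1.
_BG = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}
BACKGROUND = np.array([_BG[a] for a in AA_ALPHABET], dtype=float)
BACKGROUND /= BACKGROUND.sum()


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a dense 20x20 array in ``AA_ALPHABET`` order."""
    mat = substitution_matrices.load("BLOSUM62")
    out = np.empty((N_AA, N_AA), dtype=float)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            out[i, j] = mat[a, b]
    return out


BLOSUM62 = blosum62_matrix()

# Chou-Fasman conformational propensities (helix, sheet, turn); the turn
# column stands in for coil when the three are renormalized per position.
_CF = {
    #      helix  sheet  coil/turn
    "A": (1.42, 0.83, 0.66),
    "R": (0.98, 0.93, 0.95),
    "N": (0.67, 0.89, 1.56),
    "D": (1.01, 0.54, 1.46),
    "C": (0.70, 1.19, 1.19),
    "Q": (1.11, 1.10, 0.98),
    "E": (1.51, 0.37, 0.74),
    "G": (0.57, 0.75, 1.56),
    "H": (1.00, 0.87, 0.95),
    "I": (1.08, 1.60, 0.47),
    "L": (1.21, 1.30, 0.59),
    "K": (1.14, 0.74, 1.01),
    "M": (1.45, 1.05, 0.60),
    "F": (1.13, 1.38, 0.60),
    "P": (0.57, 0.55, 1.52),
    "S": (0.77, 0.75, 1.43),
    "T": (0.83, 1.19, 0.96),
    "W": (1.08, 1.37, 0.96),
    "Y": (0.69, 1.47, 1.14),
    "V": (1.06, 1.70, 0.50),
}
#: (20, 3) propensity table over SS classes (H, E, C), AA_ALPHABET row order.
SS_PROPENSITY = np.array([_CF[a] for a in AA_ALPHABET], dtype=float)

# Kyte-Doolittle hydropathy, mapped linearly onto an expected relative
# solvent accessibility in [0, 1]: the most hydrophobic residue (I, 4.5)
# maps to 0 exposure, the most hydrophilic (R, -4.5) to full exposure.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
RSA_PROPENSITY = np.array([(4.5 - _KD[a]) / 9.0 for a in AA_ALPHABET])

# Theoretical maximum accessible surface areas (A^2) per residue type
# (Tien et al. 2013), used to turn absolute exposed area into relative SA.
_MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}
MAX_ASA = np.array([_MAX_ASA[a] for a in AA_ALPHABET])
MAX_ASA_DEFAULT = float(MAX_ASA.mean())  # for unknown residue types

# Van der Waals radii (A) by element for surface-area computation.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
VDW_DEFAULT = 1.70

# Representative (phi, psi) bin centers in degrees for the three SS classes,
# used to turn SS class probabilities into torsion-angle predictions.
TORSION_CENTERS = {
    "H": (-62.0, -41.0),
    "E": (-120.0, 135.0),
    "C": (-75.0, 150.0),
}
SS_CLASSES = "HEC"
SS_CLASS_INDEX = {c: i for i, c in enumerate(SS_CLASSES)}
PHI_CENTERS = np.array([TORSION_CENTERS[c][0] for c in SS_CLASSES])
PSI_CENTERS = np.array([TORSION_CENTERS[c][1] for c in SS_CLASSES])


def encode_sequence(seq: str) -> np.ndarray:
    """Map a 20-letter amino-acid string to integer codes.

    Raises ``ValueError`` naming the first offending position for any
    character outside the standard alphabet.
    """
    try:
        return np.array([AA_INDEX[a] for a in seq], dtype=np.int64)
    except KeyError:
        for i, a in enumerate(seq):
            if a not in AA_INDEX:
                raise ValueError(
                    f"non-standard amino acid {a!r} at position {i}"
                ) from None
        raise  # pragma: no cover


def decode_sequence(idx) -> str:
    return "".join(AA_ALPHABET[i] for i in idx)
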