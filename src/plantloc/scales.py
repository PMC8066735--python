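"""Per-residue property scales, CTD groupings, and residue distance matrices.

Scalar physicochemical scales (Kyte-Doolittle hydrophobicity, Hopp-Woods
hydrophilicity, Vihinen flexibility, Emini accessibility, Janin transfer
energy, Guy transfer free energy) are loaded from Biopython's ProtParam data;
side-chain masses, heavy-atom counts and pH-dependent charges are computed
from standard residue chemistry.

The nine multi-dimensional descriptor scales exposed here (``cruciani``,
``fasgai``, ``mswhim``, ``protfp``, ``stscales``, ``tscales``, ``vhse``,
``zscales`` and the ``blosum`` block) are SYNTHETIC surrogates: orthogonal
components of a matrix of the genuine per-residue properties above (the
``blosum`` block is a principal-component decomposition of the real BLOSUM62
substitution rows). They reproduce the dimensionalities and the
hydrophobic/steric/electronic character of the published scale families
without transcribing their numeric tables, which are not redistributable
here. Downstream code treats them as opaque ``PropertyScale`` data.

Likewise the two residue *distance* matrices used by the sequence-order
descriptors are computed surrogates: ``physchem`` is the Euclidean distance
in the standardized hydrophobicity/hydrophilicity/side-chain-mass space, and
``blosum`` the Euclidean distance in the BLOSUM62 component space, each
normalized to a maximum of 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils import ProtParamData

from .seqio import AA_ALPHABET

AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


def _vec(table: dict) -> np.ndarray:
    """Order a per-residue dict into the fixed alphabetical AA order."""
    return np.array([table[aa] for aa in AA_ALPHABET], dtype=float)


# ---------------------------------------------------------------------------
# Scalar property scales
# ---------------------------------------------------------------------------

HYDROPHOBICITY_KD = dict(ProtParamData.kd)          # Kyte & Doolittle
HYDROPHILICITY_HW = dict(ProtParamData.hw)          # Hopp & Woods
FLEXIBILITY = dict(ProtParamData.Flex)              # Vihinen B-values
SURFACE_EMINI = dict(ProtParamData.em)              # Emini accessibility
JANIN = dict(ProtParamData.ja)                      # interior->surface energy
TRANSFER_GUY = dict(ProtParamData.gy)               # Guy transfer free energy
EISENBERG = dict(ProtParamData.es)                  # consensus hydrophobicity

#: Side-chain mass (Da): residue molecular weight relative to glycine + 1 H.
SIDE_CHAIN_MASS = {
    aa: protein_weights[aa] - protein_weights["G"] + 1.008 for aa in AA_ALPHABET
}

#: Side-chain heavy (non-hydrogen) atom counts.
HEAVY_ATOMS = {
    "A": 1, "R": 7, "N": 4, "D": 4, "C": 2, "Q": 5, "E": 5, "G": 0, "H": 6,
    "I": 4, "L": 4, "K": 5, "M": 4, "F": 7, "P": 3, "S": 2, "T": 3, "W": 10,
    "Y": 8, "V": 3,
}

AROMATIC = {aa: float(aa in "FWYH") for aa in AA_ALPHABET}
POLAR_ATOMS = {  # side-chain N + O count
    "A": 0, "R": 3, "N": 2, "D": 2, "C": 0, "Q": 2, "E": 2, "G": 0, "H": 2,
    "I": 0, "L": 0, "K": 1, "M": 0, "F": 0, "P": 0, "S": 1, "T": 1, "W": 1,
    "Y": 1, "V": 0,
}

#: EMBOSS-style side-chain / terminal pKa values used for charge and pI.
PKA = {
    "n_term": 8.6,
    "c_term": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}
POSITIVE_RESIDUES = ("K", "R", "H")
NEGATIVE_RESIDUES = ("D", "E", "C", "Y")


def residue_charge(aa_counts: dict, pH: float, include_termini: bool = True) -> float:
    """Net charge of a sequence (given residue counts) at a pH.

    Henderson-Hasselbalch per ionizable group under the PKA table.
    """
    pos = 1.0 / (1.0 + 10 ** (pH - PKA["n_term"])) if include_termini else 0.0
    neg = 1.0 / (1.0 + 10 ** (PKA["c_term"] - pH)) if include_termini else 0.0
    for aa in POSITIVE_RESIDUES:
        pos += aa_counts.get(aa, 0) / (1.0 + 10 ** (pH - PKA[aa]))
    for aa in NEGATIVE_RESIDUES:
        neg += aa_counts.get(aa, 0) / (1.0 + 10 ** (PKA[aa] - pH))
    return pos - neg


CHARGE_PH7 = {aa: residue_charge({aa: 1}, 7.0, include_termini=False) for aa in AA_ALPHABET}


def standardized(table: dict) -> np.ndarray:
    """Scale values standardized over the 20 residues (population sd)."""
    v = _vec(table)
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


#: The canonical property triplet behind pseudo-composition correlation
#: factors: normalized hydrophobicity, hydrophilicity, side-chain mass.
CHOU_TRIPLET = np.vstack(
    [
        standardized(HYDROPHOBICITY_KD),
        standardized(HYDROPHILICITY_HW),
        standardized(SIDE_CHAIN_MASS),
    ]
)

#: Scalar properties used for the Geary autocorrelation block (4 x nlag=10).
GEARY_PROPERTIES = {
    "hydrophobicity": HYDROPHOBICITY_KD,
    "hydrophilicity": HYDROPHILICITY_HW,
    "side_chain_mass": SIDE_CHAIN_MASS,
    "flexibility": FLEXIBILITY,
}


# ---------------------------------------------------------------------------
# CTD groupings: 7 physicochemical properties, 3 disjoint groups covering
# all 20 letters (the standard partition of the CTD descriptor literature).
# ---------------------------------------------------------------------------

CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

for _prop, _groups in CTD_GROUPS.items():
    assert sorted("".join(_groups)) == sorted(AA_ALPHABET), _prop


# ---------------------------------------------------------------------------
# Multi-dimensional scales (synthetic surrogates; see module docstring)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PropertyScale:
    """A named mapping from each of the 20 residues to a d-vector."""

    name: str
    table: dict  # aa -> np.ndarray of shape (d,)

    def __post_init__(self):
        if sorted(self.table) != sorted(AA_ALPHABET):
            raise ValueError(f"scale {self.name}: must cover exactly the 20 residues")
        dims = {len(np.atleast_1d(v)) for v in self.table.values()}
        if len(dims) != 1:
            raise ValueError(f"scale {self.name}: inconsistent dimensions {dims}")

    @property
    def d(self) -> int:
        return len(np.atleast_1d(next(iter(self.table.values()))))

    def matrix(self) -> np.ndarray:
        """(20, d) matrix in alphabetical residue order."""
        return np.vstack([np.atleast_1d(self.table[aa]) for aa in AA_ALPHABET])


def _pca_scores(base: np.ndarray) -> np.ndarray:
    """Deterministic PCA scores of a (20, p) property matrix (columns standardized)."""
    X = (base - base.mean(axis=0)) / base.std(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U * s
    # fix component signs: largest-|loading| entry positive
    for j in range(scores.shape[1]):
        k = np.argmax(np.abs(scores[:, j]))
        if scores[k, j] < 0:
            scores[:, j] *= -1
    return scores


_BASE_PROPERTIES = np.column_stack(
    [
        _vec(HYDROPHOBICITY_KD),
        _vec(HYDROPHILICITY_HW),
        _vec(FLEXIBILITY),
        _vec(SURFACE_EMINI),
        _vec(JANIN),
        _vec(TRANSFER_GUY),
        _vec(SIDE_CHAIN_MASS),
        _vec(HEAVY_ATOMS),
        _vec(CHARGE_PH7),
        _vec(AROMATIC),
        _vec(POLAR_ATOMS),
    ]
)

_PC = _pca_scores(_BASE_PROPERTIES)  # (20, 11)

# (name, dimension, rotation seed) for each surrogate scale family
_SCALE_SPECS = [
    ("cruciani", 3, 11),
    ("fasgai", 6, 23),
    ("mswhim", 3, 37),
    ("protfp", 8, 41),
    ("stscales", 8, 53),
    ("tscales", 5, 67),
    ("vhse", 8, 71),
    ("zscales", 5, 83),
]


def _rotated_scale(name: str, d: int, seed: int) -> PropertyScale:
    """Synthetic surrogate scale: first d components under a fixed rotation."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((d, d))
    Q, _ = np.linalg.qr(A)
    scores = _PC[:, :d] @ Q
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0)
    return PropertyScale(name, {aa: scores[AA_INDEX[aa]].copy() for aa in AA_ALPHABET})


MULTI_SCALES: dict[str, PropertyScale] = {
    name: _rotated_scale(name, d, seed) for name, d, seed in _SCALE_SPECS
}


def _blosum_scale() -> PropertyScale:
    """8-component decomposition of the real BLOSUM62 substitution rows."""
    m = substitution_matrices.load("BLOSUM62")
    rows = np.array(
        [[m[a, b] for b in AA_ALPHABET] for a in AA_ALPHABET], dtype=float
    )
    scores = _pca_scores(rows)[:, :8]
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0)
    return PropertyScale("blosum", {aa: scores[AA_INDEX[aa]].copy() for aa in AA_ALPHABET})


BLOSUM_SCALE = _blosum_scale()


# ---------------------------------------------------------------------------
# Residue distance matrices for sequence-order descriptors
# ---------------------------------------------------------------------------


def _normalized_distance(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    return D / D.max()


#: Distance in the standardized hydrophobicity/hydrophilicity/mass space.
DIST_PHYSCHEM = _normalized_distance(CHOU_TRIPLET.T)

#: Distance in the 8-dim BLOSUM62 component space.
DIST_BLOSUM = _normalized_distance(BLOSUM_SCALE.matrix())

DISTANCE_MATRICES: dict[str, np.ndarray] = {
    "physchem": DIST_PHYSCHEM,
    "blosum": DIST_BLOSUM,
}
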