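"""The 407-element physicochemical feature vector.

Each peptide is described by seven scalar descriptors followed by the 400
ordered dipeptide (di-amino-acid) relative frequencies:

====================  ========================================================
``mass_da``           average molecular mass in Daltons (residue masses + H2O)
``length_residues``   number of residues
``gravy``             grand average of hydropathy (Kyte-Doolittle scale)
``n_positive``        count of K, R, H residues
``n_negative``        count of D, E residues
``net_charge``        n_positive - n_negative
``frac_hydrophobic``  fraction of residues in {A, C, F, I, L, M, V, W}
``dp_AA .. dp_YY``    400 overlapping-pair frequencies, lexicographic order
====================  ========================================================

The dipeptide block of any valid peptide is non-negative and sums to 1.
Counts are residue-composition counts, not pH-dependent charges, and masses
are average (not monoisotopic) — these are descriptors for classification,
not values for spectral matching.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mucopep.io import AMINO_ACIDS, Peptide

#: Kyte-Doolittle hydropathy values per residue.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Average residue (monomer minus water) masses, Daltons.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS = 18.0153

POSITIVE_RESIDUES = frozenset("KRH")
NEGATIVE_RESIDUES = frozenset("DE")
HYDROPHOBIC_RESIDUES = frozenset("AVLIMFWC")

#: All 400 ordered residue pairs, lexicographic (AA, AC, ..., YY).
DIPEPTIDES: tuple[str, ...] = tuple(
    a + b for a, b in itertools.product(AMINO_ACIDS, repeat=2)
)

SCALAR_FEATURES: tuple[str, ...] = (
    "mass_da",
    "length_residues",
    "gravy",
    "n_positive",
    "n_negative",
    "net_charge",
    "frac_hydrophobic",
)

#: The fixed, bit-stable ordering of all 407 feature names.
FEATURE_NAMES: tuple[str, ...] = SCALAR_FEATURES + tuple(f"dp_{d}" for d in DIPEPTIDES)

_DIPEPTIDE_INDEX = {d: i for i, d in enumerate(DIPEPTIDES)}


def dipeptide_composition(p: Peptide) -> np.ndarray:
    """Relative frequency of each ordered adjacent residue pair.

    The entry for pair XY is the number of overlapping-window occurrences of
    XY divided by (length - 1); the 400 entries sum to 1.
    """
    seq = p.sequence
    counts = np.zeros(400)
    for i in range(len(seq) - 1):
        counts[_DIPEPTIDE_INDEX[seq[i : i + 2]]] += 1
    return counts / (len(seq) - 1)


def gravy(p: Peptide) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    return sum(KYTE_DOOLITTLE[a] for a in p.sequence) / len(p.sequence)


def charge_counts(p: Peptide) -> tuple[int, int, int]:
    """(n_positive, n_negative, net_charge) residue-composition counts.

    Positive residues are K, R, H; negative are D, E; termini are not
    counted as charges.
    """
    n_pos = sum(a in POSITIVE_RESIDUES for a in p.sequence)
    n_neg = sum(a in NEGATIVE_RESIDUES for a in p.sequence)
    return n_pos, n_neg, n_pos - n_neg


def molecular_mass(p: Peptide) -> float:
    """Average molecular mass in Daltons (residue masses plus one water)."""
    return sum(AVERAGE_RESIDUE_MASS[a] for a in p.sequence) + WATER_MASS


def featurize(p: Peptide) -> np.ndarray:
    """The full 407-element feature vector, ordered as ``FEATURE_NAMES``."""
    n_pos, n_neg, net = charge_counts(p)
    frac_hyd = sum(a in HYDROPHOBIC_RESIDUES for a in p.sequence) / len(p.sequence)
    scalars = [
        molecular_mass(p),
        float(len(p.sequence)),
        gravy(p),
        float(n_pos),
        float(n_neg),
        float(net),
        frac_hyd,
    ]
    return np.concatenate([scalars, dipeptide_composition(p)])


def featurize_all(peptides: Sequence[Peptide] | Iterable[Peptide]) -> pd.DataFrame:
    """Feature matrix for many peptides, indexed by peptide id."""
    peptides = list(peptides)
    mat = np.empty((len(peptides), len(FEATURE_NAMES)))
    for i, p in enumerate(peptides):
        mat[i] = featurize(p)
    return pd.DataFrame(
        mat, index=pd.Index([p.id for p in peptides], name="peptide_id"),
        columns=list(FEATURE_NAMES),
    )
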