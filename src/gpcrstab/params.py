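"""Packaged parameter tables for the energy surrogate and feature scales."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
CENTROID_ATOM = "SCC"  # side-chain centroid pseudo-atom

# van der Waals radii by element class (A); "X" is the side-chain centroid
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "X": 2.00}
LJ_EPSILON = 0.15  # kcal/mol, uniform well depth
LJ_RMIN_SCALE = 0.90  # soft-core scaling of contact radii
LJ_CUTOFF = 10.0
LJ_CAP = 10.0  # soft cap per clashing pair

COULOMB_K = 332.0637  # kcal*A/(mol*e^2)
ELEC_CUTOFF = 12.0

# atomic solvation parameters, kcal/mol/A^2
SOLV_SIGMA = {"C": 0.012, "N": -0.060, "O": -0.060, "S": 0.0, "X": 0.006}
PROBE_RADIUS = 1.4

HB_ENERGY = -2.0  # kcal/mol at ideal N...O distance
HB_IDEAL = (2.8, 3.2)
HB_RANGE = (2.4, 3.6)

PMF_CB_CUTOFF = 8.0  # Cbeta-Cbeta contact distance for the statistical term

# covalent disulfide reward inside the contact term: a Cys pair at
# bonding Cbeta-Cbeta distance gains a fixed cross-link energy
DISULFIDE_CB_MAX = 5.0
DISULFIDE_ENERGY = -4.0

# side-chain centroid distance from Cbeta (A); 0 = no centroid (Gly/Ala)
CENTROID_DISTANCE = {
    "G": 0.0, "A": 0.0, "S": 0.9, "C": 1.0, "T": 0.9, "P": 0.9, "V": 1.0,
    "D": 1.5, "N": 1.5, "I": 1.6, "L": 1.7, "M": 2.0, "E": 2.2, "Q": 2.2,
    "H": 2.2, "F": 2.4, "K": 2.9, "Y": 2.9, "W": 3.0, "R": 3.4,
}
CENTROID_ANGLE = 114.0  # CA-CB-centroid, degrees

# effective vdW radius of the centroid pseudo-atom, scaled with the
# side-chain size it stands in for (a Cys centroid is one sulfur; a Trp
# centroid a whole ring system)
CENTROID_RADIUS = {
    "S": 1.52, "C": 1.80, "T": 1.70, "P": 1.80, "V": 1.90, "D": 1.70,
    "N": 1.70, "I": 1.95, "L": 1.95, "M": 1.95, "E": 1.80, "Q": 1.80,
    "H": 2.00, "F": 2.10, "K": 1.90, "Y": 2.15, "W": 2.30, "R": 2.00,
}

POLAR_AA = frozenset("STNQYCHW")
CHARGED_AA = frozenset("DEKR")
HYDROPHOBIC_AA = frozenset("AVLIMFPG")
AROMATIC_AA = frozenset("FYWH")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def _read_packaged(name: str, **kw) -> pd.DataFrame:
    path = resources.files("gpcrstab.data") / name
    with path.open("r") as fh:
        return pd.read_csv(fh, sep="\t", comment="#", **kw)


@lru_cache(maxsize=1)
def aa_scales() -> pd.DataFrame:
    """Sequence-block residue scales, indexed by 1-letter code."""
    return _read_packaged("aa_scales.tsv").set_index("aa")


@lru_cache(maxsize=1)
def contact_potential() -> pd.DataFrame:
    """20x20 residue-contact energies (kcal/mol), symmetric."""
    return _read_packaged("contact_potential.tsv").set_index("aa")


@lru_cache(maxsize=1)
def unfolded_reference() -> dict[str, float]:
    """Per-residue unfolded-state reference energies (kcal/mol)."""
    df = _read_packaged("unfolded_ref.tsv")
    return dict(zip(df["aa"], df["energy"].astype(float)))


@lru_cache(maxsize=1)
def _charge_map() -> dict[str, float]:
    return {aa: float(c) for aa, c in aa_scales()["charge"].items()}


def residue_charge(aa: str) -> float:
    return _charge_map().get(aa, 0.0)


@lru_cache(maxsize=1)
def _contact_map() -> dict[tuple[str, str], float]:
    table = contact_potential()
    return {
        (a, b): float(table.at[a, b]) for a in table.index for b in table.columns
    }


def contact_energy(aa1: str, aa2: str) -> float:
    return _contact_map()[(aa1, aa2)]


def pair_pmf(aa1: str, aa2: str, cb_distance: float) -> float:
    """Residue-contact energy including the Cys-Cys cross-link reward."""
    e = _contact_map()[(aa1, aa2)]
    if aa1 == "C" and aa2 == "C" and cb_distance < DISULFIDE_CB_MAX:
        e += DISULFIDE_ENERGY
    return e


def element_of(atom_name: str) -> str:
    """Element class of a heavy atom from its PDB atom name."""
    if atom_name == CENTROID_ATOM:
        return "X"
    head = atom_name.strip()[0]
    return head if head in VDW_RADII else "C"


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element, 1.7)


def sphere_points(n: int = 100) -> np.ndarray:
    """Deterministic Fibonacci-lattice unit sphere points for SASA."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )
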