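"""Feature vectors describing a point mutation for the SVM classifier.

Each single-site mutation is projected onto a fixed-order feature
space with three blocks, computed for the wild-type residue in the
input model and for the mutant residue after side-chain repacking:

* sequence block (6): hydrophobicity, polarity, charge, side-chain
  volume, reference accessible surface, polarizability — packaged
  published scales (see ``data/aa_scales.tsv``);
* structure block (8): counts of polar, charged, hydrophobic and
  aromatic residue contacts, residue solvent exposure, buried contact
  area, mean packing void, relative accessible surface;
* energy block (6): potential of mean force (contact), electrostatic,
  van der Waals, solvation, hydrogen-bond and total interaction
  energies of the residue with the rest of the model.

The component order is ``FEATURE_NAMES`` and is identical for every
mutation in a run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import params
from .design import DesignConfig, repack_sidechains
from .energy import shrake_rupley_sasa
from .numbering import Mutation
from .structure import StructureModel, apply_mutation

SEQUENCE_FEATURES = (
    "hydrophobicity",
    "polarity",
    "charge",
    "volume",
    "asa_ref",
    "polarizability",
)
STRUCTURE_FEATURES = (
    "polar_contacts",
    "charged_contacts",
    "hydrophobic_contacts",
    "aromatic_contacts",
    "exposure",
    "contact_area",
    "void_volume",
    "rel_asa",
)
ENERGY_FEATURES = (
    "pmf",
    "electrostatic",
    "van_der_waals",
    "solvation",
    "hydrogen_bond",
    "total",
)
_BLOCK = SEQUENCE_FEATURES + STRUCTURE_FEATURES + ENERGY_FEATURES
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{state}_{name}" for state in ("wt", "mut") for name in _BLOCK
)
N_FEATURES = len(FEATURE_NAMES)

CONTACT_DISTANCE = 5.5  # min heavy-atom distance defining a residue contact


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-order numeric descriptor of one point mutation."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.names),):
            raise ValueError(
                f"feature vector length {v.shape} does not match schema "
                f"({len(self.names)})"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite feature values")
        object.__setattr__(self, "values", v)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


@dataclass(frozen=True)
class TrainingExample:
    mutation: Mutation
    features: FeatureVector
    label: int
    origin: str = ""

    def __post_init__(self) -> None:
        if self.label not in (+1, -1):
            raise ValueError("label must be +1 or -1")


def _sequence_block(aa: str) -> list[float]:
    scales = params.aa_scales()
    if aa not in scales.index:
        raise ValueError(f"no sequence scales for residue {aa!r}")
    return [float(scales.at[aa, k]) for k in SEQUENCE_FEATURES]


def _residue_energy_block(model: StructureModel, position: int) -> list[float]:
    """Interaction-energy terms of one residue with the rest of the model."""
    from .energy import _atom_charges  # shared parameterization

    idx = model.atom_indices(position)
    other = np.nonzero(model.res_ids != position)[0]
    terms = dict.fromkeys(
        ("pmf", "electrostatic", "van_der_waals", "solvation", "hydrogen_bond"), 0.0
    )
    if len(other):
        d = cdist(model.coords[idx], model.coords[other])
        elements = model.elements()
        q = _atom_charges(model)

        qq = q[idx][:, None] * q[other][None, :]
        m = (qq != 0) & (d < params.ELEC_CUTOFF)
        terms["electrostatic"] = float(
            np.sum(params.COULOMB_K * qq[m] / (4.0 * d[m] ** 2))
        )

        radii = model.vdw_radii()
        rmin = params.LJ_RMIN_SCALE * (radii[idx][:, None] + radii[other][None, :])
        sep = np.abs(model.res_ids[idx][:, None] - model.res_ids[other][None, :])
        bb = np.isin(model.atom_names, list(params.BACKBONE_ATOMS))
        excl = (sep == 1) & bb[idx][:, None] & bb[other][None, :]
        from .energy import disulfide_partners

        for i_pos, j_pos in disulfide_partners(model):
            if position in (i_pos, j_pos):
                partner = j_pos if position == i_pos else i_pos
                sc_self = np.isin(idx, model.sidechain_indices(position))
                sc_part = np.isin(other, model.sidechain_indices(partner))
                excl |= sc_self[:, None] & sc_part[None, :]
        m = (d < params.LJ_CUTOFF) & ~excl
        ratio = (rmin[m] / d[m]) ** 6
        terms["van_der_waals"] = float(
            np.sum(
                np.minimum(
                    params.LJ_EPSILON * (ratio**2 - 2.0 * ratio), params.LJ_CAP
                )
            )
        )

        is_n, is_o = elements == "N", elements == "O"
        no_pair = (is_n[idx][:, None] & is_o[other][None, :]) | (
            is_o[idx][:, None] & is_n[other][None, :]
        )
        m = no_pair & (sep >= 2) & (d < params.HB_RANGE[1])
        r = d[m]
        lo, hi = params.HB_RANGE
        ilo, ihi = params.HB_IDEAL
        w = np.ones_like(r)
        w[r < ilo] = (r[r < ilo] - lo) / (ilo - lo)
        w[r > ihi] = (hi - r[r > ihi]) / (hi - ihi)
        terms["hydrogen_bond"] = float(np.sum(params.HB_ENERGY * np.clip(w, 0, 1)))

        aa = model.residue_type(position)
        cb = model.cbeta(position)
        pmf = 0.0
        for pos2 in model.residues():
            if abs(pos2 - position) < 2:
                continue
            dist = float(np.linalg.norm(model.cbeta(pos2) - cb))
            if dist < params.PMF_CB_CUTOFF:
                pmf += params.pair_pmf(aa, model.residue_type(pos2), dist)
        terms["pmf"] = pmf

    sasa = shrake_rupley_sasa(model)
    sigma = np.array([params.SOLV_SIGMA[e] for e in model.elements()])
    terms["solvation"] = float(np.sum((sigma * sasa)[idx]))
    total = sum(terms.values())
    return [terms[k] for k in ENERGY_FEATURES[:-1]] + [total]


def _structure_block(model: StructureModel, position: int) -> list[float]:
    idx = model.atom_indices(position)
    aa = model.residue_type(position)
    counts = {"polar": 0, "charged": 0, "hydrophobic": 0, "aromatic": 0}
    gaps: list[float] = []
    radii_all = model.vdw_radii()
    for pos2 in model.residues():
        if abs(pos2 - position) < 2:
            continue
        jdx = model.atom_indices(pos2)
        d = cdist(model.coords[idx], model.coords[jdx])
        dmin = float(d.min())
        if dmin >= CONTACT_DISTANCE:
            continue
        aa2 = model.residue_type(pos2)
        if aa2 in params.POLAR_AA:
            counts["polar"] += 1
        if aa2 in params.CHARGED_AA:
            counts["charged"] += 1
        if aa2 in params.HYDROPHOBIC_AA:
            counts["hydrophobic"] += 1
        if aa2 in params.AROMATIC_AA:
            counts["aromatic"] += 1
        i0, j0 = np.unravel_index(int(d.argmin()), d.shape)
        gaps.append(
            max(dmin - radii_all[idx[i0]] - radii_all[jdx[j0]], 0.0)
        )
    sasa = shrake_rupley_sasa(model)
    exposure = float(sasa[idx].sum())
    ref = float(params.aa_scales().at[aa, "asa_ref"])
    contact_area = max(ref - exposure, 0.0)
    void = float(np.mean(gaps)) if gaps else 0.0
    rel_asa = exposure / ref
    return [
        float(counts["polar"]),
        float(counts["charged"]),
        float(counts["hydrophobic"]),
        float(counts["aromatic"]),
        exposure,
        contact_area,
        void,
        rel_asa,
    ]


def _residue_block(model: StructureModel, position: int) -> list[float]:
    aa = model.residue_type(position)
    return (
        _sequence_block(aa)
        + _structure_block(model, position)
        + _residue_energy_block(model, position)
    )


def extract_features(
    model: StructureModel,
    mutation: Mutation,
    seed: int,
    config: DesignConfig | None = None,
) -> FeatureVector:
    """Feature vector for a single-site mutation.

    The mutant residue is placed by side-chain repacking before its
    structure and energy blocks are computed.  A degenerate mutation
    (mut == wt, rejected by :class:`Mutation` itself) would give
    identical blocks by construction.
    """
    if len(mutation.sites) != 1:
        raise ValueError("features are defined for single-site mutations")
    site = mutation.sites[0]
    if site.position not in model.residues():
        raise ValueError(f"position {site.position} not in model")
    wt_block = _residue_block(model, site.position)
    mut_model = repack_sidechains(
        apply_mutation(model, mutation), {site.position}, seed, config
    )
    mut_block = _residue_block(mut_model, site.position)
    return FeatureVector(values=np.array(wt_block + mut_block))


def assemble_benchmark(
    records: pd.DataFrame,
    structures: dict[str, StructureModel],
    seed: int = 0,
    extractor=extract_features,
) -> list[TrainingExample]:
    """Build labeled training examples from mutation tables.

    ``records`` columns: receptor, position, wt, mut, stabilizing
    (boolean).  Stabilizing mutations become +1 examples and their
    reverses -1; remaining (alanine-scan style) mutations become -1.
    The reverse example approximates the back mutation on the
    wild-type backbone.
    """
    required = {"receptor", "position", "wt", "mut", "stabilizing"}
    if not required.issubset(records.columns):
        raise ValueError(f"benchmark records need columns {sorted(required)}")
    unknown = sorted(set(records["receptor"]) - set(structures))
    if unknown:
        raise ValueError(f"records reference unknown receptors: {unknown}")
    out: list[TrainingExample] = []
    for row in records.itertuples():
        model = structures[row.receptor]
        fwd = Mutation.single(int(row.position), row.wt, row.mut)
        if bool(row.stabilizing):
            out.append(
                TrainingExample(
                    mutation=fwd,
                    features=extractor(model, fwd, seed),
                    label=+1,
                    origin=row.receptor,
                )
            )
            rev = Mutation.single(int(row.position), row.mut, row.wt)
            rev_base = apply_mutation(model, fwd)
            out.append(
                TrainingExample(
                    mutation=rev,
                    features=extractor(rev_base, rev, seed),
                    label=-1,
                    origin=row.receptor,
                )
            )
        else:
            out.append(
                TrainingExample(
                    mutation=fwd,
                    features=extractor(model, fwd, seed),
                    label=-1,
                    origin=row.receptor,
                )
            )
    return out


def feature_matrix(
    examples: list[TrainingExample],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack examples into (X, y) arrays for the classifier."""
    X = np.vstack([ex.features.values for ex in examples])
    y = np.array([ex.label for ex in examples])
    return X, y
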