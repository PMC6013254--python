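"""Empirical energy surrogate for the folded/unfolded stability comparison.

A mutation is accepted by the structure lane when it improves the
predicted folding free energy,

    E_folded(mut) - E_unfolded(mut)  <  E_folded(wt) - E_unfolded(wt).

The folded-state energy is a sum of physically motivated terms computed
over heavy atoms (full-atom or centroid-coarse side chains):

* electrostatic — Coulomb between formal side-chain charges with a
  distance-dependent dielectric eps(r) = 4r (so E ~ q_i q_j / 4 r^2),
  12 A cutoff;
* van der Waals — 12-6 Lennard-Jones on element-class radii, capped
  per pair so clashes stay finite, 10 A cutoff;
* solvation — atomic solvation parameter times Shrake-Rupley
  solvent-accessible area (exposed apolar area is penalized, exposed
  polar area rewarded);
* hydrogen bond — distance well on heavy-atom N...O pairs;
* pmf — residue-contact statistical term on Cbeta-Cbeta contacts from
  a packaged 20x20 table.

The unfolded state is a sum of packaged per-residue reference
constants.  Absolute values are in arbitrary kcal/mol-scale units; only
the wt/mut comparison above is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from . import params
from .structure import StructureError, StructureModel

TERM_NAMES = ("electrostatic", "van_der_waals", "solvation", "hydrogen_bond", "pmf")


@dataclass
class EnergyBreakdown:
    """Folded/unfolded energies and the folded-state term decomposition."""

    folded: float
    unfolded: float
    terms: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(v for k, v in self.terms.items() if k != "total")
        if abs(total - self.terms.get("total", total)) > 1e-6:
            raise ValueError("term sum does not match reported total")

    @property
    def delta(self) -> float:
        """Predicted folding free energy E_folded - E_unfolded."""
        return self.folded - self.unfolded


def stability_accept(wt: EnergyBreakdown, mut: EnergyBreakdown) -> bool:
    """Strict improvement of the predicted folding free energy."""
    return mut.delta < wt.delta


# -- geometry-independent helpers ---------------------------------------


def _atom_charges(model: StructureModel) -> np.ndarray:
    """Formal side-chain charges, carried by the outermost side-chain atom.

    For coarse side chains this is the centroid; for full-atom side
    chains the charge sits on the terminal charged-group atom.
    """
    if "charges" in model._derived:
        return model._derived["charges"]
    charges = np.zeros(model.n_atoms)
    terminal = {"D": "OD2", "E": "OE2", "K": "NZ", "R": "NH1"}
    for pos in model.residues():
        aa = model.residue_type(pos)
        q = params.residue_charge(aa)
        if q == 0:
            continue
        idx = model.atom_indices(pos)
        names = model.atom_names[idx]
        for candidate in (params.CENTROID_ATOM, terminal.get(aa, ""), "CB", "CA"):
            hit = idx[names == candidate]
            if len(hit):
                charges[hit[0]] = q
                break
    model._derived["charges"] = charges
    return charges


def disulfide_partners(model: StructureModel) -> list[tuple[int, int]]:
    """Cys pairs at cross-linking Cbeta distance, treated as bonded."""
    cys = [p for p in model.residues() if model.residue_type(p) == "C"]
    out = []
    for a in range(len(cys)):
        for b in range(a + 1, len(cys)):
            i, j = cys[a], cys[b]
            if abs(i - j) < 2:
                continue
            if (
                np.linalg.norm(model.cbeta(i) - model.cbeta(j))
                < params.DISULFIDE_CB_MAX
            ):
                out.append((i, j))
    return out


def _exclusion_mask(model: StructureModel) -> np.ndarray:
    """Pairs to skip: same residue, backbone-backbone of neighbours, and
    side chains of cross-linked Cys pairs (covalently bonded)."""
    rid = model.res_ids
    same = rid[:, None] == rid[None, :]
    adjacent = np.abs(rid[:, None] - rid[None, :]) == 1
    backbone = np.isin(model.atom_names, list(params.BACKBONE_ATOMS))
    bb_pair = backbone[:, None] & backbone[None, :]
    excl = same | (adjacent & bb_pair)
    for i, j in disulfide_partners(model):
        sc_i = model.sidechain_indices(i)
        sc_j = model.sidechain_indices(j)
        excl[np.ix_(sc_i, sc_j)] = True
        excl[np.ix_(sc_j, sc_i)] = True
    return excl


def shrake_rupley_sasa(model: StructureModel, n_points: int = 100) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2)."""
    n = model.n_atoms
    if n == 0:
        return np.zeros(0)
    radii = model.vdw_radii() + params.PROBE_RADIUS
    pts = params.sphere_points(n_points)
    coords = model.coords
    d = cdist(coords, coords)
    sasa = np.zeros(n)
    for i in range(n):
        neighbors = np.nonzero((d[i] < radii[i] + radii) & (np.arange(n) != i))[0]
        surface = coords[i] + radii[i] * pts
        if len(neighbors):
            dn = cdist(surface, coords[neighbors])
            buried = np.any(dn < radii[neighbors][None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        sasa[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    return sasa


# -- term evaluations ----------------------------------------------------


def _pair_terms(model: StructureModel) -> dict[str, float]:
    n = model.n_atoms
    out = {"electrostatic": 0.0, "van_der_waals": 0.0, "hydrogen_bond": 0.0}
    if n < 2:
        return out
    d = cdist(model.coords, model.coords)
    np.fill_diagonal(d, np.inf)
    excl = _exclusion_mask(model)
    upper = np.triu(np.ones((n, n), dtype=bool), k=1) & ~excl

    # electrostatic, eps(r) = 4r
    q = _atom_charges(model)
    qq = q[:, None] * q[None, :]
    mask = upper & (qq != 0) & (d < params.ELEC_CUTOFF)
    out["electrostatic"] = float(
        np.sum(params.COULOMB_K * qq[mask] / (4.0 * d[mask] ** 2))
    )

    # Lennard-Jones
    radii = model.vdw_radii()
    rmin = params.LJ_RMIN_SCALE * (radii[:, None] + radii[None, :])
    mask = upper & (d < params.LJ_CUTOFF)
    ratio = (rmin[mask] / d[mask]) ** 6
    lj = params.LJ_EPSILON * (ratio**2 - 2.0 * ratio)
    out["van_der_waals"] = float(np.sum(np.minimum(lj, params.LJ_CAP)))

    # hydrogen bonds: N...O heavy-atom pairs, sequence separation >= 2
    elements = model.elements()
    is_n = elements == "N"
    is_o = elements == "O"
    rid = model.res_ids
    sep_ok = np.abs(rid[:, None] - rid[None, :]) >= 2
    no_pair = (is_n[:, None] & is_o[None, :]) | (is_o[:, None] & is_n[None, :])
    mask = upper & sep_ok & no_pair & (d < params.HB_RANGE[1])
    r = d[mask]
    lo, hi = params.HB_RANGE
    ideal_lo, ideal_hi = params.HB_IDEAL
    w = np.ones_like(r)
    left = r < ideal_lo
    right = r > ideal_hi
    w[left] = (r[left] - lo) / (ideal_lo - lo)
    w[right] = (hi - r[right]) / (hi - ideal_hi)
    out["hydrogen_bond"] = float(np.sum(params.HB_ENERGY * np.clip(w, 0, 1)))
    return out


def _pmf_term(model: StructureModel) -> float:
    residues = model.residues()
    if len(residues) < 2:
        return 0.0
    cbs = np.array([model.cbeta(p) for p in residues])
    aas = [model.residue_type(p) for p in residues]
    d = cdist(cbs, cbs)
    total = 0.0
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            if abs(residues[i] - residues[j]) < 2:
                continue
            if d[i, j] < params.PMF_CB_CUTOFF:
                total += params.pair_pmf(aas[i], aas[j], float(d[i, j]))
    return total


def _unfolded_energy(model: StructureModel) -> float:
    ref = params.unfolded_reference()
    total = 0.0
    for pos in model.residues():
        aa = model.residue_type(pos)
        if aa not in ref:
            raise StructureError(f"no unfolded reference for residue type {aa!r}")
        total += ref[aa]
    return total


def surrogate_energy(
    model: StructureModel, sasa: np.ndarray | None = None
) -> EnergyBreakdown:
    """Full folded/unfolded energy breakdown of a model."""
    terms = _pair_terms(model)
    if sasa is None:
        sasa = shrake_rupley_sasa(model)
    sigma = np.array([params.SOLV_SIGMA[e] for e in model.elements()])
    terms["solvation"] = float(np.sum(sigma * sasa))
    terms["pmf"] = _pmf_term(model)
    terms["total"] = sum(terms[t] for t in TERM_NAMES)
    return EnergyBreakdown(
        folded=terms["total"],
        unfolded=_unfolded_energy(model) if model.n_atoms else 0.0,
        terms=terms,
    )


def sidechain_interaction_energy(model: StructureModel, position: int) -> float:
    """Pairwise terms (elec + LJ + hbond + pmf contacts) between one
    residue's side chain and the rest of the model.

    Cheap local objective for the rotamer search; solvation is left to
    the full evaluation that brackets the search.
    """
    sc = model.sidechain_indices(position)
    if len(sc) == 0:
        return 0.0
    other = np.setdiff1d(
        np.nonzero(model.res_ids != position)[0], sc, assume_unique=False
    )
    if model.residue_type(position) == "C":
        for i, j in disulfide_partners(model):
            partner = j if i == position else i if j == position else None
            if partner is not None:
                other = np.setdiff1d(other, model.sidechain_indices(partner))
    if len(other) == 0:
        return 0.0
    d = cdist(model.coords[sc], model.coords[other])
    elements = model.elements()
    q = _atom_charges(model)

    total = 0.0
    qq = q[sc][:, None] * q[other][None, :]
    mask = (qq != 0) & (d < params.ELEC_CUTOFF)
    total += float(np.sum(params.COULOMB_K * qq[mask] / (4.0 * d[mask] ** 2)))

    radii = model.vdw_radii()
    rmin = params.LJ_RMIN_SCALE * (radii[sc][:, None] + radii[other][None, :])
    mask = d < params.LJ_CUTOFF
    ratio = (rmin[mask] / d[mask]) ** 6
    total += float(
        np.sum(np.minimum(params.LJ_EPSILON * (ratio**2 - 2.0 * ratio), params.LJ_CAP))
    )

    is_n = elements == "N"
    is_o = elements == "O"
    sep = np.abs(model.res_ids[sc][:, None] - model.res_ids[other][None, :])
    no_pair = (is_n[sc][:, None] & is_o[other][None, :]) | (
        is_o[sc][:, None] & is_n[other][None, :]
    )
    mask = no_pair & (sep >= 2) & (d < params.HB_RANGE[1])
    r = d[mask]
    lo, hi = params.HB_RANGE
    ideal_lo, ideal_hi = params.HB_IDEAL
    w = np.ones_like(r)
    w[r < ideal_lo] = (r[r < ideal_lo] - lo) / (ideal_lo - lo)
    w[r > ideal_hi] = (hi - r[r > ideal_hi]) / (hi - ideal_hi)
    total += float(np.sum(params.HB_ENERGY * np.clip(w, 0, 1)))

    # residue-level contact term for this residue
    aa = model.residue_type(position)
    cb = model.cbeta(position)
    for pos2 in model.residues():
        if abs(pos2 - position) < 2:
            continue
        dist = float(np.linalg.norm(model.cbeta(pos2) - cb))
        if dist < params.PMF_CB_CUTOFF:
            total += params.pair_pmf(aa, model.residue_type(pos2), dist)
    return total
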