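"""Structure-based lane: engineered ionic locks and disulfide bridges.

Residue pairs that could form a salt bridge when replaced by charged
residues, or a disulfide bond when replaced by cysteines, restrain the
conformational flexibility of the helical bundle.  Candidate pairs are
found by geometric screens:

* ionic lock — sequence separation >= 5 (excludes same-helix pairs),
  Cbeta-Cbeta distance in [7.0, 10.0] A, and both side chains oriented
  inward (Cbeta no farther from the bundle axis than Calpha) and toward
  each other (Calpha->Cbeta vector within 90 degrees of the
  inter-Cbeta vector); each hit proposes the four charged pairs
  E-K, E-R, D-K, D-R in both site orders.
* disulfide — sequence separation >= 5, Cbeta-Cbeta distance in
  [3.4, 4.7] A, and an idealized Sgamma placement giving a chi3
  dihedral within +/-30 degrees of +/-87 degrees; each hit proposes
  the double-cysteine mutation.

Survivors are side-chain repacked and kept only if they improve the
predicted folding free energy (see :mod:`gpcrstab.energy`); the score
is the predicted improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import params
from .energy import (
    sidechain_interaction_energy,
    stability_accept,
    surrogate_energy,
)
from .geometry import angular_diff, dihedral, place_atom, unit
from .numbering import Mutation, MutationSite, ScoredMutation
from .structure import StructureModel, apply_mutation, set_sidechain, sidechain_chi

MODULE_NAME = "structure"

CHARGED_PAIRS = (("E", "K"), ("E", "R"), ("D", "K"), ("D", "R"))

SG_BOND = 1.81  # Cbeta-Sgamma bond length, A
SG_ANGLE = 104.15  # Calpha-Cbeta-Sgamma angle, degrees


@dataclass(frozen=True)
class DesignConfig:
    """Geometry and search thresholds for the structure lane."""

    min_separation: int = 5
    ionic_cb_range: tuple[float, float] = (7.0, 10.0)
    disulfide_cb_range: tuple[float, float] = (3.4, 4.7)
    chi3_center: float = 87.0
    chi3_tolerance: float = 30.0
    shell_radius: float = 5.0
    repack_steps: int = 150
    repack_temperature: float = 1.0
    n_chi_states: int = 12

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("ionic_cb_range", "disulfide_cb_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class CandidatePair:
    """A residue pair proposed as an engineered bridge."""

    kind: str  # "ionic_lock" | "disulfide"
    residues: tuple[tuple[int, str], tuple[int, str]]
    cb_distance: float
    sequence_separation: int
    proposed_mutations: list[Mutation] = field(default_factory=list)
    geometry: dict[str, float] = field(default_factory=dict)

    @property
    def positions(self) -> tuple[int, int]:
        return self.residues[0][0], self.residues[1][0]


# -- orientation tests ---------------------------------------------------


def _inward(model: StructureModel, pos: int) -> bool:
    return model.radial(model.cbeta(pos)) <= model.radial(model.coord(pos, "CA")) + 1e-9


def _facing_dot(model: StructureModel, pos_a: int, pos_b: int) -> float:
    cb_a, cb_b = model.cbeta(pos_a), model.cbeta(pos_b)
    ca_a = model.coord(pos_a, "CA")
    return float(np.dot(unit(cb_a - ca_a), unit(cb_b - cb_a)))


def _pair_sites(model: StructureModel, i: int, j: int) -> tuple:
    return ((i, model.residue_type(i)), (j, model.residue_type(j)))


def _charged_pair_mutations(
    model: StructureModel, pos_a: int, pos_b: int
) -> list[Mutation]:
    """Mutations realizing one of the four charged pairs in both orders;
    a site whose wild type already matches the target is left unmutated."""
    ann = model.annotation
    gn = (lambda p: ann.generic_number(p)) if ann else (lambda p: None)
    out: list[Mutation] = []
    seen: set[str] = set()
    for acid, base in CHARGED_PAIRS:
        for p_acid, p_base in ((pos_a, pos_b), (pos_b, pos_a)):
            sites = []
            for p, target in ((p_acid, acid), (p_base, base)):
                wt = model.residue_type(p)
                if wt != target:
                    sites.append(MutationSite(p, wt, target, gn(p)))
            if not sites:  # pair already exists
                continue
            mut = Mutation(tuple(sorted(sites, key=lambda s: s.position)))
            if mut.label not in seen:
                seen.add(mut.label)
                out.append(mut)
    return out


def find_ionic_lock_candidates(
    model: StructureModel, config: DesignConfig | None = None
) -> list[CandidatePair]:
    """Scan all residue pairs for the ionic-lock geometry screen."""
    config = config or DesignConfig()
    if model.membrane_frame is None:
        raise ValueError("membrane frame must be set for orientation tests")
    residues = model.residues()
    lo, hi = config.ionic_cb_range
    cbs = {p: model.cbeta(p) for p in residues}
    out: list[CandidatePair] = []
    for ai, i in enumerate(residues):
        for j in residues[ai + 1 :]:
            sep = abs(j - i)
            if sep < config.min_separation:
                continue
            d = float(np.linalg.norm(cbs[i] - cbs[j]))
            if not lo <= d <= hi:
                continue
            if not (_inward(model, i) and _inward(model, j)):
                continue
            dot_ij = _facing_dot(model, i, j)
            dot_ji = _facing_dot(model, j, i)
            if dot_ij <= 0 or dot_ji <= 0:
                continue
            out.append(
                CandidatePair(
                    kind="ionic_lock",
                    residues=_pair_sites(model, i, j),
                    cb_distance=d,
                    sequence_separation=sep,
                    proposed_mutations=_charged_pair_mutations(model, i, j),
                    geometry={"facing_dot_ab": dot_ij, "facing_dot_ba": dot_ji},
                )
            )
    return out


def idealized_chi3(model: StructureModel, pos_a: int, pos_b: int) -> float:
    """chi3 dihedral Cb-Sg-Sg-Cb with each Sgamma placed ideally from
    the backbone, tilted toward the partner's Cbeta."""
    sg = {}
    for p, q in ((pos_a, pos_b), (pos_b, pos_a)):
        ca = model.coord(p, "CA")
        cb = model.cbeta(p)
        toward = model.cbeta(q)
        a = unit(ca - cb)
        u = toward - cb
        w = u - np.dot(u, a) * a
        if np.linalg.norm(w) < 1e-9:
            w = np.cross(a, np.array([1.0, 0.0, 0.0]))
        w = unit(w)
        ang = np.radians(SG_ANGLE)
        direction = np.cos(ang) * a + np.sin(ang) * w
        sg[p] = cb + SG_BOND * direction
    return dihedral(model.cbeta(pos_a), sg[pos_a], sg[pos_b], model.cbeta(pos_b))


def find_disulfide_candidates(
    model: StructureModel, config: DesignConfig | None = None
) -> list[CandidatePair]:
    """Scan all residue pairs for the engineered-disulfide screen."""
    config = config or DesignConfig()
    residues = model.residues()
    lo, hi = config.disulfide_cb_range
    cbs = {p: model.cbeta(p) for p in residues}
    ann = model.annotation
    gn = (lambda p: ann.generic_number(p)) if ann else (lambda p: None)
    out: list[CandidatePair] = []
    for ai, i in enumerate(residues):
        for j in residues[ai + 1 :]:
            sep = abs(j - i)
            if sep < config.min_separation:
                continue
            d = float(np.linalg.norm(cbs[i] - cbs[j]))
            if not lo <= d <= hi:
                continue
            chi3 = idealized_chi3(model, i, j)
            if (
                angular_diff(chi3, config.chi3_center) > config.chi3_tolerance
                and angular_diff(chi3, -config.chi3_center) > config.chi3_tolerance
            ):
                continue
            sites = [
                MutationSite(p, model.residue_type(p), "C", gn(p))
                for p in (i, j)
                if model.residue_type(p) != "C"
            ]
            if not sites:
                continue
            out.append(
                CandidatePair(
                    kind="disulfide",
                    residues=_pair_sites(model, i, j),
                    cb_distance=d,
                    sequence_separation=sep,
                    proposed_mutations=[Mutation(tuple(sites))],
                    geometry={"chi3": chi3},
                )
            )
    return out


def pairs_frame(pairs: list[CandidatePair]):
    """Candidate pairs with geometry diagnostics as a DataFrame (for TSV
    export)."""
    import pandas as pd

    rows = []
    for p in pairs:
        (pos_a, wt_a), (pos_b, wt_b) = p.residues
        rows.append(
            {
                "kind": p.kind,
                "residue_a": f"{wt_a}{pos_a}",
                "residue_b": f"{wt_b}{pos_b}",
                "cb_distance": round(p.cb_distance, 3),
                "sequence_separation": p.sequence_separation,
                "proposed_mutations": ";".join(
                    m.label for m in p.proposed_mutations
                ),
                **{k: round(v, 3) for k, v in p.geometry.items()},
            }
        )
    columns = [
        "kind",
        "residue_a",
        "residue_b",
        "cb_distance",
        "sequence_separation",
        "proposed_mutations",
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=columns)
    return df


# -- side-chain repacking ------------------------------------------------


def _neighbor_shell(
    model: StructureModel, sites: set[int], radius: float
) -> set[int]:
    """Residues with any heavy atom within ``radius`` of a site's side
    chain (falling back to Cbeta/Calpha for Gly/Ala sites)."""
    probe_coords = []
    for p in sites:
        sc = model.sidechain_indices(p)
        if len(sc):
            probe_coords.append(model.coords[sc])
        else:
            probe_coords.append(model.cbeta(p)[None, :])
    if not probe_coords:
        return set()
    probes = np.vstack(probe_coords)
    d = np.linalg.norm(
        model.coords[:, None, :] - probes[None, :, :], axis=2
    ).min(axis=1)
    return {int(r) for r in np.unique(model.res_ids[d <= radius])}


def repack_sidechains(
    model: StructureModel,
    sites: set[int],
    seed: int,
    config: DesignConfig | None = None,
) -> StructureModel:
    """Seeded discrete-rotamer Metropolis repack of ``sites`` and their
    neighbor shell, with a final greedy quench.

    Side chains of movable residues are coarse-grained to centroid
    representation and re-placed over ``n_chi_states`` evenly spaced
    chi dihedrals.  Gly/Ala have no rotamers and stay rigid.  The
    backbone is untouched, the search is deterministic given the seed,
    and the returned model never has higher full surrogate energy than
    the repack starting point (best-of guard).
    """
    config = config or DesignConfig()
    if not sites:
        return model.copy()
    shell = _neighbor_shell(model, set(sites), config.shell_radius)
    movable = sorted(
        p
        for p in (set(sites) | shell)
        if params.CENTROID_DISTANCE.get(model.residue_type(p), 0.0) > 0
    )
    if not movable:
        return model.copy()

    # coarse-grain movable side chains, preserving their current chi
    work = model
    for p in movable:
        work = set_sidechain(work, p, work.residue_type(p), sidechain_chi(work, p))
    start = work.copy()
    start_energy = surrogate_energy(start).folded

    rng = np.random.default_rng(seed)
    chis = np.linspace(-180.0, 180.0, config.n_chi_states, endpoint=False)

    # centroid placement per movable residue and chi state is fixed
    # geometry (N, CA, CB do not move): precompute, then move in place
    cen_idx: dict[int, int] = {}
    chi_coords: dict[int, np.ndarray] = {}
    for p in movable:
        idx = work.atom_indices(p)
        hit = idx[work.atom_names[idx] == params.CENTROID_ATOM]
        cen_idx[p] = int(hit[0])
        n, ca = work.coord(p, "N"), work.coord(p, "CA")
        cb = work.cbeta(p)
        d = params.CENTROID_DISTANCE[work.residue_type(p)]
        chi_coords[p] = np.array(
            [
                place_atom(n, ca, cb, d, params.CENTROID_ANGLE, float(chi))
                for chi in chis
            ]
        )

    for _ in range(config.repack_steps):
        p = movable[rng.integers(len(movable))]
        state = int(rng.integers(len(chis)))
        old = work.coords[cen_idx[p]].copy()
        before = sidechain_interaction_energy(work, p)
        work.coords[cen_idx[p]] = chi_coords[p][state]
        after = sidechain_interaction_energy(work, p)
        delta = after - before
        if not (
            delta <= 0 or rng.random() < np.exp(-delta / config.repack_temperature)
        ):
            work.coords[cen_idx[p]] = old

    # greedy quench
    for p in movable:
        energies = []
        for state in range(len(chis)):
            work.coords[cen_idx[p]] = chi_coords[p][state]
            energies.append(sidechain_interaction_energy(work, p))
        work.coords[cen_idx[p]] = chi_coords[p][int(np.argmin(energies))]

    if surrogate_energy(work).folded > start_energy:
        return start
    return work


# -- proposal ------------------------------------------------------------


def propose_structure_mutations(
    model: StructureModel,
    seed: int,
    config: DesignConfig | None = None,
    energy_fn=surrogate_energy,
) -> list[ScoredMutation]:
    """Geometry candidates from both screens, repacked and kept only on
    strict improvement of the predicted folding free energy.

    The score is wtDelta - mutDelta (positive = predicted stabilizing).
    The same mutation reachable through several pairs keeps its best
    score.
    """
    config = config or DesignConfig()
    pairs = find_ionic_lock_candidates(model, config) + find_disulfide_candidates(
        model, config
    )
    best: dict[str, ScoredMutation] = {}
    for pair in pairs:
        sites = set(pair.positions)
        wt_model = repack_sidechains(model, sites, seed, config)
        wt_e = energy_fn(wt_model)
        for mutation in pair.proposed_mutations:
            mut_model = repack_sidechains(
                apply_mutation(model, mutation), sites, seed, config
            )
            mut_e = energy_fn(mut_model)
            if not stability_accept(wt_e, mut_e):
                continue
            score = wt_e.delta - mut_e.delta
            sm = ScoredMutation(
                mutation=mutation,
                module_scores={MODULE_NAME: score},
                provenance=[MODULE_NAME],
                flags=frozenset({pair.kind}),
            )
            prev = best.get(mutation.label)
            if prev is None or score > prev.module_scores[MODULE_NAME]:
                best[mutation.label] = sm
    return sorted(
        best.values(), key=lambda s: -s.module_scores[MODULE_NAME]
    )
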