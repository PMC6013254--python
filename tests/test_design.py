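"""Geometric screens, repacking, and the stability criterion."""

import numpy as np
import pytest

from gpcrstab.design import (
    DesignConfig,
    find_disulfide_candidates,
    find_ionic_lock_candidates,
    idealized_chi3,
    propose_structure_mutations,
    repack_sidechains,
)
from gpcrstab.energy import (
    EnergyBreakdown,
    stability_accept,
    surrogate_energy,
)
from gpcrstab.fixtures import BundleSpec, synth_bundle
from gpcrstab.structure import MembraneFrame, StructureModel

CFG = DesignConfig()


# -- independent all-pairs oracle (naive re-statement of the screens) ----


def _radial(point, center):
    d = np.asarray(point) - np.asarray(center)
    return float(np.hypot(d[0], d[1]))  # frame normal is z in fixtures


def oracle_ionic_pairs(model):
    res = model.residues()
    center = model.membrane_frame.center_vec
    hits = set()
    for a in range(len(res)):
        for b in range(a + 1, len(res)):
            i, j = res[a], res[b]
            if abs(i - j) < 5:
                continue
            cbi, cbj = model.cbeta(i), model.cbeta(j)
            d = float(np.linalg.norm(cbi - cbj))
            if not 7.0 <= d <= 10.0:
                continue
            cai, caj = model.coord(i, "CA"), model.coord(j, "CA")
            if _radial(cbi, center) > _radial(cai, center) + 1e-9:
                continue
            if _radial(cbj, center) > _radial(caj, center) + 1e-9:
                continue
            vi = cbi - cai
            vj = cbj - caj
            if np.dot(vi, cbj - cbi) <= 0 or np.dot(vj, cbi - cbj) <= 0:
                continue
            hits.add((i, j))
    return hits


def oracle_disulfide_pairs(model):
    hits = set()
    res = model.residues()
    for a in range(len(res)):
        for b in range(a + 1, len(res)):
            i, j = res[a], res[b]
            if abs(i - j) < 5:
                continue
            d = float(np.linalg.norm(model.cbeta(i) - model.cbeta(j)))
            if not 3.4 <= d <= 4.7:
                continue
            chi3 = idealized_chi3(model, i, j)
            folded = abs((abs(chi3) - 87.0 + 180.0) % 360.0 - 180.0)
            if folded > 30.0:
                continue
            if model.residue_type(i) == "C" and model.residue_type(j) == "C":
                continue
            hits.add((i, j))
    return hits


class TestGeometryScreens:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_screens_match_naive_oracle(self, seed):
        model, _ = synth_bundle(BundleSpec(seed=seed))
        il = {c.positions for c in find_ionic_lock_candidates(model)}
        assert il == oracle_ionic_pairs(model)
        ss = {c.positions for c in find_disulfide_candidates(model)}
        assert ss == oracle_disulfide_pairs(model)

    def test_emitted_pairs_satisfy_printed_criteria_by_remeasurement(
        self, small_bundle
    ):
        model, _ = small_bundle
        for cand in find_ionic_lock_candidates(model):
            i, j = cand.positions
            assert cand.sequence_separation >= 5
            d = np.linalg.norm(model.cbeta(i) - model.cbeta(j))
            assert 7.0 <= d <= 10.0
            assert cand.cb_distance == pytest.approx(float(d))

    def test_ionic_pair_proposes_all_charged_pair_schemes(self, small_bundle):
        model, _ = small_bundle
        cand = find_ionic_lock_candidates(model)[0]
        # both orders of E-K, E-R, D-K, D-R (duplicates collapsed when
        # a wild type already matches)
        assert 1 <= len(cand.proposed_mutations) <= 8
        for m in cand.proposed_mutations:
            targets = {s.mut_aa for s in m.sites}
            assert targets <= {"D", "E", "K", "R"}

    def test_disulfide_candidates_propose_double_cysteine(self, tiny_bundle):
        model, _ = tiny_bundle
        cands = find_disulfide_candidates(model)
        assert cands, "tight two-helix bundle must show a disulfide window"
        for c in cands:
            muts = {s.mut_aa for m in c.proposed_mutations for s in m.sites}
            assert muts == {"C"}

    def test_same_helix_neighbours_never_emitted(self, small_bundle):
        model, _ = small_bundle
        for cand in find_ionic_lock_candidates(model):
            assert cand.sequence_separation >= 5

    def test_single_helix_has_no_ionic_locks(self):
        model, _ = synth_bundle(BundleSpec(n_helices=1, residues_per_helix=20))
        assert find_ionic_lock_candidates(model) == []


class TestStabilityAccept:
    def _bd(self, folded, unfolded=0.0):
        return EnergyBreakdown(
            folded=folded,
            unfolded=unfolded,
            terms={"pmf": folded, "total": folded},
        )

    def test_strict_improvement(self):
        assert stability_accept(self._bd(-3.0), self._bd(-5.0))

    def test_equality_rejected(self):
        assert not stability_accept(self._bd(-3.0), self._bd(-3.0))

    def test_identity_mutation_rejected(self):
        wt = self._bd(-3.0)
        assert not stability_accept(wt, wt)

    def test_antisymmetric_except_at_equality(self):
        a, b = self._bd(-5.0), self._bd(-3.0)
        assert stability_accept(b, a) != stability_accept(a, b)


class TestSurrogateEnergy:
    def _two_charges(self, distance):
        """An Asp and a Lys centroid pair at a given separation."""
        coords, names, res_ids, res_names = [], [], [], []
        for rid, aa, x in ((1, "D", 0.0), (5, "K", distance)):
            for name, offset in (
                ("N", (-1.2, -1.0, 0)),
                ("CA", (-0.6, 0, 0)),
                ("C", (-1.2, 1.0, 0)),
                ("O", (-1.2, 2.2, 0)),
                ("CB", (0.6, 0, 0)),
                ("SCC", (0, 0, 0)),
            ):
                res_ids.append(rid)
                res_names.append(aa)
                names.append(name)
                coords.append(np.array(offset) + np.array([x, 0, 0.0]))
        return StructureModel(
            res_ids=np.array(res_ids),
            res_names=np.array(res_names),
            atom_names=np.array(names),
            coords=np.array(coords),
            membrane_frame=MembraneFrame((0, 0, 1.0), (0, 0, 0)),
        )

    def test_opposite_charges_attract_less_with_distance(self):
        energies = [
            surrogate_energy(self._two_charges(d)).terms["electrostatic"]
            for d in (6.0, 8.0, 10.0)
        ]
        assert energies[0] < energies[1] < energies[2] < 0

    def test_empty_model_is_all_zero(self):
        empty = StructureModel(
            res_ids=np.array([], dtype=int),
            res_names=np.array([], dtype="<U1"),
            atom_names=np.array([], dtype="<U4"),
            coords=np.zeros((0, 3)),
        )
        e = surrogate_energy(empty)
        assert e.folded == 0.0 and e.unfolded == 0.0
        assert all(v == 0.0 for v in e.terms.values())

    def test_duplicated_distant_copy_doubles_folded_energy(self, small_bundle):
        model, _ = small_bundle
        shifted = model.copy()
        shifted.coords = shifted.coords + np.array([200.0, 0, 0])
        shifted.res_ids = shifted.res_ids + 1000
        double = StructureModel(
            res_ids=np.concatenate([model.res_ids, shifted.res_ids]),
            res_names=np.concatenate([model.res_names, shifted.res_names]),
            atom_names=np.concatenate([model.atom_names, shifted.atom_names]),
            coords=np.vstack([model.coords, shifted.coords]),
            membrane_frame=model.membrane_frame,
        )
        e1 = surrogate_energy(model)
        e2 = surrogate_energy(double)
        assert e2.folded == pytest.approx(2 * e1.folded, rel=1e-6)

    def test_term_total_consistency(self, small_bundle):
        model, _ = small_bundle
        e = surrogate_energy(model)
        named = sum(v for k, v in e.terms.items() if k != "total")
        assert e.terms["total"] == pytest.approx(named, abs=1e-6)


class TestRepack:
    def test_empty_site_set_is_identity(self, small_bundle):
        model, _ = small_bundle
        out = repack_sidechains(model, set(), seed=1)
        assert np.array_equal(out.coords, model.coords)
        assert np.array_equal(out.atom_names, model.atom_names)

    def test_same_seed_is_deterministic(self, small_bundle):
        model, _ = small_bundle
        sites = {model.residues()[3], model.residues()[12]}
        a = repack_sidechains(model, sites, seed=7)
        b = repack_sidechains(model, sites, seed=7)
        assert np.array_equal(a.coords, b.coords)

    def test_backbone_untouched(self, small_bundle):
        model, _ = small_bundle
        sites = {model.residues()[3]}
        out = repack_sidechains(model, sites, seed=1)
        for pos in model.residues():
            for atom in ("N", "CA", "C", "O"):
                assert np.allclose(out.coord(pos, atom), model.coord(pos, atom))

    def test_never_increases_full_energy_vs_start(self, small_bundle):
        model, _ = small_bundle
        sites = set(model.residues()[2:6])
        # starting point: the same coarse-graining the search begins from
        start = repack_sidechains(
            model, sites, seed=0, config=DesignConfig(repack_steps=0, n_chi_states=1)
        )
        out = repack_sidechains(model, sites, seed=5)
        assert (
            surrogate_energy(out).folded
            <= surrogate_energy(start).folded + 1e-9
        )


class TestProposeStructureMutations:
    def test_small_bundle_yields_ionic_candidates(self, small_bundle):
        model, _ = small_bundle
        cands = propose_structure_mutations(model, seed=1)
        assert cands
        assert all(c.module_scores["structure"] > 0 for c in cands)
        assert any("ionic_lock" in c.flags for c in cands)

    def test_rejecting_energy_gives_empty_list(self, small_bundle):
        model, _ = small_bundle

        def constant_energy(m):
            return EnergyBreakdown(folded=0.0, unfolded=0.0, terms={"total": 0.0})

        assert (
            propose_structure_mutations(model, seed=1, energy_fn=constant_energy)
            == []
        )

    def test_candidate_mutations_subset_of_geometry_proposals(self, small_bundle):
        model, _ = small_bundle
        proposed = {
            m.label
            for pair in (
                find_ionic_lock_candidates(model) + find_disulfide_candidates(model)
            )
            for m in pair.proposed_mutations
        }
        accepted = {c.label for c in propose_structure_mutations(model, seed=1)}
        assert accepted <= proposed
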