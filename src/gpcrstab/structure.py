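"""Atomic structure container with membrane frame and residue editing.

The receptor model is stored as flat parallel arrays of heavy atoms.
Side chains may be full-atom (as read from a PDB/mmCIF file) or
coarse-grained to a single centroid pseudo-atom (``SCC``) placed from
internal coordinates — the representation the repacking search and the
energy surrogate operate on.  Glycine carries no Cbeta atom; a virtual
Cbeta reconstructed from the backbone is used for all Cbeta-based
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb
import biotite.structure.io.pdbx as bpdbx

from . import params
from .geometry import place_atom, radial_distance, unit, virtual_cbeta
from .numbering import Mutation, ReceptorAnnotation


class StructureError(ValueError):
    """Missing atoms, unknown residues, or inconsistent annotation."""


@dataclass(frozen=True)
class MembraneFrame:
    """Membrane normal (unit vector) and bundle center."""

    normal: tuple[float, float, float]
    center: tuple[float, float, float]

    @property
    def normal_vec(self) -> np.ndarray:
        return np.asarray(self.normal, float)

    @property
    def center_vec(self) -> np.ndarray:
        return np.asarray(self.center, float)


@dataclass
class StructureModel:
    """Heavy-atom coordinates of one receptor chain."""

    res_ids: np.ndarray  # (n,) int, 1-based sequence positions
    res_names: np.ndarray  # (n,) 1-letter residue codes, per atom
    atom_names: np.ndarray  # (n,) PDB atom names ("N", "CA", ..., "SCC")
    coords: np.ndarray  # (n, 3) float, Angstrom
    membrane_frame: MembraneFrame | None = None
    annotation: ReceptorAnnotation | None = None
    _res_index: dict[int, np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype="<U1")
        self.atom_names = np.asarray(self.atom_names, dtype="<U4")
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        self._rebuild_index()

    def _rebuild_index(self) -> None:
        idx: dict[int, list[int]] = {}
        for i, rid in enumerate(self.res_ids):
            idx.setdefault(int(rid), []).append(i)
        self._res_index = {k: np.asarray(v) for k, v in idx.items()}
        self._derived: dict[str, object] = {}

    # -- queries ---------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.res_ids)

    def residues(self) -> list[int]:
        return sorted(self._res_index)

    def atom_indices(self, position: int) -> np.ndarray:
        return self._res_index.get(position, np.empty(0, dtype=int))

    def residue_type(self, position: int) -> str:
        idx = self.atom_indices(position)
        if len(idx) == 0:
            raise StructureError(f"no residue {position} in model")
        return str(self.res_names[idx[0]])

    def coord(self, position: int, atom_name: str) -> np.ndarray:
        idx = self.atom_indices(position)
        hit = idx[self.atom_names[idx] == atom_name]
        if len(hit) == 0:
            raise StructureError(f"residue {position} lacks atom {atom_name}")
        return self.coords[hit[0]]

    def has_atom(self, position: int, atom_name: str) -> bool:
        idx = self.atom_indices(position)
        return bool(np.any(self.atom_names[idx] == atom_name))

    def cbeta(self, position: int) -> np.ndarray:
        """Cbeta coordinate; for Gly (or a missing CB) a virtual Cbeta
        reconstructed from the backbone."""
        cache = self._derived.setdefault("cbeta", {})
        if position in cache:
            return cache[position]
        if self.has_atom(position, "CB"):
            cb = self.coord(position, "CB")
        else:
            try:
                cb = virtual_cbeta(
                    self.coord(position, "N"),
                    self.coord(position, "CA"),
                    self.coord(position, "C"),
                )
            except StructureError as exc:
                raise StructureError(
                    f"residue {position}: no CB and incomplete backbone"
                ) from exc
        cache[position] = cb
        return cb

    def sidechain_indices(self, position: int) -> np.ndarray:
        """Atoms beyond the backbone (CB and outward)."""
        idx = self.atom_indices(position)
        names = self.atom_names[idx]
        return idx[~np.isin(names, list(params.BACKBONE_ATOMS))]

    def elements(self) -> np.ndarray:
        if "elements" not in self._derived:
            self._derived["elements"] = np.array(
                [params.element_of(a) for a in self.atom_names]
            )
        return self._derived["elements"]

    def vdw_radii(self) -> np.ndarray:
        """Per-atom van der Waals radii; centroid pseudo-atoms use a
        residue-dependent effective radius."""
        if "vdw_radii" not in self._derived:
            radii = np.array(
                [params.vdw_radius(e) for e in self.elements()], dtype=float
            )
            cen = self.atom_names == params.CENTROID_ATOM
            for i in np.nonzero(cen)[0]:
                radii[i] = params.CENTROID_RADIUS.get(
                    str(self.res_names[i]), params.VDW_RADII["X"]
                )
            self._derived["vdw_radii"] = radii
        return self._derived["vdw_radii"]

    def copy(self) -> "StructureModel":
        return StructureModel(
            res_ids=self.res_ids.copy(),
            res_names=self.res_names.copy(),
            atom_names=self.atom_names.copy(),
            coords=self.coords.copy(),
            membrane_frame=self.membrane_frame,
            annotation=self.annotation,
        )

    def validate(self) -> None:
        """Check every annotated TM residue has backbone and a Cbeta proxy."""
        if self.annotation is None:
            return
        for pos in self.annotation.tm_positions():
            idx = self.atom_indices(pos)
            if len(idx) == 0:
                raise StructureError(f"annotated TM residue {pos} missing")
            names = set(self.atom_names[idx])
            if not {"N", "CA", "C"}.issubset(names):
                raise StructureError(f"residue {pos}: incomplete backbone")
            if "CB" not in names and self.residue_type(pos) != "G":
                raise StructureError(f"residue {pos}: missing CB")
            aa = self.residue_type(pos)
            if self.annotation.residue(pos) != aa:
                raise StructureError(
                    f"residue {pos}: structure has {aa}, annotation "
                    f"{self.annotation.residue(pos)}"
                )

    # -- membrane frame --------------------------------------------------

    def with_computed_frame(self) -> "StructureModel":
        """Set the membrane frame from the principal axis of TM CA atoms
        (all CA atoms when no annotation is attached)."""
        if self.annotation is not None:
            positions = [
                p for p in self.annotation.tm_positions() if p in self._res_index
            ]
        else:
            positions = self.residues()
        cas = np.array([self.coord(p, "CA") for p in positions])
        center = cas.mean(axis=0)
        _, _, vt = np.linalg.svd(cas - center)
        normal = unit(vt[0])
        m = self.copy()
        m.membrane_frame = MembraneFrame(tuple(normal), tuple(center))
        return m

    def radial(self, point: np.ndarray) -> float:
        if self.membrane_frame is None:
            raise StructureError("membrane frame not set")
        return radial_distance(
            point, self.membrane_frame.center_vec, self.membrane_frame.normal_vec
        )


# -- residue editing -----------------------------------------------------


def sidechain_chi(model: StructureModel, position: int) -> float:
    """Dihedral N-CA-CB-(side-chain centroid) of the current side chain."""
    from .geometry import dihedral

    sc = model.sidechain_indices(position)
    names = model.atom_names[sc]
    beyond = sc[names != "CB"]
    if len(beyond) == 0:
        return 180.0
    centroid = model.coords[beyond].mean(axis=0)
    return dihedral(
        model.coord(position, "N"),
        model.coord(position, "CA"),
        model.coord(position, "CB"),
        centroid,
    )


def set_sidechain(
    model: StructureModel, position: int, new_aa: str, chi: float = 180.0
) -> StructureModel:
    """Replace a residue's side chain with the coarse representation of
    ``new_aa``: CB (unless Gly) plus a centroid pseudo-atom at dihedral
    ``chi`` for residues larger than Ala.  Backbone is untouched."""
    if new_aa not in params.CENTROID_DISTANCE:
        raise StructureError(f"unknown residue type {new_aa!r}")
    n = model.coord(position, "N")
    ca = model.coord(position, "CA")
    c = model.coord(position, "C")
    keep = np.ones(model.n_atoms, dtype=bool)
    keep[model.sidechain_indices(position)] = False

    new_names: list[str] = []
    new_coords: list[np.ndarray] = []
    if new_aa != "G":
        new_names.append("CB")
        cb = model.cbeta(position)
        new_coords.append(cb)
        d = params.CENTROID_DISTANCE[new_aa]
        if d > 0:
            new_names.append(params.CENTROID_ATOM)
            new_coords.append(
                place_atom(n, ca, cb, d, params.CENTROID_ANGLE, chi)
            )

    res_ids = np.concatenate([model.res_ids[keep], [position] * len(new_names)])
    res_names = np.concatenate([model.res_names[keep], [new_aa] * len(new_names)])
    # the whole residue changes type
    res_names[res_ids == position] = new_aa
    atom_names = np.concatenate([model.atom_names[keep], new_names])
    coords = (
        np.vstack([model.coords[keep], np.array(new_coords)])
        if new_coords
        else model.coords[keep].copy()
    )
    order = np.lexsort((np.arange(len(res_ids)), res_ids))
    return StructureModel(
        res_ids=res_ids[order],
        res_names=res_names[order],
        atom_names=atom_names[order],
        coords=coords[order],
        membrane_frame=model.membrane_frame,
        annotation=model.annotation,
    )


def apply_mutation(model: StructureModel, mutation: Mutation) -> StructureModel:
    """Swap residue types at the mutation sites (coarse side chains,
    default rotamer); the caller is expected to repack afterwards."""
    out = model
    for site in mutation.sites:
        actual = out.residue_type(site.position)
        if actual != site.wt_aa:
            raise StructureError(
                f"{mutation.label}: model has {actual} at {site.position}"
            )
        out = set_sidechain(out, site.position, site.mut_aa)
    return out


# -- file I/O ------------------------------------------------------------


def _from_atom_array(
    arr: bst.AtomArray,
    annotation: ReceptorAnnotation | None,
    chain: str | None,
) -> StructureModel:
    mask = ~arr.hetero & (arr.element != "H")
    if chain is not None:
        mask &= arr.chain_id == chain
    else:
        first = arr.chain_id[mask][0]
        mask &= arr.chain_id == first
    arr = arr[mask]
    res_names = []
    keep = []
    for i, three in enumerate(arr.res_name):
        one = params.THREE_TO_ONE.get(three)
        if one is None:
            continue
        keep.append(i)
        res_names.append(one)
    arr = arr[np.asarray(keep, dtype=int)]
    model = StructureModel(
        res_ids=arr.res_id,
        res_names=np.array(res_names),
        atom_names=arr.atom_name,
        coords=arr.coord,
        annotation=annotation,
    )
    return model.with_computed_frame()


def read_structure(
    path, annotation: ReceptorAnnotation | None = None, chain: str | None = None
) -> StructureModel:
    """Read a PDB or mmCIF file (by extension) into a StructureModel."""
    p = str(path)
    if p.endswith((".cif", ".mmcif")):
        f = bpdbx.CIFFile.read(p)
        arr = bpdbx.get_structure(f, model=1)
    else:
        f = bpdb.PDBFile.read(p)
        arr = bpdb.get_structure(f, model=1)
    return _from_atom_array(arr, annotation, chain)


def write_pdb(model: StructureModel, path) -> None:
    """Write the model as a PDB file (centroid pseudo-atoms as carbon)."""
    n = model.n_atoms
    arr = bst.AtomArray(n)
    arr.res_id = model.res_ids
    arr.res_name = np.array(
        [params.ONE_TO_THREE[a] for a in model.res_names]
    )
    arr.atom_name = model.atom_names
    arr.element = np.array(
        [e if e != "X" else "C" for e in model.elements()]
    )
    arr.chain_id = np.full(n, "A")
    arr.coord = model.coords
    arr.hetero = np.zeros(n, dtype=bool)
    f = bpdb.PDBFile()
    bpdb.set_structure(f, arr)
    f.write(str(path))
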