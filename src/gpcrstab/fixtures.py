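"""Synthetic data generators: toy MSAs, idealized 7TM bundles, benchmarks.

Everything the four prediction lanes consume can be generated offline
and deterministically: alignments with controlled per-column
conservation and planted deviations, idealized alpha-helical bundles
with full backbone + Cbeta, and planted-signal training benchmarks
mirroring the heavy class imbalance of real alanine-scan data.
Generators are pure functions of their spec (seed included) and write
the same on-disk formats as real inputs (aligned FASTA, PDB, TSV), so
tests exercise the production readers.

These fixtures emulate the shape of real data, not its statistics: no
realistic GPCR sequence composition, no membrane atoms, no loops in
the structural models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import N_FEATURES, FeatureVector, TrainingExample
from .geometry import place_atom, virtual_cbeta
from .numbering import AMINO_ACIDS, Mutation, ReceptorAnnotation
from .structure import MembraneFrame, StructureModel

# -- MSA ----------------------------------------------------------------


@dataclass(frozen=True)
class MSASpec:
    """Controlled-conservation alignment: ``conservation[c]`` is the
    probability a non-target row carries the column consensus; planted
    columns put a rare residue in the target only."""

    n_sequences: int = 60
    length: int = 40
    conservation: tuple[float, ...] | float = 0.9
    planted_deviations: tuple[tuple[int, str], ...] = ()  # (1-based column, aa)
    seed: int = 0

    def per_column(self) -> np.ndarray:
        cons = self.conservation
        arr = (
            np.full(self.length, float(cons))
            if np.isscalar(cons)
            else np.asarray(cons, float)
        )
        if arr.shape != (self.length,):
            raise ValueError("conservation must be scalar or one value per column")
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("conservation outside [0, 1]")
        return arr


def synth_msa(spec: MSASpec) -> tuple[list[tuple[str, str]], str]:
    """Generate ``(msa_rows, target_id)``; the target is the first row."""
    cons = spec.per_column()
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    consensus = rng.choice(aa, size=spec.length)
    target = consensus.copy()
    for col, rare in spec.planted_deviations:
        if not 1 <= col <= spec.length:
            raise ValueError(f"planted column {col} outside 1..{spec.length}")
        if rare == consensus[col - 1]:
            raise ValueError(f"planted residue at column {col} equals consensus")
        target[col - 1] = rare

    rows = [("target", "".join(target))]
    planted_cols = {c - 1 for c, _ in spec.planted_deviations}
    for s in range(spec.n_sequences - 1):
        seq = consensus.copy()
        for c in range(spec.length):
            if rng.random() >= cons[c]:
                choices = [
                    x
                    for x in AMINO_ACIDS
                    if x != consensus[c] and (c not in planted_cols or x != target[c])
                ]
                seq[c] = choices[rng.integers(len(choices))]
        rows.append((f"seq{s + 1:03d}", "".join(seq)))
    return rows, "target"


def write_msa_fasta(msa: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in msa:
            fh.write(f">{seq_id}\n{seq}\n")


# -- idealized helical bundle -------------------------------------------

_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5


def _ideal_helix_backbone(n_res: int) -> list[dict[str, np.ndarray]]:
    """NeRF chain build of an ideal alpha helix (N, CA, C, O per residue)."""
    res: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = res[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, _PSI)
        ca = place_atom(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, _OMEGA)
        c = place_atom(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, _PHI)
        res.append({"N": n, "CA": ca, "C": c})
    for i in range(n_res):
        if i + 1 < n_res:
            res[i]["O"] = place_atom(
                res[i + 1]["N"], res[i]["CA"], res[i]["C"], _B_C_O, _A_CA_C_O, 180.0
            )
        else:
            res[i]["O"] = place_atom(
                res[i]["N"], res[i]["CA"], res[i]["C"], _B_C_O, _A_CA_C_O, _PSI + 180.0
            )
    return res


def _orient_to_z(res: list[dict[str, np.ndarray]]) -> list[dict[str, np.ndarray]]:
    cas = np.array([r["CA"] for r in res])
    center = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - center)
    axis = vt[0]
    if np.dot(cas[-1] - cas[0], axis) < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(np.dot(axis, z))
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array(
            [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]]
        )
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    return [
        {k: rot @ (p - center) for k, p in r.items()} for r in res
    ]


_HELIX_POOL = list("AVLIFMSTGEKDRNQYW")
_HELIX_WEIGHTS = np.array(
    [10, 8, 10, 8, 6, 4, 5, 5, 4, 3, 3, 3, 2, 3, 3, 3, 2], float
)


@dataclass(frozen=True)
class BundleSpec:
    """Idealized antiparallel helical bundle around the z axis."""

    n_helices: int = 7
    residues_per_helix: int = 18
    radius: float = 8.0  # helix axes from bundle center, A
    loop_length: int = 3  # annotation-only connecting residues
    phase_jitter: bool = True  # seed-random rotation of each helix
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 1 or self.residues_per_helix < 4:
            raise ValueError("need >= 1 helix of >= 4 residues")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def synth_bundle(spec: BundleSpec) -> tuple[StructureModel, ReceptorAnnotation]:
    """Build an idealized bundle and its generic-number annotation.

    Helices are parallel/antiparallel to z, evenly spaced on a circle
    of ``spec.radius``; the annotation interleaves short unannotated
    loops between helices.  The default geometry contains residue
    pairs inside both the ionic-lock (7-10 A) and disulfide
    (3.4-4.7 A) Cbeta-Cbeta windows.  Deterministic in the seed.
    """
    rng = np.random.default_rng(spec.seed)
    template = _orient_to_z(_ideal_helix_backbone(spec.residues_per_helix))

    res_ids, res_names, atom_names, coords = [], [], [], []
    sequence: list[str] = []
    tm_map: dict[int, str] = {}
    pos = 0
    for h in range(spec.n_helices):
        theta = 2.0 * np.pi * h / spec.n_helices
        offset = np.array(
            [spec.radius * np.cos(theta), spec.radius * np.sin(theta), 0.0]
        )
        phase = rng.uniform(0, 2 * np.pi) if spec.phase_jitter else 0.0
        cp, sp = np.cos(phase), np.sin(phase)
        spin = np.array([[cp, -sp, 0], [sp, cp, 0], [0, 0, 1.0]])
        flip = (
            np.diag([1.0, -1.0, -1.0]) if h % 2 else np.eye(3)
        )  # antiparallel
        if h > 0:
            for _ in range(spec.loop_length):
                pos += 1
                sequence.append("G")  # loop: annotation only, no atoms
        for i, r in enumerate(template):
            pos += 1
            aa = str(
                rng.choice(_HELIX_POOL, p=_HELIX_WEIGHTS / _HELIX_WEIGHTS.sum())
            )
            sequence.append(aa)
            offset_gn = 50 - spec.residues_per_helix // 2 + i
            tm_map[pos] = f"{min(h + 1, 8)}.{offset_gn:02d}"
            placed = {k: spin @ (flip @ p) + offset for k, p in r.items()}
            names = ["N", "CA", "C", "O"]
            pts = [placed[k] for k in names]
            if aa != "G":
                names.append("CB")
                pts.append(virtual_cbeta(placed["N"], placed["CA"], placed["C"]))
            for nm, pt in zip(names, pts):
                res_ids.append(pos)
                res_names.append(aa)
                atom_names.append(nm)
                coords.append(pt)

    annotation = ReceptorAnnotation(
        sequence="".join(sequence), tm_map=tm_map, name=f"bundle-{spec.seed}"
    )
    all_coords = np.array(coords)
    model = StructureModel(
        res_ids=np.array(res_ids),
        res_names=np.array(res_names),
        atom_names=np.array(atom_names),
        coords=all_coords,
        membrane_frame=MembraneFrame(
            (0.0, 0.0, 1.0), tuple(all_coords.mean(axis=0))
        ),
        annotation=annotation,
    )
    model.validate()
    return model, annotation


# -- training benchmark --------------------------------------------------


def synth_benchmark(
    n_pos: int, n_neg: int, effect: float, seed: int
) -> list[TrainingExample]:
    """Planted-signal benchmark: features of both classes are standard
    Gaussians, the positive class shifted by ``effect`` standard
    deviations along a planted direction.  Class sizes mirror the
    heavy imbalance of real stability panels (e.g. 79 vs 923)."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one example per class")
    if effect < 0:
        raise ValueError("effect size must be non-negative")
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(N_FEATURES)
    direction /= np.linalg.norm(direction)
    out: list[TrainingExample] = []
    for i in range(n_pos + n_neg):
        label = +1 if i < n_pos else -1
        x = rng.standard_normal(N_FEATURES)
        if label == +1:
            x = x + effect * direction
        wt = AMINO_ACIDS[i % 20]
        mut = AMINO_ACIDS[(i + 1) % 20]
        out.append(
            TrainingExample(
                mutation=Mutation.single(i + 1, wt, mut),
                features=FeatureVector(values=x),
                label=label,
                origin="synthetic",
            )
        )
    return out


# -- packaged miniature receptor ----------------------------------------

_MINI_SEGMENTS = (
    # (helix, first_pos, last_pos, gn offset of first_pos)
    (1, 50, 80, 30),
    (2, 85, 115, 36),
    (3, 127, 160, 25),
    (4, 170, 195, 40),
    (5, 215, 245, 40),
    (6, 310, 340, 30),
    (7, 345, 370, 30),
    (8, 372, 382, 47),
)
_MINI_LENGTH = 385
_MINI_FIXED = {99: "D", 141: "S", 143: "M", 360: "C", 362: "G"}


def mini_receptor(
    seed: int = 0,
) -> tuple[ReceptorAnnotation, dict[str, list[tuple[str, str]]], str]:
    """A serotonin-receptor-like miniature: annotation plus two MSAs.

    The target carries D at 2.50 and M at 3.41 (knowledge-rule hits),
    a rare C at the otherwise N-conserved 7.45 column, and a deviant M
    at the W-conserved 3.41 column, so the sequence lane's top
    candidate restores N at 7.45 and the 3.41 candidate overlaps the
    knowledge lane.  Deterministic in the seed.
    """
    rng = np.random.default_rng(seed)
    pool = np.array(list("AVLIFMSTYWNQEKDR"))
    seq = rng.choice(pool, size=_MINI_LENGTH)
    for pos, aa in _MINI_FIXED.items():
        seq[pos - 1] = aa
    tm_map: dict[int, str] = {}
    for helix, first, last, gn0 in _MINI_SEGMENTS:
        for i, pos in enumerate(range(first, last + 1)):
            tm_map[pos] = f"{helix}.{gn0 + i:02d}"
    annotation = ReceptorAnnotation(
        sequence="".join(seq), tm_map=tm_map, name="mini-5ht2c-like"
    )

    # ortholog-like MSA over the full sequence: consensus = target except
    # at the planted columns (7.45 mostly N, 3.41 mostly W)
    n_seqs = 60
    consensus = seq.copy()
    consensus[360 - 1] = "N"
    consensus[143 - 1] = "W"
    conservation = np.full(_MINI_LENGTH, 0.95)
    conservation[360 - 1] = 0.98
    conservation[143 - 1] = 0.85
    rows = [("target", "".join(seq))]
    for s in range(n_seqs - 1):
        row = consensus.copy()
        for c in range(_MINI_LENGTH):
            if rng.random() >= conservation[c]:
                alternatives = [
                    x for x in AMINO_ACIDS if x not in (consensus[c], seq[c])
                ]
                row[c] = alternatives[rng.integers(len(alternatives))]
        rows.append((f"orth{s + 1:03d}", "".join(row)))
    return annotation, {"orthologs": rows}, "target"
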