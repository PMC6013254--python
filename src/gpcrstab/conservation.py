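"""Sequence-based lane: conservation-deviation scoring over stacked MSAs.

Residues of the target receptor that break the conservation pattern of
an evolutionarily related group are candidate destabilizers; restoring
the conserved residue is the candidate mutation.  For alignment column
``k`` and residue ``aa`` the deviation score is

    score_k(aa) = (C_k^max - C_k^aa) / N_MSA  -  C_k^aa / C_k^max

where ``N_MSA`` is the number of sequences in the alignment,
``C_k^max`` the count of the most frequent (modal) residue in the
column, and ``C_k^aa`` the count of residue ``aa``.  The first term
approaches 1 for a residue that is nearly unique in an otherwise
super-conserved column; the second term penalizes columns without a
dominant residue.  The score lies in [-1, 1], equals -1 exactly when
``aa`` is the modal residue, and stays strictly below 1 for any finite
alignment.  A non-conserved wild-type glycine has its score doubled:
Gly destabilizes transmembrane alpha-helices, so deviant glycines are
prioritized (doubled scores may exceed 1 and are not clipped).

Deviation patterns differ with evolutionary depth (orthologs give few,
sharp deviations; whole-class alignments flag breaks at the most
conserved class positions), so up to five alignments are scored
independently and averaged cell-wise into a net matrix.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO

from .numbering import AMINO_ACIDS, Mutation, ReceptorAnnotation, ScoredMutation

MODULE_NAME = "sequence"
GAP_CHARS = set("-.")


class AlignmentError(ValueError):
    """Ragged alignment or missing target row."""


@dataclass(frozen=True)
class ColumnProfile:
    """Residue counts for one alignment column mapped to a target position."""

    counts: dict[str, int]
    n_total: int

    @property
    def modal_count(self) -> int:
        return max(self.counts.values()) if self.counts else 0

    def modal_residues(self) -> list[str]:
        """All residues attaining the modal count (alphabetical)."""
        cmax = self.modal_count
        return sorted(aa for aa, c in self.counts.items() if c == cmax)

    def count(self, aa: str) -> int:
        return self.counts.get(aa, 0)


@dataclass
class DeviationScoreMatrix:
    """Positions x 20 amino acids deviation scores for one MSA (or the net)."""

    values: pd.DataFrame  # index: target positions, columns: AMINO_ACIDS
    msa_id: str

    def score(self, position: int, aa: str) -> float:
        return float(self.values.at[position, aa])

    @property
    def positions(self) -> list[int]:
        return list(self.values.index)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="position")


def read_msa(path) -> list[tuple[str, str]]:
    """Read an aligned FASTA into ``[(id, row), ...]``, checking raggedness."""
    alignment = AlignIO.read(path, "fasta")
    return [(rec.id, str(rec.seq).upper()) for rec in alignment]


def build_profiles(
    msa: list[tuple[str, str]], target_id: str
) -> dict[int, ColumnProfile]:
    """Per-column residue tallies keyed by the target's 1-based positions.

    The target must be a row of the alignment; columns where the target
    has a gap are dropped.  Gaps (and non-standard letters) in other
    rows are excluded from the counts while ``n_total`` stays the full
    number of sequences, so heavily gapped columns are implicitly
    penalized through a small modal count.
    """
    if not msa:
        raise AlignmentError("empty alignment")
    length = len(msa[0][1])
    for seq_id, row in msa:
        if len(row) != length:
            raise AlignmentError(
                f"row {seq_id!r} has length {len(row)}, expected {length}"
            )
    target_rows = [row for seq_id, row in msa if seq_id == target_id]
    if not target_rows:
        raise AlignmentError(f"target {target_id!r} not found in alignment")
    target = target_rows[0]
    n_total = len(msa)
    profiles: dict[int, ColumnProfile] = {}
    position = 0
    for col in range(length):
        if target[col] in GAP_CHARS:
            continue
        position += 1
        counts = Counter(
            row[col] for _, row in msa if row[col] in AMINO_ACIDS
        )
        profiles[position] = ColumnProfile(counts=dict(counts), n_total=n_total)
    return profiles


def deviation_score(profile: ColumnProfile, target_aa: str) -> float:
    """Deviation score of ``target_aa`` in one column (see module docstring)."""
    n = profile.n_total
    cmax = profile.modal_count
    if n < 1 or cmax < 1:
        raise ValueError("profile must contain at least one counted residue")
    caa = profile.count(target_aa)
    return (cmax - caa) / n - caa / cmax


def apply_gly_rule(score: float, wt_aa: str, profile: ColumnProfile) -> float:
    """Double the score when the wild type is a non-modal glycine."""
    if wt_aa == "G" and "G" not in profile.modal_residues():
        return 2.0 * score
    return score


def score_matrix(
    profiles: dict[int, ColumnProfile],
    msa_id: str,
    annotation: ReceptorAnnotation | None = None,
    gly_adjust: bool = True,
) -> DeviationScoreMatrix:
    """Deviation scores for all 20 residues at every profiled position.

    With ``gly_adjust`` the glycine column of each row is doubled where
    Gly is not modal, so a wild-type Gly lookup sees the adjusted score.
    """
    positions = sorted(profiles)
    data = np.empty((len(positions), len(AMINO_ACIDS)))
    for i, pos in enumerate(positions):
        prof = profiles[pos]
        for j, aa in enumerate(AMINO_ACIDS):
            s = deviation_score(prof, aa)
            if gly_adjust:
                s = apply_gly_rule(s, aa, prof)
            data[i, j] = s
    df = pd.DataFrame(data, index=positions, columns=list(AMINO_ACIDS))
    return DeviationScoreMatrix(values=df, msa_id=msa_id)


def net_score_matrix(matrices: list[DeviationScoreMatrix]) -> DeviationScoreMatrix:
    """Cell-wise unweighted mean over 1-5 per-MSA matrices.

    Positions absent from an alignment contribute nothing to that
    cell's mean (the mean runs over the matrices that cover it).
    """
    if not matrices:
        raise ValueError("need at least one deviation-score matrix")
    if len(matrices) > 5:
        raise ValueError("at most five stacked alignments are supported")
    stacked = pd.concat([m.values for m in matrices])
    mean = stacked.groupby(level=0).mean()
    return DeviationScoreMatrix(
        values=mean.sort_index(), msa_id="net(" + ",".join(m.msa_id for m in matrices) + ")"
    )


def propose_sequence_mutations(
    net: DeviationScoreMatrix,
    per_msa_profiles: list[dict[int, ColumnProfile]],
    annotation: ReceptorAnnotation,
    top_k: int = 40,
    min_score: float = 0.0,
) -> list[ScoredMutation]:
    """Candidate substitutions restoring conserved residues.

    Annotated TM positions are ranked by the wild-type residue's net
    deviation score (descending; positions scoring <= ``min_score`` are
    dropped).  Each selected position proposes a substitution to the
    modal residue of every contributing alignment, deduplicated, each
    carrying the net wild-type score.  At most ``top_k`` candidates.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    scored_positions: list[tuple[float, int]] = []
    for pos in annotation.tm_positions():
        if pos not in net.values.index:
            continue
        wt = annotation.residue(pos)
        if wt not in AMINO_ACIDS:
            continue
        s = net.score(pos, wt)
        if s > min_score:
            scored_positions.append((s, pos))
    scored_positions.sort(key=lambda t: (-t[0], t[1]))

    out: list[ScoredMutation] = []
    for s, pos in scored_positions:
        wt = annotation.residue(pos)
        # modal residue per contributing MSA; ties broken by total count
        # across MSAs, then alphabetically
        replacements: dict[str, int] = {}
        for profiles in per_msa_profiles:
            prof = profiles.get(pos)
            if prof is None:
                continue
            modal_set = prof.modal_residues()
            if len(modal_set) == 1:
                modal = modal_set[0]
            else:
                def total(aa: str) -> int:
                    return sum(
                        p[pos].count(aa) for p in per_msa_profiles if pos in p
                    )

                modal = sorted(modal_set, key=lambda aa: (-total(aa), aa))[0]
            if modal != wt:
                replacements[modal] = replacements.get(modal, 0) + 1
        for mut_aa in sorted(replacements):
            if len(out) >= top_k:
                return out
            out.append(
                ScoredMutation(
                    mutation=Mutation.single(
                        pos, wt, mut_aa, gn=annotation.generic_number(pos)
                    ),
                    module_scores={MODULE_NAME: s},
                    provenance=[MODULE_NAME],
                )
            )
    return out
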