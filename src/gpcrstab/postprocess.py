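"""Post-processing: pocket/loop filters and the merged ranked report.

Candidates that could interfere with ligand binding are removed:
generic positions seen contacting a ligand in more than a threshold
number (default 5, strict) of distinct class-A structures form the
exclusion set.  Candidates at positions without a TM generic number
(loops, termini) are removed as well — modeling accuracy there is too
low to trust a prediction.  Knowledge-lane sodium-pocket candidates
target an allosteric site distinct from the orthosteric pocket and are
retained, but flagged.

Surviving per-lane lists are merged into one report: identical
mutations proposed by several lanes collapse into one record with
concatenated provenance, ranked by (number of proposing lanes, best
within-lane normalized rank) — a documented heuristic, since the lanes
score on incommensurable scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources

import pandas as pd

from .knowledge import SODIUM_POCKET_FLAG
from .numbering import ReceptorAnnotation, ScoredMutation

DEFAULT_POCKET_PATH = resources.files("gpcrstab.data") / "pocket_contacts.tsv"
DEFAULT_POCKET_THRESHOLD = 5


@dataclass(frozen=True)
class PocketExclusionSet:
    """Generic positions excluded as likely ligand-binding."""

    positions: frozenset[str]
    support_counts: dict[str, int]
    threshold: int

    def __contains__(self, gn: str | None) -> bool:
        return gn is not None and gn in self.positions


def build_exclusion_set(
    contact_table: pd.DataFrame, threshold: int = DEFAULT_POCKET_THRESHOLD
) -> PocketExclusionSet:
    """Positions whose distinct-structure support count strictly exceeds
    ``threshold``.  ``contact_table`` columns: structure_id, generic_number."""
    required = {"structure_id", "generic_number"}
    if not required.issubset(contact_table.columns):
        raise ValueError(f"contact table needs columns {sorted(required)}")
    counts = (
        contact_table.groupby("generic_number")["structure_id"].nunique().to_dict()
    )
    members = frozenset(gn for gn, c in counts.items() if c > threshold)
    return PocketExclusionSet(
        positions=members, support_counts=counts, threshold=threshold
    )


def load_default_exclusion_set(
    threshold: int = DEFAULT_POCKET_THRESHOLD,
) -> PocketExclusionSet:
    with DEFAULT_POCKET_PATH.open("r") as fh:
        table = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
    return build_exclusion_set(table, threshold)


def filter_candidates(
    candidates: list[ScoredMutation],
    pocket: PocketExclusionSet,
    annotation: ReceptorAnnotation,
) -> list[ScoredMutation]:
    """Drop pocket-contacting and non-TM candidates (monotone, idempotent).

    Sodium-pocket flagged candidates from the knowledge lane survive
    the pocket filter (allosteric sodium site != orthosteric ligand
    pocket) but keep their flag.
    """
    out: list[ScoredMutation] = []
    for cand in candidates:
        keep = True
        for site in cand.mutation.sites:
            gn_obj = annotation.tm_number(site.position)
            if gn_obj is None:  # loop / terminus / unannotated
                keep = False
                break
            gn = annotation.generic_number(site.position)
            if gn in pocket and SODIUM_POCKET_FLAG not in cand.flags:
                keep = False
                break
        if keep:
            out.append(cand)
    return out


def merge_and_rank(
    per_module: dict[str, list[ScoredMutation]], top_k: int = 40
) -> list[ScoredMutation]:
    """Merge per-lane candidate lists into one ranked report.

    Identical mutations from several lanes merge into one record with
    concatenated provenance and all module scores retained.  Ranking
    key: number of proposing lanes, then the best within-lane
    normalized rank (1 = top of its lane); truncated to ``top_k``.
    """
    # within-lane normalized rank in (0, 1], 1 = best
    norm_rank: dict[tuple[str, str], float] = {}
    for module, cands in per_module.items():
        n = len(cands)
        for i, cand in enumerate(cands):
            norm_rank[(module, cand.label)] = 1.0 - i / n if n else 0.0

    merged: dict[str, ScoredMutation] = {}
    wt_claim: dict[int, str] = {}
    for module, cands in per_module.items():
        for cand in cands:
            for site in cand.mutation.sites:
                claimed = wt_claim.setdefault(site.position, site.wt_aa)
                if claimed != site.wt_aa:
                    raise ValueError(
                        f"conflicting wild-type residues at position "
                        f"{site.position}: {claimed} vs {site.wt_aa}"
                    )
            prev = merged.get(cand.label)
            if prev is None:
                merged[cand.label] = replace(
                    cand,
                    module_scores=dict(cand.module_scores),
                    provenance=list(cand.provenance),
                )
                continue
            prev.module_scores.update(cand.module_scores)
            for m in cand.provenance:
                if m not in prev.provenance:
                    prev.provenance.append(m)
            merged[cand.label] = replace(prev, flags=prev.flags | cand.flags)

    def sort_key(sm: ScoredMutation):
        best_norm = max(
            norm_rank.get((m, sm.label), 0.0) for m in sm.provenance
        )
        return (-len(sm.provenance), -best_norm, sm.label)

    ranked = sorted(merged.values(), key=sort_key)[:top_k]
    out = []
    for rank, sm in enumerate(ranked, start=1):
        best_norm = max(norm_rank.get((m, sm.label), 0.0) for m in sm.provenance)
        out.append(
            replace(sm, rank=rank, final_score=len(sm.provenance) + best_norm)
        )
    return out


# -- report output -------------------------------------------------------


def report_frame(candidates: list[ScoredMutation]) -> pd.DataFrame:
    rows = []
    for sm in candidates:
        rows.append(
            {
                "rank": sm.rank,
                "mutation": sm.label,
                "provenance": "+".join(sm.provenance),
                "final_score": sm.final_score,
                "flags": ",".join(sorted(sm.flags)),
                **{f"score_{k}": v for k, v in sorted(sm.module_scores.items())},
            }
        )
    return pd.DataFrame(rows)


def write_report(candidates: list[ScoredMutation], tsv_path=None, json_path=None):
    df = report_frame(candidates)
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)
    return df
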