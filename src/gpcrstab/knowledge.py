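"""Knowledge-based lane: transferable class-A stabilizing mutations.

A short list of point mutations at structurally or functionally
conserved class-A sites (sodium pocket, P-I-F and DRY microswitches,
the 3.41 TM3/TM4/TM5 interface position, ...) has repeatedly helped
crystallize multiple receptors.  This lane simply checks each rule
against the target: if the rule's generic position is annotated and
the wild-type residue is admissible, the substitution is emitted with
score 1.0; otherwise nothing.

The rule set ships as a plain TSV
(:data:`DEFAULT_RULES_PATH`) so it can grow, or be overridden by the
user, without code changes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .numbering import (
    AMINO_ACIDS,
    GenericNumber,
    Mutation,
    ReceptorAnnotation,
    ScoredMutation,
    parse_generic_number,
)

MODULE_NAME = "knowledge"
SODIUM_POCKET_FLAG = "sodium_pocket"

DEFAULT_RULES_PATH = resources.files("gpcrstab.data") / "knowledge_rules.tsv"

_MUTSPEC_RE = re.compile(r"^\s*([A-Z,\s]+)\s*->\s*([A-Z,\s]+)\s*$")


class RuleError(ValueError):
    """Unparseable rule table row."""


@dataclass(frozen=True)
class KnowledgeRule:
    """One transferable mutation rule at a generic position.

    ``allowed_wt`` is the set of admissible wild-type residues;
    ``None`` means the wildcard "any residue except the targets".
    """

    gn: GenericNumber
    allowed_wt: frozenset[str] | None
    target_aa: tuple[str, ...]
    role: str = ""
    exemplar_structures: str = ""

    def __post_init__(self) -> None:
        if not self.target_aa:
            raise RuleError(f"rule at {self.gn} has no target residues")

    def admissible_wt(self, wt: str) -> bool:
        if wt in self.target_aa:
            return False
        if self.allowed_wt is None:  # wildcard
            return wt in AMINO_ACIDS
        return wt in self.allowed_wt

    @property
    def is_sodium_pocket(self) -> bool:
        return "sodium" in self.role.lower()


def _parse_mutation_spec(spec: str, row: int) -> tuple[frozenset[str] | None, tuple[str, ...]]:
    m = _MUTSPEC_RE.match(spec)
    if m is None:
        raise RuleError(f"row {row}: unparseable mutation spec {spec!r}")
    wt_part = [t.strip() for t in m.group(1).split(",") if t.strip()]
    targets = tuple(t.strip() for t in m.group(2).split(",") if t.strip())
    allowed = None if wt_part == ["X"] else frozenset(wt_part)
    return allowed, targets


def load_rules(source=None) -> list[KnowledgeRule]:
    """Load rules from a TSV (columns position, mutation, role, ...).

    With no argument, loads the packaged default table.
    """
    if source is None:
        source = DEFAULT_RULES_PATH
    if hasattr(source, "open") and not isinstance(source, (str, bytes)):
        with source.open("r") as fh:
            df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    if not {"position", "mutation"}.issubset(df.columns):
        raise RuleError("rule table needs columns position, mutation")
    rules = []
    for i, row in enumerate(df.itertuples(), start=1):
        try:
            gn = parse_generic_number(row.position)
        except ValueError as exc:
            raise RuleError(f"row {i}: {exc}") from exc
        allowed, targets = _parse_mutation_spec(row.mutation, i)
        rules.append(
            KnowledgeRule(
                gn=gn,
                allowed_wt=allowed,
                target_aa=targets,
                role=getattr(row, "role", ""),
                exemplar_structures=getattr(row, "exemplar_structures", ""),
            )
        )
    return rules


def score_knowledge(
    annotation: ReceptorAnnotation, rules: list[KnowledgeRule] | None = None
) -> list[ScoredMutation]:
    """Emit every rule-applicable substitution for the target, score 1.0.

    A rule applies when its generic position is annotated in the
    target, the wild-type residue there is admissible, and differs
    from the rule's target residue.  Inapplicable rules are silent.
    """
    if rules is None:
        rules = load_rules()
    out: list[ScoredMutation] = []
    for rule in rules:
        hit = annotation.resolve(rule.gn)
        if hit is None:
            continue
        position, wt = hit
        if not rule.admissible_wt(wt):
            continue
        for target in rule.target_aa:
            mut = Mutation.single(position, wt, target, gn=str(rule.gn))
            sm = ScoredMutation(
                mutation=mut,
                module_scores={MODULE_NAME: 1.0},
                provenance=[MODULE_NAME],
            )
            if rule.is_sodium_pocket:
                sm = sm.with_flag(SODIUM_POCKET_FLAG)
            out.append(sm)
    return out
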