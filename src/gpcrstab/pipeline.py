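"""End-to-end orchestration: run the prediction lanes, filter, merge."""

from __future__ import annotations

from dataclasses import dataclass, field

from .conservation import (
    build_profiles,
    net_score_matrix,
    propose_sequence_mutations,
    score_matrix,
)
from .design import DesignConfig, propose_structure_mutations
from .knowledge import score_knowledge
from .ml import PredictionModel, propose_ml_mutations
from .numbering import ReceptorAnnotation, ScoredMutation
from .postprocess import (
    PocketExclusionSet,
    filter_candidates,
    load_default_exclusion_set,
    merge_and_rank,
)
from .structure import StructureModel


@dataclass
class PipelineResult:
    per_module: dict[str, list[ScoredMutation]]
    filtered: dict[str, list[ScoredMutation]]
    report: list[ScoredMutation] = field(default_factory=list)


def run_pipeline(
    annotation: ReceptorAnnotation,
    msas: dict[str, list[tuple[str, str]]] | None = None,
    target_id: str | None = None,
    structure: StructureModel | None = None,
    ml_models: list[PredictionModel] | None = None,
    pocket: PocketExclusionSet | None = None,
    seed: int = 0,
    top_k: int = 40,
    design_config: DesignConfig | None = None,
) -> PipelineResult:
    """Run every lane with available inputs and build the merged report.

    The knowledge lane always runs; the sequence lane needs MSAs, the
    structure lane a structural model, and the ML lane both a model
    and a trained ensemble.  Lanes without inputs are skipped.
    """
    per_module: dict[str, list[ScoredMutation]] = {}
    per_module["knowledge"] = score_knowledge(annotation)

    if msas:
        profiles = [
            build_profiles(msa, target_id or "target") for msa in msas.values()
        ]
        matrices = [
            score_matrix(prof, msa_id=name)
            for prof, name in zip(profiles, msas.keys())
        ]
        net = net_score_matrix(matrices)
        per_module["sequence"] = propose_sequence_mutations(
            net, profiles, annotation, top_k=top_k
        )

    if structure is not None:
        per_module["structure"] = propose_structure_mutations(
            structure, seed=seed, config=design_config
        )

    if structure is not None and ml_models:
        per_module["ml"] = propose_ml_mutations(
            structure, annotation, ml_models, seed=seed
        )

    if pocket is None:
        pocket = load_default_exclusion_set()
    filtered = {
        name: filter_candidates(cands, pocket, annotation)
        for name, cands in per_module.items()
    }
    report = merge_and_rank(filtered, top_k=top_k)
    return PipelineResult(per_module=per_module, filtered=filtered, report=report)
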