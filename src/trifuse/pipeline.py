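"""End-to-end orchestration: fit every condition, then predict and rank.

Ties the modules together the way the full analysis runs: factorize each
cell condition, cluster the disease conditions' gene factors, screen the
clusters for enrichment in the known disease genes, take stage-specific
predictions per time point, and intersect them into movement-ranked core
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data_io import ConditionInputs
from .embedding_analysis import (
    ClusterAssignment,
    EnrichmentResult,
    MovementVector,
    cluster_enrichment,
    cluster_genes,
    compute_gmm,
    compute_movement,
)
from .nmtf_core import DecompositionConfig, FitResult, compute_U, fit
from .prediction import (
    CorePredictions,
    StagePredictions,
    core_predictions,
    stage_specific_predictions,
)

CONTROL, DISEASE = "control", "disease"


@dataclass
class StudyAnalysis:
    fits: dict[tuple[str, int], FitResult]
    assignments: dict[int, ClusterAssignment]
    enrichments: dict[int, EnrichmentResult]
    movements: dict[int, MovementVector]
    stages: list[StagePredictions]
    core: CorePredictions


def fit_conditions(
    conditions: dict[tuple[str, int], ConditionInputs], config: DecompositionConfig
) -> dict[tuple[str, int], FitResult]:
    """Factorize every cell condition with the same configuration."""
    return {key: fit(cond, config) for key, cond in sorted(conditions.items())}


def analyze_study(
    conditions: dict[tuple[str, int], ConditionInputs],
    disease_genes: set[str],
    config: DecompositionConfig,
    alpha: float = 0.05,
    cluster_restarts: int = 10,
    fits: dict[tuple[str, int], FitResult] | None = None,
) -> StudyAnalysis:
    """Run the full two-step prediction pipeline on paired conditions.

    ``conditions`` maps ``(line, day)`` to its inputs, with both a control
    and a disease entry per day. Clustering uses the disease conditions'
    G1 at k1 clusters; movement uses U = G1 S5 between the disease and
    control conditions of each day.
    """
    if fits is None:
        fits = fit_conditions(conditions, config)
    days = sorted({day for _, day in conditions})

    assignments: dict[int, ClusterAssignment] = {}
    enrichments: dict[int, EnrichmentResult] = {}
    movements: dict[int, MovementVector] = {}
    stages: list[StagePredictions] = []
    for day in days:
        dis = conditions[(DISEASE, day)]
        ctl = conditions[(CONTROL, day)]
        genes_dis = dis.expression.gene_ids
        assignment = cluster_genes(
            fits[(DISEASE, day)].factors.G1,
            genes_dis,
            k=config.k1,
            seed=config.seed,
            restarts=cluster_restarts,
        )
        enrichment = cluster_enrichment(
            assignment, disease_genes, universe=set(genes_dis), alpha=alpha
        )
        stages.append(
            stage_specific_predictions(
                enrichment,
                assignment,
                disease_genes=disease_genes,
                control_expressed=ctl.expression.expressed_genes(),
                day=day,
            )
        )
        gmm_dis = compute_gmm(compute_U(fits[(DISEASE, day)].factors), genes_dis)
        gmm_ctl = compute_gmm(
            compute_U(fits[(CONTROL, day)].factors), ctl.expression.gene_ids
        )
        movements[day] = compute_movement(gmm_dis, gmm_ctl)
        assignments[day] = assignment
        enrichments[day] = enrichment

    core = core_predictions(stages, movements)
    return StudyAnalysis(
        fits=fits,
        assignments=assignments,
        enrichments=enrichments,
        movements=movements,
        stages=stages,
        core=core,
    )
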