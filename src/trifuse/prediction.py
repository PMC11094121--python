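"""Two-step disease-gene prediction from enriched embedding clusters.

Step 1, per time point: cluster the disease condition's genes, keep the
clusters significantly enriched in the known disease-gene set, and collect
their member genes that are (a) not themselves labelled disease genes and
(b) expressed in the time-matched control — the *stage-specific
predictions*. Step 2: intersect the stage-specific sets across all time
points to get the *core predictions*, ranked by each gene's average
movement between disease and control across time points, largest first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ValidationError
from .embedding_analysis import ClusterAssignment, EnrichmentResult, MovementVector


@dataclass
class StagePredictions:
    day: int
    genes: set[str]
    provenance: list[int]  # enriched-cluster labels the genes came from


@dataclass
class CorePredictions:
    """Ranked consensus predictions with per-day and average movements."""

    table: pd.DataFrame  # gene, avg_movement, movement_d<day>..., rank

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


def stage_specific_predictions(
    enrichment: EnrichmentResult,
    assignment: ClusterAssignment,
    disease_genes: set[str],
    control_expressed: set[str],
    day: int = 0,
) -> StagePredictions:
    """Genes of enriched clusters, minus disease labels, in the control."""
    if len(enrichment.table) != assignment.k:
        raise ValidationError("enrichment and assignment describe different clusterings")
    enriched = enrichment.significant_clusters()
    genes: set[str] = set()
    for label in enriched:
        genes |= assignment.members(label)
    genes = (genes - disease_genes) & control_expressed
    return StagePredictions(day=day, genes=genes, provenance=enriched)


def core_predictions(
    stages: list[StagePredictions],
    movements: dict[int, MovementVector],
) -> CorePredictions:
    """Intersect stage predictions and rank by average movement, largest first.

    Every intersected gene must have a movement value at every day (a gene
    expressed at all time points does); ties in average movement break
    lexicographically by gene id.
    """
    if len(stages) < 2:
        raise ValidationError("need at least two stages to take a consensus")
    core = set.intersection(*(s.genes for s in stages))
    days = sorted(movements)
    series = {d: movements[d].as_series() for d in days}
    for g in sorted(core):
        for d in days:
            if g not in series[d].index:
                raise ValidationError(f"gene {g!r} has no movement value at day {d}")
    rows = []
    for g in sorted(core):
        per_day = [float(series[d][g]) for d in days]
        rows.append([g, float(np.mean(per_day))] + per_day)
    cols = ["gene", "avg_movement"] + [f"movement_d{d}" for d in days]
    table = pd.DataFrame(rows, columns=cols)
    table = table.sort_values(
        ["avg_movement", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return CorePredictions(table=table)


def overlap_matrix(stages: list[StagePredictions]) -> pd.DataFrame:
    """Pairwise intersection sizes plus the all-way intersection size.

    Returns a symmetric table indexed by day (diagonal = set size) with an
    attached ``.attrs['global_intersection']`` count.
    """
    days = [s.day for s in stages]
    sets = [s.genes for s in stages]
    M = np.zeros((len(stages), len(stages)), dtype=int)
    for i in range(len(stages)):
        for j in range(len(stages)):
            M[i, j] = len(sets[i] & sets[j])
    df = pd.DataFrame(M, index=days, columns=days)
    df.attrs["global_intersection"] = len(set.intersection(*sets)) if sets else 0
    return df
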