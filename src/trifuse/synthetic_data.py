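"""Synthetic paired control/disease multi-timepoint studies.

Generates the full input bundle the pipeline consumes — one expression
matrix plus four aligned interaction networks per cell condition, a
known-disease-gene annotation set, and ground truth — with planted
structure at every level:

* genes and cells belong to latent blocks; expression is a non-negative
  block factor product plus half-normal noise (half-normal keeps the matrix
  non-negative without clipping artifacts);
* the four networks are independent stochastic-block-model draws aligned to
  the gene blocks;
* in the disease line, a planted set of "disease genes" has its latent rows
  mixed toward a common freshly drawn block signature, so the planted genes
  form a coherent perturbed module whose relative geometry differs from the
  control line — the signal the movement statistic and the cluster
  enrichment screen are designed to detect;
* the annotation set contains a configurable fraction of the planted genes
  plus random decoys, mimicking an incomplete disease-gene catalogue.

The generator targets the geometric and statistical structure the method
assumes; it does not imitate real scRNA-seq count distributions (library
size, zero inflation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import (
    ConditionInputs,
    ExpressionMatrix,
    GeneSetCollection,
    InteractionNetwork,
    NETWORK_KINDS,
    ValidationError,
)
from .embedding_analysis import compute_gmm, compute_movement
from .nmtf_core import FitResult, compute_U
from .validation_stats import TwoSampleTestResult, mwu_one_sided

CONTROL, DISEASE = "control", "disease"


@dataclass
class StudyConfig:
    n_genes: int = 200
    n_cells: int = 100
    n_timepoints: int = 4
    k_true: int = 5
    k2_true: int = 5
    noise_sd: float = 0.05
    n_disease_genes: int = 20
    perturbation_strength: float = 1.0
    within_block_edge_prob: float = 0.3
    between_block_edge_prob: float = 0.02
    fraction_annotated_disease: float = 0.5
    decoy_fraction: float = 0.05
    dropout_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_block_edge_prob", "between_block_edge_prob",
                     "fraction_annotated_disease", "decoy_fraction", "dropout_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.perturbation_strength < 0:
            raise ValidationError("perturbation_strength must be non-negative")
        if self.n_disease_genes > self.n_genes:
            raise ValidationError("n_disease_genes cannot exceed n_genes")
        if self.within_block_edge_prob < self.between_block_edge_prob:
            raise ValidationError("within-block edges must be at least as likely as between")
        if self.k_true > self.n_genes or self.k2_true > self.n_cells:
            raise ValidationError("block counts cannot exceed matrix dimensions")


@dataclass
class SyntheticStudy:
    config: StudyConfig
    conditions: dict[tuple[str, int], ConditionInputs]
    gene_block_labels: np.ndarray
    cell_block_labels: np.ndarray
    planted_genes: list[str]
    annotations: GeneSetCollection

    @property
    def days(self) -> list[int]:
        return sorted({day for _, day in self.conditions})

    @property
    def gene_ids(self) -> list[str]:
        first = next(iter(self.conditions.values()))
        return first.expression.gene_ids


def _block_rows(rng: np.random.Generator, labels: np.ndarray, k: int) -> np.ndarray:
    """Non-negative factor rows near the axis of each row's block."""
    n = labels.shape[0]
    rows = 0.05 * rng.random((n, k))
    rows[np.arange(n), labels] += rng.uniform(0.8, 1.2, size=n)
    return rows


def _sbm_network(
    draw: np.ndarray,
    kind: str,
    gene_ids: list[str],
    membership: np.ndarray,
    p_in: float,
    p_out: float,
) -> InteractionNetwork:
    """Stochastic-block-model network from soft block memberships.

    ``membership`` rows are (mixed) one-hot block vectors; the edge
    probability is p_out + (p_in - p_out) * (m_i . m_j), which reduces to
    the plain SBM for exact one-hot rows. ``draw`` is a pre-drawn uniform
    matrix, shared across conditions so that two conditions differing only
    in a few memberships get near-identical networks (common random
    numbers), mirroring how condition-specific networks induced from one
    database differ only where the genes differ.
    """
    probs = p_out + (p_in - p_out) * (membership @ membership.T)
    upper = np.triu(draw < probs, k=1)
    ii, jj = np.nonzero(upper)
    edges = {(gene_ids[i], gene_ids[j]) for i, j in zip(ii, jj)}
    return InteractionNetwork(kind=kind, node_ids=list(gene_ids), edges=edges)


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate one paired control/disease study; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    n, m, k, k2 = config.n_genes, config.n_cells, config.k_true, config.k2_true

    gene_ids = [f"g{i:04d}" for i in range(n)]
    gene_blocks = (np.arange(n) * k) // n
    cell_blocks = (np.arange(m) * k2) // m

    G1_base = _block_rows(rng, gene_blocks, k)
    G2_base = _block_rows(rng, cell_blocks, k2)
    S5 = rng.uniform(0.3, 1.0, size=(k, k2))
    r = min(k, k2)
    S5[np.arange(r), np.arange(r)] += 1.0  # keep cell blocks distinguishable

    # planted genes are drawn outside the target block: reassignment must
    # actually change their geometry for them to be disease ground truth
    target_block = int(rng.integers(k))
    eligible = np.nonzero(gene_blocks != target_block)[0]
    if eligible.size < config.n_disease_genes:
        raise ValidationError("too many disease genes for the non-target blocks")
    planted_idx = np.sort(rng.choice(eligible, size=config.n_disease_genes, replace=False))
    planted = [gene_ids[i] for i in planted_idx]
    redrawn = _block_rows(rng, np.full(config.n_disease_genes, target_block), k)
    # mixing weight: 0 leaves planted genes untouched, 1 fully reassigns
    # their latent rows to the target block; values above 1 saturate
    w = min(config.perturbation_strength, 1.0)
    G1_disease = G1_base.copy()
    G1_disease[planted_idx] = (1 - w) * G1_base[planted_idx] + w * redrawn

    membership_control = np.eye(k)[gene_blocks]
    membership_disease = membership_control.copy()
    membership_disease[planted_idx] = (1 - w) * membership_control[planted_idx]
    membership_disease[planted_idx, target_block] += w

    # annotation set: a fraction of the planted genes plus random decoys
    n_annot = int(np.ceil(config.fraction_annotated_disease * config.n_disease_genes))
    shuffled = rng.permutation(config.n_disease_genes)
    annotated_planted = {planted[i] for i in shuffled[:n_annot]}
    non_planted = [g for g in gene_ids if g not in set(planted)]
    n_decoys = min(len(non_planted), int(round(config.decoy_fraction * n)))
    decoys = set(rng.choice(non_planted, size=n_decoys, replace=False)) if n_decoys else set()
    disease_set = annotated_planted | decoys
    if not disease_set:
        raise ValidationError("annotation set is empty; raise fraction_annotated_disease")
    annotations = GeneSetCollection(
        sets={"disease_genes": disease_set}, universe=set(gene_ids)
    )

    # one uniform draw per network kind, shared by every condition: the
    # control and disease networks then differ only around the planted genes
    network_draws = {kind: rng.random((n, n)) for kind in NETWORK_KINDS}
    networks_by_line = {
        line: {
            kind: _sbm_network(
                network_draws[kind], kind, gene_ids, membership,
                config.within_block_edge_prob, config.between_block_edge_prob,
            )
            for kind in NETWORK_KINDS
        }
        for line, membership in ((CONTROL, membership_control), (DISEASE, membership_disease))
    }

    conditions: dict[tuple[str, int], ConditionInputs] = {}
    for line in (CONTROL, DISEASE):
        G1_line = G1_base if line == CONTROL else G1_disease
        for day in range(config.n_timepoints):
            noise = np.abs(rng.normal(0.0, config.noise_sd, size=(n, m))) if config.noise_sd else 0.0
            E = G1_line @ S5 @ G2_base.T + noise
            if config.dropout_fraction > 0:
                n_drop = int(round(config.dropout_fraction * n))
                drop = rng.choice(n, size=n_drop, replace=False)
                E = E.copy()
                E[drop, :] = 0.0
            cell_ids = [f"{line}_d{day}_c{j:03d}" for j in range(m)]
            expr = ExpressionMatrix(
                gene_ids=list(gene_ids),
                cell_ids=cell_ids,
                values=E,
                condition=(line, day),
            )
            conditions[(line, day)] = ConditionInputs(
                expression=expr, networks=networks_by_line[line]
            )

    return SyntheticStudy(
        config=config,
        conditions=conditions,
        gene_block_labels=gene_blocks,
        cell_block_labels=cell_blocks,
        planted_genes=planted,
        annotations=annotations,
    )


def movement_effect_check(
    study: SyntheticStudy, fits: dict[tuple[str, int], FitResult]
) -> dict[int, TwoSampleTestResult]:
    """MWU test that planted genes move more than background, per day.

    Movement is computed between the disease and control condition of each
    time point from the fitted embeddings U = G1 S5.
    """
    planted = set(study.planted_genes)
    results: dict[int, TwoSampleTestResult] = {}
    for day in study.days:
        gmms = {}
        for line in (CONTROL, DISEASE):
            cond = study.conditions[(line, day)]
            U = compute_U(fits[(line, day)].factors)
            gmms[line] = compute_gmm(U, cond.expression.gene_ids)
        mv = compute_movement(gmms[DISEASE], gmms[CONTROL]).as_series()
        x = mv[mv.index.isin(planted)].to_numpy()
        y = mv[~mv.index.isin(planted)].to_numpy()
        results[day] = mwu_one_sided(x, y, alternative="greater")
    return results
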