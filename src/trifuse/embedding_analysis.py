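"""Geometry and cluster-level summaries of the fitted gene embeddings.

Two embedding views are used downstream: the rows of ``G1`` (dominated by
the networks; used for clustering) and the rows of ``U = G1 S5`` (projected
into the cell-space coordinates; used for the cross-condition "gene
movement"). The gene mapping matrix (GMM) of a condition holds all pairwise
Euclidean distances between rows of U divided by ||U||_F, so it captures
each gene's position *relative to every other gene* in that condition,
independent of the embedding's overall scale or orientation. The movement
of a gene between two conditions is the Euclidean distance between its GMM
row in one condition and in the other, over the shared genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom
from sklearn.cluster import KMeans

from .data_io import ValidationError


@dataclass
class GeneMappingMatrix:
    """Symmetric, zero-diagonal matrix of norm-scaled embedding distances."""

    gene_ids: list[str]
    values: np.ndarray

    def restrict(self, genes: list[str]) -> np.ndarray:
        """Rows and columns for ``genes``, in the given order."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in genes]
        return self.values[np.ix_(idx, idx)]


@dataclass
class MovementVector:
    """Per-gene movement between two conditions, over their shared genes."""

    gene_ids: list[str]
    values: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.gene_ids, name="movement")


@dataclass
class ClusterAssignment:
    gene_ids: list[str]
    labels: np.ndarray
    k: int
    seed: int
    restarts: int

    def members(self, label: int) -> set[str]:
        return {g for g, l in zip(self.gene_ids, self.labels) if l == label}


@dataclass
class EnrichmentResult:
    """Per-cluster hypergeometric enrichment in an annotated gene set."""

    table: pd.DataFrame  # cluster, size, overlap, p_value, fold_enrichment, significant
    alpha: float

    def significant_clusters(self) -> list[int]:
        return [int(c) for c in self.table.loc[self.table["significant"], "cluster"]]


def compute_gmm(U: np.ndarray, gene_ids: list[str]) -> GeneMappingMatrix:
    """Pairwise Euclidean distances between gene embeddings, / ||U||_F."""
    U = np.asarray(U, float)
    if U.shape[0] != len(gene_ids):
        raise ValidationError("gene_ids must match the rows of U")
    norm = np.linalg.norm(U)
    if norm == 0:
        raise ValidationError("all-zero embedding matrix has no relative geometry")
    D = squareform(pdist(U, metric="euclidean")) / norm
    return GeneMappingMatrix(gene_ids=list(gene_ids), values=D)


def compute_movement(gmm_a: GeneMappingMatrix, gmm_b: GeneMappingMatrix) -> MovementVector:
    """Movement of each shared gene between the two conditions.

    Both GMMs are restricted (rows and columns) to the shared genes in a
    canonical sorted order; the movement of gene i is the Euclidean distance
    between its restricted row in a and in b. Restricting rather than
    recomputing preserves each condition's own normalization.
    """
    shared = sorted(set(gmm_a.gene_ids) & set(gmm_b.gene_ids))
    if not shared:
        raise ValidationError("the two conditions share no genes")
    Da = gmm_a.restrict(shared)
    Db = gmm_b.restrict(shared)
    gm = np.linalg.norm(Da - Db, axis=1)
    return MovementVector(gene_ids=shared, values=gm)


def cluster_genes(
    G1: np.ndarray, gene_ids: list[str], k: int, seed: int = 0, restarts: int = 10
) -> ClusterAssignment:
    """k-means on the rows of G1 (squared-Euclidean objective, k-means++)."""
    G1 = np.asarray(G1, float)
    if k > G1.shape[0]:
        raise ValidationError(f"k={k} exceeds the number of genes {G1.shape[0]}")
    if k < 1:
        raise ValidationError("k must be positive")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(G1)
    return ClusterAssignment(
        gene_ids=list(gene_ids), labels=labels, k=k, seed=seed, restarts=restarts
    )


def cluster_enrichment(
    assignment: ClusterAssignment,
    annotated: set[str],
    universe: set[str],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Hypergeometric upper-tail enrichment of each cluster.

    For a cluster of size c with x annotated members, p = P(X >= x) with X
    hypergeometric(N=|universe|, K=|annotated ∩ universe|, c). Fold
    enrichment is (x/c) / (K/N). No multiple-testing correction is applied
    at this screening step; ``significant`` means raw p <= alpha.
    """
    genes = set(assignment.gene_ids)
    if not genes <= universe:
        raise ValidationError("assignment genes must be inside the universe")
    K_set = annotated & universe
    N, K = len(universe), len(K_set)
    if K == 0:
        warnings.warn("annotated set is empty within the universe; all p-values are 1")
    rows = []
    for label in range(assignment.k):
        members = assignment.members(label)
        c = len(members)
        x = len(members & K_set)
        p = 1.0 if K == 0 else float(hypergeom.sf(x - 1, N, K, c))
        fold = 0.0 if (c == 0 or K == 0) else (x / c) / (K / N)
        rows.append((label, c, x, min(p, 1.0), fold, p <= alpha))
    table = pd.DataFrame(
        rows,
        columns=["cluster", "size", "overlap", "p_value", "fold_enrichment", "significant"],
    )
    return EnrichmentResult(table=table, alpha=alpha)


def percent_enriched_clusters(result: EnrichmentResult) -> float:
    """Percentage of clusters significantly enriched (0..100)."""
    n = len(result.table)
    if n == 0:
        raise ValidationError("no clusters in enrichment result")
    return 100.0 * float(result.table["significant"].sum()) / n
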