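"""Statistics used to validate predicted disease genes.

Covers the one-sided Mann-Whitney U comparison of two score distributions
(e.g. literature co-occurrence counts, or movement values), an empirical
sampling-with-replacement test for the overlap of several prediction sets,
unweighted shortest-path proximity of gene groups to a target gene in an
interaction network, and hypergeometric gene-set / pathway enrichment with
Benjamini-Hochberg correction across pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .data_io import GeneSetCollection, InteractionNetwork, ValidationError

#: largest combined sample size at which the exact MWU null is enumerated
EXACT_MWU_MAX_N = 12


@dataclass
class TwoSampleTestResult:
    statistic: float
    p_value: float
    alternative: str
    n_x: int
    n_y: int
    method: str = ""


@dataclass
class ResamplingResult:
    observed_overlap: int
    null_overlaps: np.ndarray
    repetitions: int
    p_value: float


@dataclass
class PathDistanceResult:
    distances: dict[str, dict[str, int]]  # group -> gene -> shortest-path length
    unreachable: dict[str, list[str]]
    group_means: dict[str, float]


@dataclass
class EnrichmentTestResult:
    p_value: float
    fraction: float
    overlap: int
    n_predictions: int


def mwu_one_sided(x, y, alternative: str = "greater") -> TwoSampleTestResult:
    """One-sided Mann-Whitney U test of ``x`` against ``y``.

    Uses the exact null distribution (full enumeration over rank splits)
    when the combined sample size is at most ``EXACT_MWU_MAX_N`` and there
    are no ties; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValidationError("alternative must be 'greater' or 'less'")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    exact = no_ties and pooled.size <= EXACT_MWU_MAX_N
    res = scipy.stats.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return TwoSampleTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        n_x=x.size,
        n_y=y.size,
        method="exact" if exact else "asymptotic",
    )


def overlap_resampling(
    observed_sets: list[set[str]],
    universes: list[set[str]],
    repetitions: int = 10_000,
    seed: int = 0,
    with_replacement: bool = False,
) -> ResamplingResult:
    """Empirical significance of the multi-way overlap of prediction sets.

    Null model: for each set i, draw a uniform random subset of universe_i
    of the same size as set_i, and record the size of the multi-way
    intersection of the draws. With ``with_replacement=True`` the draws are
    |set_i| independent picks reduced to their distinct members instead, so
    null sets are typically slightly smaller than the observed ones; the
    default preserves the observed set sizes exactly. The p-value uses the
    +1/(R+1) pseudo-count estimator, so it is never exactly zero.
    """
    if len(observed_sets) != len(universes):
        raise ValidationError("need one universe per observed set")
    if len(observed_sets) < 2:
        raise ValidationError("need at least two sets to measure an overlap")
    for s, u in zip(observed_sets, universes):
        if not s <= u:
            raise ValidationError("each observed set must be inside its universe")
    if repetitions < 100:
        warnings.warn("fewer than 100 repetitions gives a coarse p-value")
    rng = np.random.default_rng(seed)
    observed = len(set.intersection(*observed_sets))
    unis = [sorted(u) for u in universes]
    sizes = [len(s) for s in observed_sets]
    null = np.empty(repetitions, dtype=int)
    for r in range(repetitions):
        drawn = []
        for uni, size in zip(unis, sizes):
            idx = (
                rng.integers(0, len(uni), size=size)  # draw count = size, then distinct
                if with_replacement
                else rng.choice(len(uni), size=size, replace=False)
            )
            drawn.append({uni[i] for i in idx})
        null[r] = len(set.intersection(*drawn))
    p = (int(np.sum(null >= observed)) + 1) / (repetitions + 1)
    return ResamplingResult(
        observed_overlap=observed, null_overlaps=null, repetitions=repetitions, p_value=p
    )


def shortest_paths_to_target(
    net: InteractionNetwork, target: str, groups: dict[str, set[str]]
) -> PathDistanceResult:
    """Unweighted shortest-path lengths from each group's genes to ``target``.

    Genes absent from the network or disconnected from the target are
    listed as unreachable and excluded from the group means; the target
    itself is excluded from every group.
    """
    if target not in set(net.node_ids):
        raise ValidationError(f"target gene {target!r} is not in the network")
    g = nx.Graph()
    g.add_nodes_from(net.node_ids)
    g.add_edges_from(net.edges)
    lengths = nx.single_source_shortest_path_length(g, target)
    distances: dict[str, dict[str, int]] = {}
    unreachable: dict[str, list[str]] = {}
    means: dict[str, float] = {}
    for name, members in groups.items():
        dist = {}
        missing = []
        for gene in sorted(members - {target}):
            if gene in lengths:
                dist[gene] = int(lengths[gene])
            else:
                missing.append(gene)
        distances[name] = dist
        unreachable[name] = missing
        means[name] = float(np.mean(list(dist.values()))) if dist else float("nan")
    return PathDistanceResult(distances=distances, unreachable=unreachable, group_means=means)


def gene_set_enrichment(
    predictions: set[str], annotated: set[str], background: set[str]
) -> EnrichmentTestResult:
    """Hypergeometric upper-tail enrichment of predictions in a gene set.

    The universe is ``predictions | background``; the annotated set is
    intersected with it. Also reports the supported fraction
    |predictions ∩ annotated| / |predictions|.
    """
    if not predictions:
        raise ValidationError("prediction set is empty")
    universe = predictions | background
    K = len(annotated & universe)
    x = len(predictions & annotated)
    p = 1.0 if K == 0 else float(scipy.stats.hypergeom.sf(x - 1, len(universe), K, len(predictions)))
    return EnrichmentTestResult(
        p_value=min(p, 1.0),
        fraction=x / len(predictions),
        overlap=x,
        n_predictions=len(predictions),
    )


def pathway_enrichment(
    predictions: set[str],
    pathways: GeneSetCollection,
    background: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-pathway hypergeometric enrichment with BH correction.

    Returns a table (pathway, overlap, gene_count, p_value, p_adjusted,
    fold_enrichment, significant) ranked by adjusted p ascending, with raw
    p and pathway name breaking ties deterministically.
    """
    if not predictions:
        raise ValidationError("prediction set is empty")
    universe = predictions | background
    n = len(predictions)
    N = len(universe)
    rows = []
    for name in pathways.names():
        members = pathways[name] & universe
        K = len(members)
        x = len(predictions & members)
        p = 1.0 if K == 0 else float(scipy.stats.hypergeom.sf(x - 1, N, K, n))
        fold = 0.0 if K == 0 else (x / n) / (K / N)
        rows.append((name, x, K, min(p, 1.0), fold))
    df = pd.DataFrame(rows, columns=["pathway", "overlap", "gene_count", "p_value", "fold_enrichment"])
    if len(df):
        reject, p_adj, _, _ = multipletests(df["p_value"], alpha=alpha, method="fdr_bh")
        df["p_adjusted"] = p_adj
        df["significant"] = reject
    else:
        df["p_adjusted"] = []
        df["significant"] = []
    df = df.sort_values(
        ["p_adjusted", "p_value", "pathway"], kind="mergesort"
    ).reset_index(drop=True)
    return df[
        ["pathway", "overlap", "gene_count", "p_value", "p_adjusted", "fold_enrichment", "significant"]
    ]
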