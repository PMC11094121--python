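import numpy as np
import pytest

from trifuse.data_io import (
    ConditionInputs,
    ExpressionMatrix,
    InteractionNetwork,
    NETWORK_KINDS,
)
from trifuse.nmtf_core import DecompositionConfig, FactorSet


def make_network(kind, nodes, edges):
    return InteractionNetwork(kind=kind, node_ids=list(nodes), edges=set(edges))


def random_instance(seed, n=30, m=15, k1=4, k2=3, density=0.2):
    """A random non-negative problem instance (binary symmetric A_i, random E)."""
    rng = np.random.default_rng(seed)
    As = []
    for _ in range(4):
        A = np.triu((rng.random((n, n)) < density).astype(float), 1)
        As.append(A + A.T)
    E = 2.0 * rng.random((n, m))
    return E, As


def random_factors(seed, n=30, m=15, k1=4, k2=3):
    rng = np.random.default_rng(seed)
    return FactorSet(
        G1=rng.random((n, k1)),
        G2=rng.random((m, k2)),
        S=[rng.random((k1, k1)) for _ in range(4)],
        S5=rng.random((k1, k2)),
    )


def exact_instance(seed, n=24, m=12, k1=3, k2=3):
    """Inputs synthesized exactly from known non-negative block factors.

    S factors are symmetric so the networks A_i = G1 S_i G1^T are symmetric,
    as adjacency matrices are; G1/G2 rows are block-dominant so the true
    ranks are cleanly recoverable.
    """
    rng = np.random.default_rng(seed)

    def block_rows(rows, k):
        X = 0.05 * rng.random((rows, k))
        X[np.arange(rows), (np.arange(rows) * k) // rows] += 1.0
        return X

    S = []
    for _ in range(4):
        R = rng.random((k1, k1))
        S.append((R + R.T) / 2 + np.eye(k1))
    f = FactorSet(
        G1=block_rows(n, k1),
        G2=block_rows(m, k2),
        S=S,
        S5=rng.random((k1, k2)) + np.eye(k1, k2),
    )
    E = f.G1 @ f.S5 @ f.G2.T
    As = [f.G1 @ Si @ f.G1.T for Si in f.S]
    return f, E, As


@pytest.fixture
def tiny_condition():
    """4 genes x 3 cells with aligned 4-node networks of every kind."""
    genes = ["g1", "g2", "g3", "g4"]
    cells = ["c1", "c2", "c3"]
    rng = np.random.default_rng(7)
    expr = ExpressionMatrix(genes, cells, rng.random((4, 3)) + 0.1)
    nets = {
        kind: make_network(kind, genes, {("g1", "g2"), ("g2", "g3"), ("g3", "g4")})
        for kind in NETWORK_KINDS
    }
    return ConditionInputs(expression=expr, networks=nets)


@pytest.fixture(scope="session")
def small_study_analysis():
    """A reduced end-to-end run shared by pipeline-level tests."""
    from trifuse.pipeline import analyze_study
    from trifuse.synthetic_data import StudyConfig, generate_study

    config = StudyConfig(n_genes=120, n_cells=60, n_timepoints=2, seed=11)
    study = generate_study(config)
    dconfig = DecompositionConfig(k1=5, k2=5, max_iterations=400, seed=11)
    analysis = analyze_study(
        study.conditions, study.annotations["disease_genes"], dconfig
    )
    return study, analysis
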