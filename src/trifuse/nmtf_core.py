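"""Shared-factor non-negative matrix tri-factorization solver.

One cell condition contributes five matrices: four binary network
adjacencies ``A_1..A_4`` (PPI, GI, COEX, MI) and the expression matrix
``E``. All five are decomposed simultaneously,

    A_i ≈ G1 S_i G1^T,    E ≈ G1 S5 G2^T,

with one gene factor ``G1`` (n x k1) shared across every decomposition and a
cell factor ``G2`` (m x k2), minimizing

    F = sum_i ||A_i - G1 S_i G1^T||_F^2 + ||E - G1 S5 G2^T||_F^2

subject to G1, G2 >= 0. The solver initializes from the absolute values of
truncated SVD factors (making it deterministic) and iterates multiplicative
update rules, which preserve non-negativity; this solver keeps the S factors
non-negative too, a deliberate restriction that the initialization and the
multiplicative updates maintain automatically.

Latent ranks are chosen by clustering-stability: the rank maximizing the
dispersion coefficient of a consensus connectivity matrix built from
repeated k-means runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .data_io import ConditionInputs, ValidationError


class NumericalError(RuntimeError):
    """A factor became non-finite during iteration."""


@dataclass
class DecompositionConfig:
    k1: int
    k2: int
    max_iterations: int = 1000
    check_every: int = 10
    rel_tolerance: float = 1e-3
    epsilon: float = 1e-10
    zero_tolerance: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k1 < 1 or self.k2 < 1:
            raise ValidationError("ranks k1, k2 must be positive")
        if self.max_iterations < 1 or self.check_every < 1:
            raise ValidationError("max_iterations and check_every must be positive")
        if self.rel_tolerance <= 0 or self.epsilon <= 0:
            raise ValidationError("rel_tolerance and epsilon must be positive")


@dataclass
class FactorSet:
    """G1 (n x k1), G2 (m x k2), S (four k1 x k1), S5 (k1 x k2)."""

    G1: np.ndarray
    G2: np.ndarray
    S: list[np.ndarray]
    S5: np.ndarray

    def copy(self) -> "FactorSet":
        return FactorSet(
            self.G1.copy(), self.G2.copy(), [s.copy() for s in self.S], self.S5.copy()
        )


@dataclass
class FitResult:
    factors: FactorSet
    objective_history: list[float]
    iterations_run: int
    converged: bool


@dataclass
class DimensionSelection:
    candidate_ks: list[int]
    dispersion: list[float]
    chosen_k: int


def _as_arrays(inputs) -> tuple[np.ndarray, list[np.ndarray]]:
    if isinstance(inputs, ConditionInputs):
        return inputs.matrices()
    E, As = inputs
    return np.asarray(E, float), [np.asarray(A, float) for A in As]


def objective_value(factors: FactorSet, inputs) -> float:
    """Sum of the five squared Frobenius residuals."""
    E, As = _as_arrays(inputs)
    G1, G2, S5 = factors.G1, factors.G2, factors.S5
    if G1.shape[0] != E.shape[0] or G2.shape[0] != E.shape[1]:
        raise ValidationError("factor shapes do not match the inputs")
    if len(As) != len(factors.S):
        raise ValidationError("number of networks does not match S factors")
    value = float(np.linalg.norm(E - G1 @ S5 @ G2.T) ** 2)
    for A, Si in zip(As, factors.S):
        if A.shape != (G1.shape[0], G1.shape[0]):
            raise ValidationError("network adjacency shape mismatch")
        value += float(np.linalg.norm(A - G1 @ Si @ G1.T) ** 2)
    return value


def svd_initialize(inputs, config: DecompositionConfig) -> FactorSet:
    """Deterministic initialization from truncated SVDs.

    G1 comes from the top-k1 left singular vectors of the column-wise
    concatenation [A_1|A_2|A_3|A_4|E] (so the shared gene factor reflects
    every input); G2 from the top-k2 right singular vectors of E; S5 from
    E's leading singular values on the diagonal; S_i = |G1^T A_i G1|.
    Non-negativity is enforced by taking absolute values, which also makes
    the result independent of SVD sign conventions.
    """
    E, As = _as_arrays(inputs)
    n, m = E.shape
    if config.k1 > n or config.k2 > m:
        raise ValidationError(f"requested ranks ({config.k1},{config.k2}) exceed ({n},{m})")
    concat = np.concatenate(As + [E], axis=1)
    U_cat, s_cat, _ = np.linalg.svd(concat, full_matrices=False)
    tiny = max(concat.shape) * np.finfo(float).eps * (s_cat[0] if s_cat.size else 0.0)
    if np.sum(s_cat > tiny) < config.k1:
        raise ValidationError(
            f"inputs have rank < k1={config.k1}; choose a smaller gene rank"
        )
    Ue, se, Vte = np.linalg.svd(E, full_matrices=False)
    tiny_e = max(E.shape) * np.finfo(float).eps * (se[0] if se.size else 0.0)
    if np.sum(se > tiny_e) < config.k2:
        raise ValidationError(
            f"expression matrix has rank < k2={config.k2}; choose a smaller cell rank"
        )
    G1 = np.abs(U_cat[:, : config.k1])
    G2 = np.abs(Vte[: config.k2, :].T)
    S5 = np.zeros((config.k1, config.k2))
    r = min(config.k1, config.k2)
    S5[:r, :r] = np.diag(se[:r])
    S = [np.abs(G1.T @ A @ G1) for A in As]
    return FactorSet(G1=G1, G2=G2, S=S, S5=S5)


def mur_update(factors: FactorSet, inputs, epsilon: float = 1e-10) -> FactorSet:
    """One multiplicative-update sweep in the order G1, G2, S_i, S5.

    Each factor is multiplied element-wise by the ratio of the negative to
    the positive part of the objective gradient (the standard KKT
    construction), so non-negativity is preserved and exact zeros stay zero.
    G1 appears on both sides of the network terms, hence the symmetric pair
    A_i G1 S_i^T + A_i G1 S_i in its numerator.
    """
    E, As = _as_arrays(inputs)
    G1, G2, S5 = factors.G1, factors.G2, factors.S5
    S = factors.S

    num = E @ G2 @ S5.T
    den = G1 @ S5 @ (G2.T @ G2) @ S5.T
    GtG = G1.T @ G1
    for A, Si in zip(As, S):
        num = num + A @ G1 @ Si.T + A @ G1 @ Si
        den = den + G1 @ (Si @ GtG @ Si.T + Si.T @ GtG @ Si)
    G1 = G1 * (num / (den + epsilon))

    GtG = G1.T @ G1
    G2 = G2 * ((E.T @ G1 @ S5) / (G2 @ S5.T @ GtG @ S5 + epsilon))
    S = [Si * ((G1.T @ A @ G1) / (GtG @ Si @ GtG + epsilon)) for A, Si in zip(As, S)]
    S5 = S5 * ((G1.T @ E @ G2) / (GtG @ S5 @ (G2.T @ G2) + epsilon))

    out = FactorSet(G1=G1, G2=G2, S=S, S5=S5)
    for name, M in (("G1", G1), ("G2", G2), ("S5", S5), *((f"S{i+1}", Si) for i, Si in enumerate(S))):
        if not np.all(np.isfinite(M)):
            raise NumericalError(f"non-finite values in factor {name}")
    return out


def fit(inputs, config: DecompositionConfig, init: FactorSet | None = None) -> FitResult:
    """SVD-initialize then iterate MUR sweeps until convergence.

    The objective is recorded every ``check_every`` iterations (and at
    iteration 0); iteration stops once the relative change between
    consecutive recordings drops to ``rel_tolerance`` (default 1e-3 over a
    10-iteration window), or when the objective is exactly zero, or at
    ``max_iterations``. Deterministic for fixed inputs and config. An
    explicit ``init`` factor set overrides the SVD initialization (used by
    the stability-based rank scan).

    An exactly factorizable input drives the objective geometrically toward
    numerical zero, in which case the relative change stalls at the decay
    rate and the relative rule alone would never fire; the fit is therefore
    also declared converged once the objective drops below
    ``zero_tolerance`` times its initial value.
    """
    E, As = _as_arrays(inputs)
    factors = init.copy() if init is not None else svd_initialize((E, As), config)
    history = [objective_value(factors, (E, As))]
    zero_floor = config.zero_tolerance * history[0]
    converged = history[0] <= 0.0
    it = 0
    while it < config.max_iterations and not converged:
        it += 1
        try:
            factors = mur_update(factors, (E, As), epsilon=config.epsilon)
        except NumericalError as exc:
            raise NumericalError(f"{exc} at iteration {it}") from exc
        if it % config.check_every == 0:
            f_now = objective_value(factors, (E, As))
            f_prev = history[-1]
            history.append(f_now)
            if f_now <= zero_floor or abs(f_prev - f_now) / f_now <= config.rel_tolerance:
                converged = True
    return FitResult(
        factors=factors,
        objective_history=history,
        iterations_run=it,
        converged=converged,
    )


def compute_U(factors: FactorSet) -> np.ndarray:
    """Gene embeddings in the cell-space coordinates: U = G1 @ S5."""
    return factors.G1 @ factors.S5


def consensus_connectivity(label_runs: Sequence[np.ndarray]) -> np.ndarray:
    """Fraction of runs in which each item pair shares a cluster.

    Symmetric with a unit diagonal; entries in [0, 1].
    """
    runs = [np.asarray(lab) for lab in label_runs]
    if not runs:
        raise ValidationError("need at least one label run")
    n = runs[0].shape[0]
    if any(lab.shape != (n,) for lab in runs):
        raise ValidationError("label runs must all have the same length")
    C = np.zeros((n, n))
    for lab in runs:
        C += (lab[:, None] == lab[None, :]).astype(float)
    return C / len(runs)


def dispersion_coefficient(consensus: np.ndarray) -> float:
    """rho = (1/n^2) sum_ij 4 (C_ij - 1/2)^2; 1 means perfectly stable."""
    C = np.asarray(consensus, float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValidationError("consensus matrix must be square")
    n = C.shape[0]
    return float(np.sum(4.0 * (C - 0.5) ** 2) / (n * n))


def jittered_initialize(
    inputs, config: DecompositionConfig, rng: np.random.Generator, sigma: float = 1.5
) -> FactorSet:
    """SVD initialization perturbed by multiplicative log-normal noise.

    Each factor entry is multiplied by exp(N(0, sigma^2)), giving a
    stochastic restart that stays non-negative and on the data's scale.
    Restarts land in the same basin when the rank matches stable structure
    and in different basins when it does not, which is what the
    stability-based rank scan measures.
    """
    base = svd_initialize(inputs, config)

    def jitter(M: np.ndarray) -> np.ndarray:
        return M * np.exp(rng.normal(0.0, sigma, M.shape))

    return FactorSet(
        G1=jitter(base.G1),
        G2=jitter(base.G2),
        S=[jitter(s) for s in base.S],
        S5=jitter(base.S5),
    )


def restart_embedder(
    inputs,
    k2: int | None = None,
    sweeps: int = 300,
    jitter_sigma: float = 1.5,
) -> Callable[[int, int], np.ndarray]:
    """Build the per-restart embedding callable for ``select_dimension``.

    ``embed(k, run_seed)`` refits the decomposition at gene rank k (cell
    rank ``k2``, defaulting to k) from a jittered SVD initialization with
    a fixed number of MUR sweeps, and returns the resulting G1 rows.
    """
    E, As = _as_arrays(inputs)
    cache: dict[int, DecompositionConfig] = {}

    def embed(k: int, run_seed: int) -> np.ndarray:
        config = cache.setdefault(
            k, DecompositionConfig(k1=k, k2=k2 or k, max_iterations=sweeps,
                                   check_every=sweeps, rel_tolerance=1e-12)
        )
        rng = np.random.default_rng(run_seed)
        init = jittered_initialize((E, As), config, rng, sigma=jitter_sigma)
        factors = init
        for _ in range(sweeps):
            factors = mur_update(factors, (E, As))
        return factors.G1

    return embed


def select_dimension(
    embed: Callable[[int, int], np.ndarray],
    candidates: Sequence[int],
    runs: int = 20,
    seed: int = 0,
) -> DimensionSelection:
    """Pick the rank whose consensus clustering is most stable.

    For each candidate k, ``embed(k, run_seed)`` produces the factor rows
    for one stochastic restart (G1 for the gene rank, G2 for the cell
    rank; see :func:`restart_embedder`); each restart's rows are clustered
    into k groups, the consensus connectivity matrix over the ``runs``
    restarts is built, and its dispersion coefficient computed. The
    candidate maximizing dispersion wins; ties go to the smallest k.
    """
    if runs < 2:
        raise ValidationError("need at least 2 clustering runs for a consensus")
    cands = list(candidates)
    if not cands:
        raise ValidationError("no candidate ranks given")
    rhos = []
    for k in cands:
        labels = []
        for r in range(runs):
            X = np.asarray(embed(k, seed + r), float)
            labels.append(
                KMeans(n_clusters=k, n_init=10, random_state=seed + r).fit_predict(X)
            )
        rhos.append(dispersion_coefficient(consensus_connectivity(labels)))
    best = min(range(len(cands)), key=lambda i: (-rhos[i], cands[i]))
    return DimensionSelection(candidate_ks=cands, dispersion=rhos, chosen_k=cands[best])
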