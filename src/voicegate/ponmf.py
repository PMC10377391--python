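"""Pareto-optimized non-negative matrix factorization of the masked spectrogram.

The masked magnitude spectrogram ``V = |S_mod|`` is approximated as a
product ``W H`` of a non-negative basis (spectral templates, m x k) and
non-negative weights (activations, k x n).  Factorization minimizes the
L1-penalized Frobenius objective

    ||V - W H||_F^2  +  lambda * ||H||_1

by multiplicative updates, which preserve non-negativity exactly and,
for lambda = 0, decrease the Frobenius objective monotonically.

Model selection is multi-objective: every candidate on a (rank k,
sparsity weight lambda) grid is scored on three normalized, minimized
objectives —

    f1  relative reconstruction error   ||V - WH||_F / ||V||_F
    f2  activation density              1 - hoyer_sparsity(H)
    f3  model complexity                k / k_max

— the Pareto front (mutually non-dominated candidates) is extracted
exactly by pairwise dominance, and the compromise solution is the front
member closest (Euclidean, after per-objective min-max normalization) to
the ideal point, with deterministic tie-breaks.  The selected model's
magnitude reconstruction replaces |S_mod|; the original phase is reused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spectral import Spectrogram

logger = logging.getLogger(__name__)

__all__ = [
    "NMFModel",
    "ObjectiveVector",
    "ParetoCandidate",
    "nmf_factorize",
    "hoyer_sparsity",
    "objective_vector",
    "pareto_front",
    "select_solution",
    "clean_spectrogram",
]

_EPS = 1e-12

DEFAULT_K_GRID = (2, 4, 8, 16)
DEFAULT_LAMBDA_GRID = (0.0, 0.01, 0.1, 1.0)


@dataclass
class NMFModel:
    """A fitted non-negative factorization V ~= W H."""

    W: np.ndarray  # (m, k) basis spectra
    H: np.ndarray  # (k, n) activations
    k: int
    lambda_sparsity: float
    n_iter_run: int
    converged: bool
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


@dataclass(frozen=True)
class ObjectiveVector:
    """The three minimized model-selection objectives."""

    f1_recon: float
    f2_density: float
    f3_complexity: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f1_recon, self.f2_density, self.f3_complexity])


@dataclass
class ParetoCandidate:
    model: NMFModel
    objectives: ObjectiveVector
    on_front: bool = False
    selected: bool = False


def nmf_factorize(
    V: np.ndarray,
    k: int,
    lambda_sparsity: float = 0.0,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> NMFModel:
    """Factorize ``V >= 0`` by multiplicative updates.

    Updates (eps = 1e-12 guards division)::

        H <- H * (W^T V) / (W^T W H + lambda + eps)
        W <- W * (V H^T) / (W H H^T + eps)

    After each sweep the basis columns are rescaled to unit L2 norm with
    the inverse scale absorbed into H.  This leaves the product W H (and
    hence the fit term) unchanged but pins the scale split between the
    factors, without which the L1 activation penalty is ill-posed —
    inflating W while deflating H shrinks lambda * ||H||_1 at constant
    fit, so the sparsity weight would have no stable effect.

    Both factors are initialized from seeded uniform(0, 1) entries
    scaled by ``sqrt(mean(V) / k)`` so the initial product matches V's
    scale.  Iteration stops when the relative change of the penalized
    objective drops below ``tol`` or after ``max_iter`` sweeps.
    Identical inputs and seed give bit-identical factors.
    """
    V = np.asarray(V, dtype=np.float64)
    if V.ndim != 2:
        raise ValueError("V must be a matrix")
    if np.any(V < 0):
        raise ValueError("V must be non-negative")
    m, n = V.shape
    if not 1 <= k <= min(m, n):
        raise ValueError(f"rank k={k} outside [1, {min(m, n)}]")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if lambda_sparsity < 0:
        raise ValueError("lambda_sparsity must be >= 0")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(V.mean(), _EPS) / k)
    W = rng.uniform(0.0, 1.0, size=(m, k)) * scale
    H = rng.uniform(0.0, 1.0, size=(k, n)) * scale

    def objective(Wm: np.ndarray, Hm: np.ndarray) -> float:
        r = V - Wm @ Hm
        return float(np.sum(r * r) + lambda_sparsity * np.sum(np.abs(Hm)))

    history = [objective(W, H)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ V) / (W.T @ W @ H + lambda_sparsity + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        col = np.linalg.norm(W, axis=0)
        col = np.where(col > 0, col, 1.0)
        W /= col
        H *= col[:, None]
        obj = objective(W, H)
        history.append(obj)
        prev = history[-2]
        if prev > 0 and abs(prev - obj) / prev < tol:
            converged = True
            break
    return NMFModel(
        W=W,
        H=H,
        k=k,
        lambda_sparsity=lambda_sparsity,
        n_iter_run=it,
        converged=converged,
        objective_history=np.asarray(history),
    )


def hoyer_sparsity(H: np.ndarray) -> float:
    """Hoyer's sparsity measure, (sqrt(N) - ||H||_1 / ||H||_2) / (sqrt(N) - 1).

    0 for all-equal entries, 1 for a single nonzero entry.  An all-zero
    matrix is defined as maximally sparse (1).
    """
    H = np.asarray(H, dtype=np.float64)
    N = H.size
    l2 = np.linalg.norm(H.ravel())
    if l2 == 0:
        return 1.0
    l1 = np.abs(H).sum()
    root = np.sqrt(N)
    return float((root - l1 / l2) / (root - 1.0))


def objective_vector(V: np.ndarray, model: NMFModel, k_max: int) -> ObjectiveVector:
    """Score a fitted model on the three selection objectives."""
    if k_max < model.k:
        raise ValueError("k_max must be >= model rank")
    V = np.asarray(V, dtype=np.float64)
    denom = np.linalg.norm(V)
    recon_err = np.linalg.norm(V - model.reconstruction()) / max(denom, _EPS)
    return ObjectiveVector(
        f1_recon=float(recon_err),
        f2_density=float(1.0 - hoyer_sparsity(model.H)),
        f3_complexity=float(model.k / k_max),
    )


def pareto_front(candidates: list[ParetoCandidate]) -> list[ParetoCandidate]:
    """Mark the non-dominated candidates (minimization) and return them.

    ``a`` dominates ``b`` iff a <= b in every objective and a < b in at
    least one.  Exact pairwise O(n^2) filtering; duplicate objective
    vectors are all retained on the front.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    objs = np.stack([c.objectives.as_array() for c in candidates])
    if objs.ndim != 2:
        raise ValueError("inconsistent objective vector lengths")
    for i, c in enumerate(candidates):
        dominated = False
        for j in range(len(candidates)):
            if j == i:
                continue
            if np.all(objs[j] <= objs[i]) and np.any(objs[j] < objs[i]):
                dominated = True
                break
        c.on_front = not dominated
    return [c for c in candidates if c.on_front]


def select_solution(front: list[ParetoCandidate]) -> ParetoCandidate:
    """Pick the knee-point compromise from a Pareto front.

    Objectives are min-max normalized to [0, 1] across the front (an
    objective constant on the front contributes 0) and the member with
    the smallest Euclidean distance to the ideal point is selected.
    Ties break toward smaller rank, then smaller sparsity weight, then
    earlier candidate order.
    """
    if not front:
        raise ValueError("front is empty")
    objs = np.stack([c.objectives.as_array() for c in front])
    lo, hi = objs.min(axis=0), objs.max(axis=0)
    span = hi - lo
    normed = np.where(span > 0, (objs - lo) / np.where(span > 0, span, 1.0), 0.0)
    dist = np.sqrt((normed**2).sum(axis=1))
    order = sorted(
        range(len(front)),
        key=lambda i: (
            dist[i],
            front[i].model.k,
            front[i].model.lambda_sparsity,
            i,
        ),
    )
    for c in front:
        c.selected = False
    best = front[order[0]]
    best.selected = True
    return best


def sweep_candidates(
    V: np.ndarray,
    k_grid: tuple[int, ...],
    lambda_grid: tuple[float, ...],
    max_iter: int,
    tol: float,
    seed: int,
) -> list[ParetoCandidate]:
    """Fit one NMF per (k, lambda) pair; seeds offset as seed + 1000*index."""
    m, n = np.asarray(V).shape
    ks = sorted({min(k, min(m, n)) for k in k_grid})
    k_max = max(ks)
    cands: list[ParetoCandidate] = []
    idx = 0
    for k in ks:
        for lam in lambda_grid:
            model = nmf_factorize(
                V, k, lam, max_iter=max_iter, tol=tol, seed=seed + 1000 * idx
            )
            cands.append(ParetoCandidate(model, objective_vector(V, model, k_max)))
            idx += 1
    return cands


def clean_spectrogram(
    s_mod: Spectrogram,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[Spectrogram, ParetoCandidate, list[ParetoCandidate]]:
    """Low-rank clean reconstruction of the masked spectrogram.

    Runs the (k, lambda) candidate sweep on ``V = |S_mod|``, extracts the
    Pareto front, selects the compromise model, and rebuilds the complex
    spectrogram as ``(W H) * exp(i * phase(S_mod))``.

    Returns (clean spectrogram, selected candidate, all candidates).
    """
    if not k_grid:
        raise ValueError("k_grid must be nonempty")
    V = np.abs(s_mod.values)
    if not V.any():
        logger.warning("all-zero spectrogram: skipping NMF stage")
        cand = ParetoCandidate(
            NMFModel(
                W=np.zeros((V.shape[0], 1)),
                H=np.zeros((1, V.shape[1])),
                k=1,
                lambda_sparsity=0.0,
                n_iter_run=0,
                converged=True,
            ),
            ObjectiveVector(0.0, 0.0, 1.0),
            on_front=True,
            selected=True,
        )
        return s_mod.with_values(s_mod.values, "clean"), cand, [cand]

    cands = sweep_candidates(V, tuple(k_grid), tuple(lambda_grid), max_iter, tol, seed)
    front = pareto_front(cands)
    best = select_solution(front)
    recon = best.model.reconstruction()
    phase = np.exp(1j * np.angle(s_mod.values))
    return s_mod.with_values(recon * phase, "clean"), best, cands
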