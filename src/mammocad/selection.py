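"""Wrapper feature selection by flower pollination with regula-falsi
threshold refinement (FPcRF).

The flower pollination algorithm (FPA) maintains ``n`` continuous pollen
positions in the unit hypercube ``[0, 1]^d``, one coordinate per feature.
Each iteration every pollen moves either by *global pollination* — a
Lévy-flight step relative to the global best position B,

    y' = y + theta * L(lambda) * (y - B),

— or, with probability ``1 - p``, by *local pollination*, a uniform mix of
two other population members:

    y' = y + mu * (y_z - y_k),   mu ~ Uniform(0, 1).

Positions are clipped to [0, 1] and mapped to feature subsets by
thresholding at ``tau0`` (coordinates >= tau0 are selected; an all-zero
mask falls back to the single largest coordinate). The wrapper fitness is
the stratified k-fold cross-validated misclassification rate of a
1-nearest-neighbor classifier (the "fine KNN" preset) on the selected
columns; moves are accepted greedily, so the best-so-far fitness trace is
non-increasing. After the last iteration the binarization threshold itself
is refined: the fitness-difference function of the threshold is rooted by
the regula-falsi (false position) iteration over [min(B), max(B)], with a
grid-argmin fallback that guarantees the refinement never degrades fitness.

Lévy steps use the Mantegna algorithm, which reproduces the heavy
``s^-(1+lambda)`` tail of the Lévy-stable law without sampling the
(non-normalizable) density directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix

__all__ = [
    "FPcRFConfig",
    "SelectionResult",
    "BracketError",
    "levy_step",
    "global_pollination",
    "local_pollination",
    "binarize",
    "knn_cv_error",
    "fitness",
    "regula_falsi",
    "refine_threshold",
    "fpcrf_select",
]


class BracketError(ValueError):
    """Raised when a root bracket has no sign change."""


@dataclass(frozen=True)
class FPcRFConfig:
    """Tunable parameters of the selector.

    Defaults follow standard FPA practice: 20 pollens, 50 iterations,
    switch probability p = 0.8 (global pollination dominant), scaling
    factor theta = 0.01, Lévy exponent lambda = 1.5.
    """

    n_pollens: int = 20
    max_iter: int = 50
    p: float = 0.8
    theta: float = 0.01
    levy_lambda: float = 1.5
    tau0: float = 0.5
    folds: int = 5
    seed: int = 0
    rf_tol: float = 1e-4
    rf_max_iter: int = 50
    scan_points: int = 11
    canonical_fpa: bool = False  # use (B - y) orientation in the global step

    def __post_init__(self) -> None:
        if self.n_pollens < 2:
            raise ValueError("population size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("switch probability p must be in [0, 1]")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not 1.0 < self.levy_lambda < 3.0:
            raise ValueError("Lévy exponent must be in (1, 3)")
        if not 0.0 < self.tau0 < 1.0:
            raise ValueError("tau0 must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class SelectionResult:
    """Everything a run produced, sufficient to reproduce and audit it."""

    mask: np.ndarray  # boolean, length d
    selected_indices: np.ndarray
    threshold: float  # final binarization threshold Vn
    fitness_trace: np.ndarray  # best-so-far fitness per iteration (non-increasing)
    final_fitness: float
    baseline_fitness: float  # fitness of binarize(B, tau0) before refinement
    bracket: tuple[float, float]
    rf_iterates: list[float]
    best_position: np.ndarray
    config: FPcRFConfig

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "selected_indices": [int(i) for i in self.selected_indices],
            "threshold": self.threshold,
            "final_fitness": self.final_fitness,
            "baseline_fitness": self.baseline_fitness,
            "bracket": list(self.bracket),
            "rf_iterates": self.rf_iterates,
            "fitness_trace": [float(f) for f in self.fitness_trace],
            "config": asdict(self.config),
        }


def levy_step(
    lam: float, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Heavy-tailed step sizes with tail index ``lam`` (Mantegna algorithm).

    Draws s = u / |v|^(1/lam) with u ~ N(0, sigma_u^2), v ~ N(0, 1) and

        sigma_u = [Gamma(1+lam) sin(pi lam / 2) /
                   (Gamma((1+lam)/2) lam 2^((lam-1)/2))]^(1/lam),

    which gives P(|s| > x) ~ x^-lam for large x.
    """
    if not 1.0 < lam < 3.0:
        raise ValueError(f"Lévy exponent must be in (1, 3), got {lam}")
    if count == 0:
        return np.empty(0)
    sigma_u = (
        math.gamma(1.0 + lam)
        * math.sin(math.pi * lam / 2.0)
        / (math.gamma((1.0 + lam) / 2.0) * lam * 2.0 ** ((lam - 1.0) / 2.0))
    ) ** (1.0 / lam)
    u = rng.normal(0.0, sigma_u, size=count)
    v = rng.normal(0.0, 1.0, size=count)
    return u / np.abs(v) ** (1.0 / lam)


def global_pollination(
    y: np.ndarray,
    best: np.ndarray,
    theta: float,
    lam: float,
    rng: np.random.Generator,
    canonical: bool = False,
) -> np.ndarray:
    """Lévy-flight move relative to the global best, clipped to [0, 1].

    The default orientation is ``y + theta*L*(y - B)``; ``canonical=True``
    flips the displacement to the textbook ``(B - y)``.
    """
    y = np.asarray(y, dtype=np.float64)
    best = np.asarray(best, dtype=np.float64)
    if y.shape != best.shape:
        raise ValueError("position and best must have the same length")
    L = levy_step(lam, y.size, rng)
    diff = (best - y) if canonical else (y - best)
    return np.clip(y + theta * L * diff, 0.0, 1.0)


def local_pollination(
    y: np.ndarray,
    y_z: np.ndarray,
    y_k: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform mixing move ``y + mu*(y_z - y_k)``, mu ~ U(0,1), clipped."""
    y = np.asarray(y, dtype=np.float64)
    if not (y.shape == np.shape(y_z) == np.shape(y_k)):
        raise ValueError("all three positions must have the same length")
    mu = rng.uniform()
    return np.clip(y + mu * (np.asarray(y_z) - np.asarray(y_k)), 0.0, 1.0)


def binarize(position: np.ndarray, tau: float) -> np.ndarray:
    """Threshold a continuous position into a feature mask.

    Coordinates >= tau are selected. If none qualify, the single largest
    coordinate (lowest index on ties) is forced on so the mask is never
    empty.
    """
    position = np.asarray(position, dtype=np.float64)
    mask = position >= tau
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(position))] = True
    return mask


def _fold_assignment(codes: np.ndarray, folds: int, seed: int) -> np.ndarray:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_id = np.empty(codes.size, dtype=np.int64)
    for f, (_, test) in enumerate(skf.split(np.zeros((codes.size, 1)), codes)):
        fold_id[test] = f
    return fold_id


def knn_cv_error(
    X: np.ndarray, y: np.ndarray, folds: int = 5, seed: int = 0
) -> float:
    """Leave-fold-out 1-NN (Euclidean) misclassification rate.

    Stratified fold assignment is seeded, so the result is deterministic.
    Each sample is predicted by its nearest neighbor outside its own fold
    (first index wins distance ties, matching the usual argmin rule).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, codes = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes for the wrapper fitness")
    fold = _fold_assignment(codes, folds, seed)
    sq = (X * X).sum(axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(D, 0.0, out=D)
    D[fold[:, None] == fold[None, :]] = np.inf
    nn = np.argmin(D, axis=1)
    return float(np.mean(codes[nn] != codes))


def fitness(mask: np.ndarray, X: FeatureMatrix, config: FPcRFConfig) -> float:
    """Wrapper fitness of a feature mask: CV error of 1-NN on the subset."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no features")
    return knn_cv_error(
        X.values[:, mask], X.labels, folds=config.folds, seed=config.seed
    )


def regula_falsi(
    f: Callable[[float], float],
    r1: float,
    r2: float,
    tol: float = 1e-10,
    max_iter: int = 100,
    return_history: bool = False,
):
    """False-position root finding on a bracketing interval.

    Iterates the secant-through-endpoints update

        V = (r1 f(r2) - r2 f(r1)) / (f(r2) - f(r1)),

    replacing whichever endpoint shares V's sign, until |f(V)| <= tol or
    ``max_iter`` iterations. The iterate always stays inside the original
    bracket; a linear f is solved exactly in one step. Raises
    :class:`BracketError` when f(r1) and f(r2) have the same sign.
    """
    f1, f2 = f(r1), f(r2)
    history: list[float] = []
    if f1 == 0.0:
        return (r1, history) if return_history else r1
    if f2 == 0.0:
        return (r2, history) if return_history else r2
    if f1 * f2 > 0:
        raise BracketError(
            f"no sign change on [{r1}, {r2}]: f(r1)={f1}, f(r2)={f2}"
        )
    v = r1
    for _ in range(max_iter):
        v = (r1 * f2 - r2 * f1) / (f2 - f1)
        fv = f(v)
        history.append(v)
        if abs(fv) <= tol:
            break
        if f1 * fv < 0:
            r2, f2 = v, fv
        else:
            r1, f1 = v, fv
    return (v, history) if return_history else v


def refine_threshold(
    best: np.ndarray,
    X: FeatureMatrix,
    config: FPcRFConfig,
    _fitness_of_mask: Callable[[np.ndarray], float] | None = None,
) -> tuple[float, np.ndarray, tuple[float, float], list[float]]:
    """Refine the binarization threshold of the converged best position.

    Defines g(tau) = fitness(binarize(best, tau)) - fitness at tau0 over
    the bracket [min(best), max(best)]. A coarse scan looks for a sign
    change; if one exists regula falsi localizes the root Vn, otherwise Vn
    is the scan-grid argmin. If the refined mask would be worse than the
    tau0 mask, Vn falls back to tau0 — refinement never degrades fitness.

    Returns ``(Vn, mask, (r1, r2), rf_iterates)``.
    """
    best = np.asarray(best, dtype=np.float64)
    fit = _fitness_of_mask or (lambda m: fitness(m, X, config))
    base_mask = binarize(best, config.tau0)
    base = fit(base_mask)
    r1, r2 = float(best.min()), float(best.max())
    if r2 - r1 < 1e-12:
        return config.tau0, base_mask, (r1, r2), []

    def g(tau: float) -> float:
        return fit(binarize(best, tau)) - base

    grid = np.linspace(r1, r2, config.scan_points)
    gvals = np.array([g(t) for t in grid])
    vn: float | None = None
    iterates: list[float] = []
    for i in range(len(grid) - 1):
        if gvals[i] * gvals[i + 1] < 0:
            vn, iterates = regula_falsi(
                g, float(grid[i]), float(grid[i + 1]),
                tol=config.rf_tol, max_iter=config.rf_max_iter,
                return_history=True,
            )
            break
    if vn is None:
        vn = float(grid[int(np.argmin(gvals))])
    mask = binarize(best, vn)
    if fit(mask) > base:
        vn, mask = config.tau0, base_mask
    return float(vn), mask, (r1, r2), iterates


def _mask_rank(fit_val: float, mask: np.ndarray) -> tuple:
    # Tie-break between equal-fitness masks: fewer features, then
    # lexicographically smaller index set.
    idx = tuple(np.flatnonzero(mask))
    return (fit_val, len(idx), idx)


def fpcrf_select(X: FeatureMatrix, config: FPcRFConfig | None = None) -> SelectionResult:
    """Run the full FPcRF selector on a feature matrix.

    Positions are initialized uniformly in [0, 1]^d from the seed; the
    algorithm always runs all ``max_iter`` iterations (no early stop), with
    greedy per-pollen acceptance and an elitist global best, then finishes
    with the regula-falsi threshold refinement. Identical config and seed
    give an identical result.
    """
    if config is None:
        config = FPcRFConfig()
    d = X.n_features
    if d < 2:
        raise ValueError("need at least 2 features to select from")
    rng = np.random.default_rng(config.seed)

    cache: dict[bytes, float] = {}

    def fit_mask(mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        val = cache.get(key)
        if val is None:
            val = fitness(mask, X, config)
            if not np.isfinite(val):
                raise ValueError("non-finite fitness encountered")
            cache[key] = val
        return val

    pos = rng.uniform(size=(config.n_pollens, d))
    fits = np.array([fit_mask(binarize(pos[i], config.tau0)) for i in range(config.n_pollens)])

    best_i = int(np.argmin(fits))
    best_pos = pos[best_i].copy()
    best_rank = _mask_rank(fits[best_i], binarize(best_pos, config.tau0))
    for i in range(config.n_pollens):
        rank = _mask_rank(fits[i], binarize(pos[i], config.tau0))
        if rank < best_rank:
            best_rank, best_pos = rank, pos[i].copy()

    trace = np.empty(config.max_iter)
    for j in range(config.max_iter):
        for i in range(config.n_pollens):
            if rng.random() < config.p:
                cand = global_pollination(
                    pos[i], best_pos, config.theta, config.levy_lambda,
                    rng, canonical=config.canonical_fpa,
                )
            else:
                others = np.delete(np.arange(config.n_pollens), i)
                z, k = rng.choice(others, size=2, replace=False)
                cand = local_pollination(pos[i], pos[z], pos[k], rng)
            f_new = fit_mask(binarize(cand, config.tau0))
            if f_new < fits[i]:
                pos[i], fits[i] = cand, f_new
                rank = _mask_rank(f_new, binarize(cand, config.tau0))
                if rank < best_rank:
                    best_rank, best_pos = rank, cand.copy()
        trace[j] = best_rank[0]

    vn, mask, bracket, iterates = refine_threshold(
        best_pos, X, config, _fitness_of_mask=fit_mask
    )
    return SelectionResult(
        mask=mask,
        selected_indices=np.flatnonzero(mask),
        threshold=vn,
        fitness_trace=trace,
        final_fitness=fit_mask(mask),
        baseline_fitness=fit_mask(binarize(best_pos, config.tau0)),
        bracket=bracket,
        rf_iterates=iterates,
        best_position=best_pos,
        config=config,
    )
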