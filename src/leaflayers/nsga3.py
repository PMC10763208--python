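"""Reference-point NSGA-III with the leaf-specific encoding and fitness.

The optimizer is a standard elitist (mu + lambda) NSGA-III: simulated binary
crossover and polynomial mutation generate offspring, the combined population
is partitioned by fast non-dominated sorting, objectives are adaptively
normalized (ideal point + intercepts from achievement-scalarizing extreme
points), and the partially-accepted last front is filled by niche-preserving
selection against a Das–Dennis reference-point set.  All randomness flows
from one :class:`numpy.random.Generator`, so a run is bit-reproducible from
its seed.

With a single objective (the default for spectrum fitting) the machinery
degenerates gracefully: every non-dominated "front" is a value class and
selection is elitist rank truncation.

The leaf-specific pieces are :func:`encode_partition`, mapping the unit
hypercube onto the admissible two-layer partitions

    N1 = N * (2 + 0.01 * x1)      N2 = N * (0.1 + 2.9 * x2)
    Cab12 = x3                    Cm12 = x4        (Cw12 fixed at 1)

and :func:`fitness_y`, the summed relative deviation between modelled and
measured reflectance over the 601 bands.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .forward import LayerPartition

__all__ = [
    "GAConfig",
    "ReferencePointSet",
    "NormalizationState",
    "NSGA3Result",
    "fast_nondominated_sort",
    "generate_reference_points",
    "adaptive_normalize",
    "niche_select",
    "nsga3_run",
    "encode_partition",
    "fitness_y",
    "fitness_y_batch",
]

logger = logging.getLogger(__name__)

_PENALTY = 1e18  # stand-in for +inf so normalization stays finite


@dataclass(frozen=True)
class GAConfig:
    """Hyper-parameters of one optimizer run (canonical NSGA-III defaults)."""

    pop_size: int = 100
    generations: int = 200
    n_obj: int = 1
    eta_crossover: float = 30.0
    eta_mutation: float = 20.0
    mutation_prob: float | None = None  # None -> 1/d
    divisions: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size <= 0 or self.pop_size % 2:
            raise ValueError("pop_size must be positive and even")
        if self.generations < 0:
            raise ValueError("generations must be nonnegative")
        if self.n_obj < 1:
            raise ValueError("n_obj must be >= 1")


@dataclass(frozen=True)
class ReferencePointSet:
    """Das–Dennis simplex-lattice reference points (each sums to 1)."""

    points: np.ndarray
    divisions: int


@dataclass(frozen=True)
class NormalizationState:
    ideal: np.ndarray
    intercepts: np.ndarray


@dataclass(frozen=True)
class NSGA3Result:
    """Final population plus the best-by-scalar individual and its trace."""

    X: np.ndarray
    F: np.ndarray
    best_x: np.ndarray
    best_f: np.ndarray
    best_scalar: float
    trace: np.ndarray  # per-generation best total objective
    n_evaluations: int


def fast_nondominated_sort(objectives) -> list[list[int]]:
    """Partition indices into Pareto fronts (minimization).

    Returns a list of fronts, each a list of indices; front 0 is the
    non-dominated set of the whole input.
    """
    F = np.atleast_2d(np.asarray(objectives, dtype=float))
    if F.size == 0:
        raise ValueError("cannot sort an empty population")
    le = (F[:, None, :] <= F[None, :, :]).all(axis=-1)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=-1)
    dominates = le & lt  # [i, j] True iff i dominates j
    n_dominators = dominates.sum(axis=0)
    fronts: list[list[int]] = []
    remaining = np.ones(len(F), dtype=bool)
    while remaining.any():
        current = remaining & (n_dominators == 0)
        if not current.any():  # numerical safety; cannot happen for finite F
            current = remaining.copy()
        fronts.append(np.flatnonzero(current).tolist())
        n_dominators = n_dominators - dominates[current].sum(axis=0)
        remaining &= ~current
    return fronts


def _simplex_lattice(M: int, p: int) -> list[tuple[int, ...]]:
    if M == 1:
        return [(p,)]
    out = []
    for i in range(p + 1):
        for rest in _simplex_lattice(M - 1, p - i):
            out.append((i, *rest))
    return out


def generate_reference_points(M: int, p: int) -> ReferencePointSet:
    """All C(M+p-1, p) simplex-lattice points with denominator ``p``."""
    if M < 1 or p < 1:
        raise ValueError("M and p must be >= 1")
    pts = np.asarray(_simplex_lattice(M, p), dtype=float) / p
    return ReferencePointSet(points=pts, divisions=p)


def adaptive_normalize(
    objectives, state: NormalizationState | None = None
) -> tuple[np.ndarray, NormalizationState]:
    """Translate by the ideal point and scale by hyperplane intercepts.

    Extreme points per axis are picked by the achievement scalarizing
    function; if the intercept system is singular or yields nonpositive
    intercepts, the per-axis maxima are used instead (and unity when even
    those degenerate).
    """
    F = np.atleast_2d(np.asarray(objectives, dtype=float))
    M = F.shape[1]
    ideal = F.min(axis=0)
    if state is not None:
        ideal = np.minimum(ideal, state.ideal)
    Fp = F - ideal

    span = Fp.max(axis=0)
    if np.all(span <= 0):
        warnings.warn("all individuals identical; normalization falls back to unit intercepts")
        intercepts = np.ones(M)
    else:
        weights = np.full((M, M), 1e-6) + np.eye(M)
        asf = (Fp[:, None, :] / weights[None, :, :]).max(axis=-1)  # (n, M)
        extremes = Fp[asf.argmin(axis=0)]  # (M, M)
        intercepts = None
        if M > 1:
            try:
                u = np.linalg.solve(extremes, np.ones(M))
                cand = 1.0 / u
                if np.all(np.isfinite(cand)) and np.all(cand > 1e-12):
                    intercepts = cand
            except np.linalg.LinAlgError:
                intercepts = None
        if intercepts is None:
            intercepts = np.where(span > 1e-12, span, 1.0)
    Fn = Fp / intercepts
    return Fn, NormalizationState(ideal=ideal, intercepts=intercepts)


def _associate(Fn: np.ndarray, refs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest reference line per individual and the perpendicular distance."""
    norms = np.linalg.norm(refs, axis=1)
    dirs = refs / norms[:, None]
    proj = Fn @ dirs.T  # (n, R) scalar projections
    d2 = (Fn**2).sum(axis=1)[:, None] - proj**2
    dist = np.sqrt(np.maximum(d2, 0.0))
    nearest = dist.argmin(axis=1)
    return nearest, dist[np.arange(len(Fn)), nearest]


def niche_select(
    Fn: np.ndarray,
    accepted: Sequence[int],
    last_front: Sequence[int],
    K: int,
    refs: ReferencePointSet,
    rng: np.random.Generator,
) -> list[int]:
    """Choose ``K`` members of the last front by niche preservation.

    ``Fn`` holds normalized objectives of the combined population;
    ``accepted`` are the indices already carried over (fronts before the
    last); niche counts are seeded from them.  Within a niche the member
    closest to the reference line is taken; ``rng`` breaks ties between
    equally crowded niches.
    """
    last_front = list(last_front)
    if K > len(last_front):
        raise ValueError("K cannot exceed the size of the last front")
    if K == len(last_front):
        return last_front
    nearest, dist = _associate(Fn, refs.points)
    counts = np.zeros(len(refs.points), dtype=int)
    for i in accepted:
        counts[nearest[i]] += 1
    candidates: dict[int, list[int]] = {}
    for i in last_front:
        candidates.setdefault(nearest[i], []).append(i)
    active = set(candidates)
    chosen: list[int] = []
    while len(chosen) < K:
        act = sorted(active)
        cmin = min(counts[j] for j in act)
        minimal = [j for j in act if counts[j] == cmin]
        j = minimal[rng.integers(len(minimal))] if len(minimal) > 1 else minimal[0]
        pool = candidates[j]
        # closest member of the niche; index breaks exact distance ties
        pick = min(pool, key=lambda i: (dist[i], i))
        pool.remove(pick)
        chosen.append(pick)
        counts[j] += 1
        if not pool:
            active.discard(j)
    return chosen


def _sbx(rng: np.random.Generator, X: np.ndarray, eta: float) -> np.ndarray:
    """Simulated binary crossover on consecutive pairs, bounds [0, 1]."""
    P1, P2 = X[0::2], X[1::2]
    u = rng.random(P1.shape)
    beta = np.where(
        u <= 0.5,
        (2.0 * u) ** (1.0 / (eta + 1.0)),
        (0.5 / (1.0 - u)) ** (1.0 / (eta + 1.0)),
    )
    cross = rng.random(P1.shape) < 0.5
    beta = np.where(cross, beta, 1.0)
    C1 = 0.5 * ((1.0 + beta) * P1 + (1.0 - beta) * P2)
    C2 = 0.5 * ((1.0 - beta) * P1 + (1.0 + beta) * P2)
    out = np.empty_like(X)
    out[0::2], out[1::2] = C1, C2
    return np.clip(out, 0.0, 1.0)


def _polynomial_mutation(
    rng: np.random.Generator, X: np.ndarray, eta: float, prob: float
) -> np.ndarray:
    u = rng.random(X.shape)
    do = rng.random(X.shape) < prob
    d1, d2 = X, 1.0 - X  # distances to the [0, 1] bounds
    delta = np.where(
        u < 0.5,
        (2.0 * u + (1.0 - 2.0 * u) * (1.0 - d1) ** (eta + 1.0)) ** (1.0 / (eta + 1.0)) - 1.0,
        1.0 - (2.0 * (1.0 - u) + 2.0 * (u - 0.5) * (1.0 - d2) ** (eta + 1.0)) ** (1.0 / (eta + 1.0)),
    )
    return np.clip(np.where(do, X + delta, X), 0.0, 1.0)


def _evaluate(problem: Callable, X: np.ndarray, M: int) -> np.ndarray:
    F = np.asarray(problem(X), dtype=float)
    if M == 1 and F.ndim == 1:
        F = F[:, None]
    F = np.atleast_2d(F)
    if F.shape != (X.shape[0], M):
        raise ValueError(f"problem returned shape {F.shape}, expected ({X.shape[0]}, {M})")
    bad = ~np.isfinite(F)
    if bad.any():
        logger.warning("penalized %d non-finite objective values", int(bad.sum()))
        F = np.where(bad, _PENALTY, F)
    return F


def _environmental_selection(
    F: np.ndarray,
    N: int,
    refs: ReferencePointSet,
    rng: np.random.Generator,
    state: NormalizationState | None,
) -> tuple[np.ndarray, NormalizationState]:
    fronts = fast_nondominated_sort(F)
    accepted: list[int] = []
    for fi, front in enumerate(fronts):
        if len(accepted) + len(front) <= N:
            accepted.extend(front)
            if len(accepted) == N:
                return np.asarray(accepted), state
        else:
            last = front
            K = N - len(accepted)
            pool = accepted + last
            Fn, state = adaptive_normalize(F[pool], state)
            # remap to combined indices
            Fn_full = np.zeros((len(F), F.shape[1]))
            Fn_full[pool] = Fn
            chosen = niche_select(Fn_full, accepted, last, K, refs, rng)
            accepted.extend(chosen)
            return np.asarray(accepted), state
    return np.asarray(accepted), state


def nsga3_run(
    problem: Callable[[np.ndarray], np.ndarray],
    d: int,
    config: GAConfig,
) -> NSGA3Result:
    """Run NSGA-III on ``problem`` over the box [0, 1]^d.

    ``problem`` is called with a ``(P, d)`` matrix and must return a
    ``(P, n_obj)`` (or ``(P,)`` when ``n_obj == 1``) array of objectives to
    minimize.  Non-finite values are penalized.  The scalar used for "best"
    and the trace is the sum of objectives (equal to the single objective in
    scalar mode).
    """
    if d < 1:
        raise ValueError("dimension must be >= 1")
    rng = np.random.default_rng(config.seed)
    M = config.n_obj
    refs = generate_reference_points(M, config.divisions if M > 1 else 1)
    p_mut = config.mutation_prob if config.mutation_prob is not None else 1.0 / d

    N = config.pop_size
    X = rng.random((N, d))
    F = _evaluate(problem, X, M)
    n_eval = N
    state: NormalizationState | None = None

    def best_of(Xp, Fp):
        scal = Fp.sum(axis=1)
        i = int(scal.argmin())
        return Xp[i].copy(), Fp[i].copy(), float(scal[i])

    trace = [best_of(X, F)[2]]
    for _ in range(config.generations):
        parents = X[rng.permutation(N)]
        children = _sbx(rng, parents, config.eta_crossover)
        children = _polynomial_mutation(rng, children, config.eta_mutation, p_mut)
        Fc = _evaluate(problem, children, M)
        n_eval += N
        R = np.vstack([X, children])
        FR = np.vstack([F, Fc])
        keep, state = _environmental_selection(FR, N, refs, rng, state)
        X, F = R[keep], FR[keep]
        trace.append(best_of(X, F)[2])

    best_x, best_f, best_scalar = best_of(X, F)
    return NSGA3Result(
        X=X,
        F=F,
        best_x=best_x,
        best_f=best_f,
        best_scalar=best_scalar,
        trace=np.asarray(trace),
        n_evaluations=n_eval,
    )


def encode_partition(x, N: float = 1.0) -> LayerPartition:
    """Map a point of the unit hypercube onto an admissible layer partition."""
    x = np.asarray(x, dtype=float)
    if x.shape != (4,) or np.any(x < 0) or np.any(x > 1):
        raise ValueError("x must be a 4-vector in [0, 1]^4")
    return LayerPartition(
        N1=N * (2.0 + 0.01 * x[0]),
        N2=N * (0.1 + 2.9 * x[1]),
        cab12=float(x[2]),
        cm12=float(x[3]),
        cw12=1.0,
    )


#: floor applied to measured reflectance in the relative-deviation fitness
FITNESS_FLOOR = 1e-6


def fitness_y_batch(R_mod: np.ndarray, R_meas: np.ndarray) -> np.ndarray:
    """Summed relative deviation for a batch of modelled spectra.

    ``R_mod`` has shape ``(P, n_bands)``, ``R_meas`` shape ``(n_bands,)``;
    returns ``(P,)``.  Bands where the measured reflectance is <= 0 are
    floored at :data:`FITNESS_FLOOR` (with a warning).
    """
    R_mod = np.atleast_2d(np.asarray(R_mod, dtype=float))
    R_meas = np.asarray(R_meas, dtype=float)
    if np.any(R_meas <= 0):
        warnings.warn(
            "measured reflectance <= 0 at some bands; flooring the fitness denominator"
        )
        R_meas = np.maximum(R_meas, FITNESS_FLOOR)
    return np.abs(R_mod - R_meas[None, :]).__truediv__(R_meas[None, :]).sum(axis=1)


def fitness_y(R_mod, R_meas) -> float:
    """Scalar fitness: sum over bands of |R_mod - R_meas| / R_meas."""
    return float(fitness_y_batch(np.atleast_2d(R_mod), R_meas)[0])
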