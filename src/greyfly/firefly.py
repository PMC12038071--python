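"""Box-constrained firefly-algorithm minimizer.

A population of candidate solutions ("fireflies") is scored by the objective
(lower = brighter). Each sweep, every firefly moves toward every brighter one
with attractiveness decaying in the squared Euclidean distance,

    beta(r) = beta_min + (beta0 - beta_min) * exp(-absorption * r**2),

plus a uniform random-walk perturbation ``step_factor * (U - 0.5)`` per
dimension; positions are clamped to the box after every move. The brightest
firefly, having no one to follow, performs a pure random-walk step. The
best-ever position is tracked separately (elitism), so the reported optimum
is monotone non-increasing across iterations.

Reproducibility contract: all randomness comes from one seeded NumPy
generator. Per iteration it is consumed as a single (N, N, d) block of
uniforms indexed by (moving firefly i, target firefly j, dimension) followed
by an (N, d) block for random walks; entries for pairs that do not move are
drawn and discarded. Identical seed + config + objective therefore gives a
bit-identical trajectory.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FireflyConfig",
    "OptimizationResult",
    "attractiveness",
    "pairwise_distance",
    "move_firefly",
    "optimize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FireflyConfig:
    """Firefly-swarm settings; defaults follow common practice for 2-D tuning
    problems (population 50, 1000 sweeps, absorption 1, step 0.01, beta0 1,
    beta_min 0.2)."""

    bounds: tuple[tuple[float, float], ...]
    population_size: int = 50
    max_iterations: int = 1000
    absorption: float = 1.0
    step_factor: float = 0.01
    beta0: float = 1.0
    beta_min: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "bounds", tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        )
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.absorption < 0 or self.step_factor < 0:
            raise ValueError("absorption and step_factor must be >= 0")
        if self.beta_min > self.beta0:
            raise ValueError("beta_min must not exceed beta0")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bound ({lo}, {hi}): need low < high")

    @property
    def dim(self) -> int:
        return len(self.bounds)


@dataclass(frozen=True)
class OptimizationResult:
    best_position: np.ndarray
    best_value: float
    trajectory: np.ndarray = field(repr=False)  # best value after each sweep
    evaluations: int = 0


def attractiveness(r: float, config: FireflyConfig) -> float:
    """Distance-decaying attraction with floor beta_min.

    Equals beta0 at r = 0, decays as exp(-absorption * r**2), and tends to
    beta_min at large distance; with beta_min = 0 this is the textbook form.
    """
    if r < 0:
        raise ValueError("distance must be >= 0")
    return config.beta_min + (config.beta0 - config.beta_min) * math.exp(
        -config.absorption * r * r
    )


def pairwise_distance(xi, xj) -> float:
    """Euclidean distance between two positions of equal dimension."""
    a = np.asarray(xi, dtype=np.float64)
    b = np.asarray(xj, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def move_firefly(xi, xj, config: FireflyConfig, draws) -> np.ndarray:
    """One attraction step of firefly i toward a brighter firefly j.

    new = xi + beta(r_ij) * (xj - xi) + step_factor * (draws - 0.5),
    clamped to the box. ``draws`` is one uniform in [0, 1) per dimension.
    """
    a = np.asarray(xi, dtype=np.float64)
    b = np.asarray(xj, dtype=np.float64)
    u = np.asarray(draws, dtype=np.float64)
    beta = attractiveness(pairwise_distance(a, b), config)
    new = a + beta * (b - a) + config.step_factor * (u - 0.5)
    lows = np.array([lo for lo, _ in config.bounds])
    highs = np.array([hi for _, hi in config.bounds])
    return np.clip(new, lows, highs)


def _safe_eval(objective, x: np.ndarray) -> float:
    val = objective(x)
    if val is None or (isinstance(val, float) and math.isnan(val)) or np.isnan(val):
        logger.warning("objective returned NaN at %s; treating as +inf", x)
        return math.inf
    return float(val)


def optimize(
    objective, config: FireflyConfig, initial_positions=None
) -> OptimizationResult:
    """Minimize ``objective`` over the configured box.

    Infeasible points should be signalled by returning ``math.inf``; NaN is
    coerced to +inf with a warning. Runs the full ``max_iterations`` sweeps
    (no early stopping) and evaluates each firefly once per sweep, so the
    evaluation count is population_size * (max_iterations + 1).

    ``initial_positions`` (optional, shape (m, d) with m <= population) warm-
    starts the swarm: the first m seeded positions are replaced after the
    stream draw, so random-stream consumption — and hence every later draw —
    is unchanged. Elitism then guarantees the result is at least as good as
    the best warm start.
    """
    rng = np.random.default_rng(config.seed)
    npop, d = config.population_size, config.dim
    lows = np.array([lo for lo, _ in config.bounds])
    highs = np.array([hi for _, hi in config.bounds])
    span = highs - lows
    gam = config.absorption
    b0, bmin = config.beta0, config.beta_min
    step = config.step_factor

    positions = lows + rng.random((npop, d)) * span
    if initial_positions is not None:
        warm = np.clip(np.atleast_2d(np.asarray(initial_positions, dtype=np.float64)),
                       lows, highs)
        if warm.shape[0] > npop or warm.shape[1] != d:
            raise ValueError(
                f"initial_positions shape {warm.shape} incompatible with "
                f"population {npop} x dim {d}"
            )
        positions[: warm.shape[0]] = warm
    brightness = np.array([_safe_eval(objective, positions[i]) for i in range(npop)])
    evaluations = npop
    best_idx = int(np.argmin(brightness))
    best_value = float(brightness[best_idx])
    best_position = positions[best_idx].copy()
    trajectory = []

    # positions as python lists of floats: the O(N^2) inner sweep dominates
    # the runtime at population 50 x 1000 sweeps, and scalar math is several
    # times faster than per-move numpy dispatch for d <= 3
    pos = [list(map(float, positions[i])) for i in range(npop)]
    lows_l, highs_l = list(map(float, lows)), list(map(float, highs))
    dims = range(d)

    for _ in range(config.max_iterations):
        snapshot = brightness.copy()
        u_pair = rng.random((npop, npop, d))
        u_walk = rng.random((npop, d))
        for i in range(npop):
            xi = pos[i]
            bi = snapshot[i]
            moved = False
            for j in range(npop):
                if not snapshot[j] < bi:
                    continue
                moved = True
                xj = pos[j]
                r2 = 0.0
                for p in dims:
                    diff = xi[p] - xj[p]
                    r2 += diff * diff
                beta = bmin + (b0 - bmin) * math.exp(-gam * r2)
                u = u_pair[i, j]
                for p in dims:
                    v = xi[p] + beta * (xj[p] - xi[p]) + step * (u[p] - 0.5)
                    if v < lows_l[p]:
                        v = lows_l[p]
                    elif v > highs_l[p]:
                        v = highs_l[p]
                    xi[p] = v
            if not moved:
                # brightest firefly: pure random walk
                u = u_walk[i]
                for p in dims:
                    v = xi[p] + step * (u[p] - 0.5)
                    if v < lows_l[p]:
                        v = lows_l[p]
                    elif v > highs_l[p]:
                        v = highs_l[p]
                    xi[p] = v
        for i in range(npop):
            brightness[i] = _safe_eval(objective, np.array(pos[i]))
        evaluations += npop
        it_best = int(np.argmin(brightness))
        if brightness[it_best] < best_value:
            best_value = float(brightness[it_best])
            best_position = np.array(pos[it_best])
        trajectory.append(best_value)

    if not math.isfinite(best_value):
        raise RuntimeError(
            "firefly optimization never found a feasible point "
            "(objective was +inf/NaN everywhere it was evaluated)"
        )
    return OptimizationResult(
        best_position=best_position,
        best_value=best_value,
        trajectory=np.array(trajectory),
        evaluations=evaluations,
    )
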