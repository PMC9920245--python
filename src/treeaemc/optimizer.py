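"""Grey wolf optimizer (GWO) with multi-strategy improvements (IGWO).

Canonical GWO steers a population toward its three best members (alpha,
beta, delta): for each wolf and each leader L, with distance-control
parameter a = 2(1 - t/tmax) decaying over iterations,

    D_L = |C_L * X_L - X|,   C_L = 2 r2
    X_L' = X_L - A_L * D_L,  A_L = 2 a r1 - a

and the new position is the mean of the three candidates, clamped to the
box.  The improved variant (IGWO) adds three strategies:

* **Henon-map initialization** — seed the population from the chaotic
  transient of the Henon recurrence so the initial wolves cover the box
  near-uniformly;
* **reverse (opposition-based) learning** — once per iteration, mirror the
  incumbent best through the box bounds, blend back toward it with a
  decaying control parameter, and keep the better of the pair;
* **firefly perturbation** — attract every wolf toward/away from the alpha
  with distance-attenuated strength plus bounded jitter, accepting only
  improving moves.

Ablation variants named after the convention (strategy subsets) are
provided, together with the four standard benchmark functions and a
multi-run ablation harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BenchmarkFunction", "StrategyConfig", "WolfPack", "RunResult",
    "sphere", "rosenbrock", "schwefel", "rastrigin", "make_benchmark",
    "BENCHMARKS", "henon_init", "gwo_step", "reverse_learning_step",
    "firefly_perturb_step", "optimize", "ablation_suite", "VARIANTS",
]


# ---------------------------------------------------------------------------
# Benchmark functions (vectorized over the last axis)

def sphere(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.sum(x * x, axis=-1)


def rosenbrock(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    a, b = x[..., :-1], x[..., 1:]
    return np.sum(100.0 * (b - a * a) ** 2 + (1.0 - a) ** 2, axis=-1)


def schwefel(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    d = x.shape[-1]
    return 418.9829 * d - np.sum(x * np.sin(np.sqrt(np.abs(x))), axis=-1)


def rastrigin(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    d = x.shape[-1]
    return 10.0 * d + np.sum(x * x - 10.0 * np.cos(2 * np.pi * x), axis=-1)


@dataclass(frozen=True)
class BenchmarkFunction:
    name: str
    dim: int
    bounds: tuple[float, float]           # same box in every dimension
    evaluate: Callable[[np.ndarray], np.ndarray]
    known_min: float
    known_argmin: np.ndarray


_BENCH_SPECS: dict[str, tuple[Callable, tuple[float, float], float, float]] = {
    # name: (fn, (lb, ub), known_min, argmin coordinate)
    "sphere": (sphere, (-5.12, 5.12), 0.0, 0.0),
    "rosenbrock": (rosenbrock, (-30.0, 30.0), 0.0, 1.0),
    "schwefel": (schwefel, (-500.0, 500.0), 0.0, 420.9687),
    "rastrigin": (rastrigin, (-5.12, 5.12), 0.0, 0.0),
}


def make_benchmark(name: str, dim: int = 30) -> BenchmarkFunction:
    fn, bounds, kmin, argc = _BENCH_SPECS[name]
    return BenchmarkFunction(name=name, dim=dim, bounds=bounds, evaluate=fn,
                             known_min=kmin,
                             known_argmin=np.full(dim, argc))


BENCHMARKS = tuple(_BENCH_SPECS)


# ---------------------------------------------------------------------------
# Strategy configuration / ablation variants

@dataclass(frozen=True)
class StrategyConfig:
    """Which improvement strategies are active, and their parameters.

    The firefly parameters are the attraction scale ``beta0``, the light
    absorption coefficient ``gamma`` (larger = attraction falls off faster
    with distance) and the jitter step factor ``theta`` in [0, 1].
    """

    henon_init: bool = True
    reverse_learning: bool = True
    firefly_perturb: bool = True
    henon_a: float = 0.6
    henon_b: float = 0.7
    firefly_beta0: float = 2.0
    firefly_gamma: float = 1.0
    firefly_theta: float = 0.6

    @classmethod
    def variant(cls, name: str) -> "StrategyConfig":
        return VARIANTS[name]


VARIANTS: dict[str, StrategyConfig] = {
    "GWO": StrategyConfig(henon_init=False, reverse_learning=False,
                          firefly_perturb=False),
    "IGWO1": StrategyConfig(firefly_perturb=False),      # no firefly
    "IGWO2": StrategyConfig(reverse_learning=False),     # no reverse learning
    "IGWO3": StrategyConfig(henon_init=False),           # no Henon init
    "IGWO": StrategyConfig(),                            # all three
}


# ---------------------------------------------------------------------------
# Henon-map population initialization

def _henon_values(count: int, a: float, b: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Chaotic-transient samples of the Henon recurrence.

    The recurrence y1 <- 1 - a*y1^2 + y2, y2 <- b*y1 is iterated in short
    orbits (16 steps, first 2 discarded) from seeded random starts; the
    transient spans roughly [-2, 2.25].  Long orbits are avoided because at
    the default (a, b) the map ultimately settles on a short cycle, which
    would collapse the population; orbits that diverge (|y1| > 10) are
    restarted from a fresh seeded point.
    """
    out: list[float] = []
    orbit_len, burn = 16, 2
    while len(out) < count:
        y1, y2 = rng.uniform(-0.5, 0.5, size=2)
        for i in range(orbit_len):
            # classic Henon update: y2 couples to the *previous* y1 — coupling
            # to the updated y1 collapses the recurrence to a 1-D quadratic
            # map with an attracting fixed point and no diversity at all
            y1, y2 = 1.0 - a * y1 * y1 + y2, b * y1
            if abs(y1) > 10.0:               # divergent orbit: restart
                y1, y2 = rng.uniform(-0.5, 0.5, size=2)
                continue
            if i >= burn:
                out.append(y1)
    return np.asarray(out[:count])


def henon_init(
    n: int,
    dim: int,
    bounds: tuple[np.ndarray, np.ndarray],
    a: float = 0.6,
    b: float = 0.7,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Initial (n, dim) positions from normalized Henon-transient values.

    Values are mapped affinely from [-2, 2.25] to [0, 1], clamped, then
    scaled into the per-dimension box ``lb + z * (ub - lb)``.
    """
    if n * dim < 1:
        raise ValueError("population must contain at least one coordinate")
    if rng is None:
        rng = np.random.default_rng(seed)
    lb, ub = bounds
    z = np.clip((_henon_values(n * dim, a, b, rng) + 2.0) / 4.25, 0.0, 1.0)
    return lb + z.reshape(n, dim) * (ub - lb)


# ---------------------------------------------------------------------------
# Pack state and update steps

@dataclass
class WolfPack:
    """Population state: positions, fitness, iteration counters and box."""

    positions: np.ndarray                 # (n, dim)
    fitness: np.ndarray                   # (n,)
    lb: np.ndarray
    ub: np.ndarray
    t: int = 0
    tmax: int = 500

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def leaders(self) -> np.ndarray:
        """Indices of alpha, beta, delta (ties broken by lowest index)."""
        return np.argsort(self.fitness, kind="stable")[:3]

    @property
    def best_index(self) -> int:
        return int(self.leaders[0])


def _evaluate(objective: Callable, x: np.ndarray) -> np.ndarray:
    """Batch-evaluate; non-finite objective values are treated as +inf."""
    x = np.atleast_2d(x)
    try:
        vals = np.asarray(objective(x), dtype=float)
        if vals.shape != (x.shape[0],):
            raise TypeError
    except Exception:
        vals = np.array([float(objective(row)) for row in x])
    return np.where(np.isfinite(vals), vals, np.inf)


def gwo_step(pack: WolfPack, objective: Callable,
             rng: np.random.Generator) -> None:
    """One canonical encircling/hunting update of the whole pack (in place)."""
    a = 2.0 * (1.0 - pack.t / pack.tmax)
    x = pack.positions
    n, dim = x.shape
    lead = x[pack.leaders]                        # (3, dim)
    r1 = rng.random((3, n, dim))
    r2 = rng.random((3, n, dim))
    coef_a = 2.0 * a * r1 - a
    coef_c = 2.0 * r2
    dist = np.abs(coef_c * lead[:, None, :] - x[None, :, :])
    cand = lead[:, None, :] - coef_a * dist
    new_x = np.clip(cand.mean(axis=0), pack.lb, pack.ub)
    pack.positions = new_x
    pack.fitness = _evaluate(objective, new_x)


def reverse_learning_step(pack: WolfPack, objective: Callable,
                          rng: np.random.Generator) -> None:
    """Elite opposition: mirror the incumbent best and keep the better point.

    The opposition point is ``X_op = ub + r * (lb - X_best)`` with r uniform
    per dimension; the candidate blends back toward the best with control
    parameter ``c1 = ((tmax - t)/tmax)^t`` (1 at t=0, decaying after).  The
    incumbent is replaced only on strict improvement, so ties keep it.
    """
    b = pack.best_index
    x_best = pack.positions[b]
    r = rng.random(x_best.size)
    x_op = pack.ub + r * (pack.lb - x_best)
    frac = (pack.tmax - pack.t) / pack.tmax
    c1 = frac**pack.t
    cand = np.clip(x_op + c1 * (x_best - x_op), pack.lb, pack.ub)
    f_cand = _evaluate(objective, cand[None, :])[0]
    if f_cand < pack.fitness[b]:
        pack.positions[b] = cand
        pack.fitness[b] = f_cand


def firefly_perturb_step(pack: WolfPack, objective: Callable,
                         rng: np.random.Generator,
                         beta0: float = 2.0, gamma: float = 1.0,
                         theta: float = 0.6) -> None:
    """Distance-attenuated perturbation relative to the alpha, plus jitter.

    Each wolf moves by ``sigma * (X - X_p) + theta_t * (ub - lb) * (rand - 1/2)``
    with ``sigma = beta0 * exp(-gamma * r^2)`` and r its Euclidean distance to
    the prey (alpha) position *normalized by the box diagonal*, so the
    attenuation and the jitter amplitude are invariant to the scale of the
    search box.  The jitter step decays linearly over the run,
    ``theta_t = theta * (1 - t/tmax)``, so late iterations refine rather than
    jump (on a unit box the jitter magnitude never exceeds theta/2 per
    dimension).  Moves are accepted greedily, so the update can only improve
    each wolf.
    """
    x = pack.positions
    x_p = x[pack.best_index].copy()
    span = pack.ub - pack.lb
    diag2 = float(np.sum(span**2))
    r2 = np.sum((x - x_p) ** 2, axis=1) / diag2
    sigma = beta0 * np.exp(-gamma * r2)
    theta_t = theta * (1.0 - pack.t / pack.tmax)
    y = x + sigma[:, None] * (x - x_p) + theta_t * span * (rng.random(x.shape) - 0.5)
    y = np.clip(y, pack.lb, pack.ub)
    f_y = _evaluate(objective, y)
    improve = f_y < pack.fitness
    pack.positions[improve] = y[improve]
    pack.fitness[improve] = f_y[improve]


# ---------------------------------------------------------------------------
# Full optimization run

@dataclass
class RunResult:
    best_x: np.ndarray
    best_f: float
    history: np.ndarray                   # best-so-far per iteration (tmax+1)
    converged_at: int                     # first iter within tol of final best
    seed: int | None


def _converged_iteration(history: np.ndarray, tol: float) -> int:
    within = history - history[-1] <= tol
    return int(np.argmax(within))


def optimize(
    objective: Callable,
    bounds: tuple[Sequence[float], Sequence[float]],
    strategies: StrategyConfig = StrategyConfig(),
    n: int = 30,
    tmax: int = 500,
    seed: int | None = None,
    tol: float = 1e-6,
    dim: int | None = None,
) -> RunResult:
    """Minimize ``objective`` over a box with (I)GWO.

    ``bounds`` is (lb, ub), scalars or per-dimension arrays (scalars require
    ``dim``).  Per iteration: GWO step, then reverse learning and firefly
    perturbation if enabled.  A best-so-far archive guarantees the recorded
    history is non-increasing (elitism: the best solution is never lost).
    ``converged_at`` is the first history index whose value is within
    ``tol`` of the final best.
    """
    lb = np.atleast_1d(np.asarray(bounds[0], dtype=float))
    ub = np.atleast_1d(np.asarray(bounds[1], dtype=float))
    if lb.size == 1 and dim is not None:
        lb = np.full(dim, lb[0])
        ub = np.full(dim, ub[0])
    if lb.shape != ub.shape or np.any(lb >= ub):
        raise ValueError("bounds must satisfy lb < ub elementwise")
    if n < 4:
        raise ValueError("population must have n >= 4 (alpha, beta, delta + omega)")
    d = lb.size
    rng = np.random.default_rng(seed)

    if strategies.henon_init:
        x0 = henon_init(n, d, (lb, ub), a=strategies.henon_a,
                        b=strategies.henon_b, rng=rng)
    else:
        x0 = lb + rng.random((n, d)) * (ub - lb)
    pack = WolfPack(positions=x0, fitness=_evaluate(objective, x0),
                    lb=lb, ub=ub, t=0, tmax=max(tmax, 1))

    b = pack.best_index
    best_x = pack.positions[b].copy()
    best_f = float(pack.fitness[b])
    history = [best_f]
    for t in range(tmax):
        pack.t = t
        gwo_step(pack, objective, rng)
        if strategies.reverse_learning:
            reverse_learning_step(pack, objective, rng)
        if strategies.firefly_perturb:
            firefly_perturb_step(pack, objective, rng,
                                 beta0=strategies.firefly_beta0,
                                 gamma=strategies.firefly_gamma,
                                 theta=strategies.firefly_theta)
        b = pack.best_index
        if pack.fitness[b] < best_f:
            best_f = float(pack.fitness[b])
            best_x = pack.positions[b].copy()
        history.append(best_f)
    hist = np.asarray(history)
    return RunResult(best_x=best_x, best_f=best_f, history=hist,
                     converged_at=_converged_iteration(hist, tol), seed=seed)


def ablation_suite(
    functions: Iterable[str | BenchmarkFunction],
    variants: Iterable[str] = tuple(VARIANTS),
    runs: int = 50,
    n: int = 30,
    tmax: int = 500,
    seed0: int = 0,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Repeat-run comparison of strategy variants on benchmark functions.

    Runs each (function, variant) pair with seeds ``seed0 .. seed0+runs-1``
    and tabulates the mean and standard deviation of the final best fitness
    and of the convergence iteration.  Deterministic for fixed ``seed0``.
    """
    rows = []
    for fn in functions:
        bench = make_benchmark(fn) if isinstance(fn, str) else fn
        lo, hi = bench.bounds
        for vname in variants:
            strat = VARIANTS[vname] if isinstance(vname, str) else vname
            finals, convs = [], []
            for i in range(runs):
                res = optimize(bench.evaluate, (lo, hi), strategies=strat,
                               n=n, tmax=tmax, seed=seed0 + i, tol=tol,
                               dim=bench.dim)
                finals.append(res.best_f)
                convs.append(res.converged_at)
            rows.append({
                "function": bench.name, "variant": vname,
                "mean_best_f": float(np.mean(finals)),
                "sd_best_f": float(np.std(finals, ddof=1)) if runs > 1 else 0.0,
                "mean_converged_at": float(np.mean(convs)),
                "sd_converged_at": float(np.std(convs, ddof=1)) if runs > 1 else 0.0,
            })
    return pd.DataFrame(rows)
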