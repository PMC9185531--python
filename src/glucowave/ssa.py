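"""Sparrow Search Algorithm (SSA) for hyperparameter optimisation.

SSA is a population metaheuristic modelled on the foraging of a sparrow
flock.  Each individual is a point in the (continuously encoded) search
box; on every iteration the population is ranked by fitness and updated in
three waves:

* **producers** (best ``producer_frac`` of the flock) explore: while the
  alarm value ``R2`` stays below the safety threshold ``ST`` they contract
  multiplicatively, ``x <- x * exp(-i / (alpha * n_iter))``; once danger is
  signalled they take a Gaussian step, ``x <- x + Q``;
* **scroungers** follow the best producer ``x_p``: the worse half scatter
  towards the global worst, ``x <- Q * exp((x_worst - x) / i^2)``, the
  better half move ``x <- x_p + |x - x_p| . A+`` with a random signed
  direction;
* a random ``alarm_frac`` of the flock is **danger-aware**: individuals
  away from the optimum jump towards it, ``x <- x_best + beta * |x -
  x_best|``; individuals at the optimum step away from the worst.

Positions are clipped to the box after every move, decoded to the integer
hyperparameter grid for evaluation (kernel sizes snap to odd values), and
evaluations are cached per decoded vector so re-visited settings cost
nothing.  The incumbent (best decoded vector and its fitness) can only
improve, so the recorded history is non-decreasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

#: dimension kinds: continuous values, integers, or odd integers
DimKind = str


@dataclass
class SearchSpace:
    """Box bounds plus per-dimension decoding kind and grid step."""

    bounds: list[tuple[float, float]]
    kinds: list[DimKind] = field(default_factory=list)
    steps: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.kinds:
            self.kinds = ["float"] * len(self.bounds)
        if not self.steps:
            self.steps = [1.0] * len(self.bounds)
        if len(self.kinds) != len(self.bounds) or len(self.steps) != len(self.bounds):
            raise ValueError("kinds, steps and bounds must have equal length")
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid bound ({lo}, {hi})")

    @property
    def dim(self) -> int:
        return len(self.bounds)

    def clip(self, x: np.ndarray) -> np.ndarray:
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.clip(x, lo, hi)


def decode(position: np.ndarray, space: SearchSpace) -> tuple:
    """Decode a continuous position to the evaluation grid.

    Clips to the box, rounds integer dimensions to the nearest point of
    their grid (``lo + k * step``) and odd-integer dimensions to the
    nearest odd value (ties upward: 4.0 decodes to 5), re-clipping so the
    result stays inside the bounds.
    """
    x = space.clip(np.asarray(position, dtype=float))
    out = []
    for v, (lo, hi), kind, step in zip(x, space.bounds, space.kinds, space.steps):
        if kind == "float":
            out.append(float(v))
        elif kind == "int":
            snapped = lo + step * round((v - lo) / step)
            out.append(int(np.clip(round(snapped), np.ceil(lo), np.floor(hi))))
        elif kind == "odd_int":
            o = 2 * round((v - 1.0) / 2.0) + 1
            lo_odd = int(np.ceil(lo)) + (1 - int(np.ceil(lo)) % 2)
            hi_odd = int(np.floor(hi)) - (1 - int(np.floor(hi)) % 2)
            out.append(int(np.clip(o, lo_odd, hi_odd)))
        else:
            raise ValueError(f"unknown dimension kind {kind!r}")
    return tuple(out)


@dataclass
class SsaHistory:
    """Per-iteration record of the incumbent."""

    best_fitness: list[float] = field(default_factory=list)
    best_position: list[tuple] = field(default_factory=list)
    n_evaluations: int = 0


def ssa_optimize(
    objective: Callable[[tuple], float],
    space: SearchSpace | Sequence[tuple[float, float]],
    pop_size: int = 6,
    n_iter: int = 5,
    seed: int = 0,
    producer_frac: float = 0.2,
    alarm_frac: float = 0.1,
    safety_threshold: float = 0.8,
    init_positions: Sequence[Sequence[float]] | None = None,
) -> tuple[tuple, float, SsaHistory]:
    """Maximise ``objective`` over the search space with SSA.

    Parameters
    ----------
    objective
        Maps a decoded hyperparameter tuple to a fitness (higher is
        better).  An exception inside the objective demotes that individual
        to the worst possible fitness and the run continues.
    space
        A :class:`SearchSpace`, or bare bounds for an all-float space.
    pop_size, n_iter, seed
        Flock size (>= 4), number of iterations, RNG seed.  The run is a
        deterministic function of its arguments.
    init_positions
        Optional positions for the first individuals — handy to guarantee
        that a reference configuration (e.g. the default hyperparameters)
        is part of the initial flock.

    Returns
    -------
    (best decoded vector, best fitness, history)
    """
    if not isinstance(space, SearchSpace):
        space = SearchSpace(bounds=[tuple(map(float, b)) for b in space])
    if pop_size < 4:
        raise ValueError("population size must be at least 4")
    if n_iter < 1:
        raise ValueError("need at least one iteration")
    rng = np.random.default_rng(seed)
    dim = space.dim
    lo = np.array([b[0] for b in space.bounds])
    hi = np.array([b[1] for b in space.bounds])

    cache: dict[tuple, float] = {}

    def fitness(position: np.ndarray) -> float:
        key = decode(position, space)
        if key not in cache:
            history.n_evaluations += 1
            try:
                cache[key] = float(objective(key))
            except Exception as exc:  # demote, log, continue
                warnings.warn(f"objective failed at {key}: {exc}")
                cache[key] = -np.inf
        return cache[key]

    history = SsaHistory()

    positions = lo + rng.random((pop_size, dim)) * (hi - lo)
    if init_positions is not None:
        for i, p in enumerate(init_positions[:pop_size]):
            positions[i] = space.clip(np.asarray(p, dtype=float))
    fits = np.array([fitness(p) for p in positions])

    best_i = int(np.argmax(fits))
    best_pos = positions[best_i].copy()
    best_fit = float(fits[best_i])

    n_producers = max(1, int(round(producer_frac * pop_size)))
    n_aware = max(1, int(round(alarm_frac * pop_size)))

    for it in range(1, n_iter + 1):
        order = np.argsort(-fits)  # best first
        worst_pos = positions[order[-1]].copy()
        r2 = rng.random()
        # --- producers -------------------------------------------------
        for rank in range(n_producers):
            i = order[rank]
            if r2 < safety_threshold:
                alpha = rng.random() + 1e-12
                positions[i] = positions[i] * np.exp(
                    -(rank + 1) / (alpha * n_iter)
                )
            else:
                positions[i] = positions[i] + rng.standard_normal(dim)
            positions[i] = space.clip(positions[i])
        producer_best = positions[order[0]].copy()
        # --- scroungers ------------------------------------------------
        for rank in range(n_producers, pop_size):
            i = order[rank]
            if rank + 1 > pop_size / 2:
                q = rng.standard_normal(dim)
                positions[i] = q * np.exp(
                    (worst_pos - positions[i]) / (rank + 1) ** 2
                )
            else:
                a = rng.choice([-1.0, 1.0], size=dim)
                step = float(np.abs(positions[i] - producer_best) @ a) / dim
                positions[i] = producer_best + step
            positions[i] = space.clip(positions[i])
        # --- danger-aware individuals ---------------------------------
        for i in rng.choice(pop_size, size=n_aware, replace=False):
            fi = fits[i]
            if fi < best_fit:
                beta = rng.standard_normal()
                positions[i] = best_pos + beta * np.abs(positions[i] - best_pos)
            else:  # already at the optimum: step away from the worst
                k = rng.uniform(-1.0, 1.0)
                worst_fit = float(fits[order[-1]])
                denom = abs(fi - worst_fit) + 1e-50
                positions[i] = positions[i] + k * (
                    np.abs(positions[i] - worst_pos) / denom
                )
            positions[i] = space.clip(positions[i])
        # --- evaluate and update incumbent ----------------------------
        fits = np.array([fitness(p) for p in positions])
        cand = int(np.argmax(fits))
        if fits[cand] > best_fit:
            best_fit = float(fits[cand])
            best_pos = positions[cand].copy()
        history.best_fitness.append(best_fit)
        history.best_position.append(decode(best_pos, space))

    return decode(best_pos, space), best_fit, history
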