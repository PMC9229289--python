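"""Bound-constrained Whale Optimization Algorithm (WOA).

A population metaheuristic alternating three moves around the elitist best
position X*: prey-encircling ``X <- X* - A.D`` with ``D = |C.X* - X|``,
logarithmic-spiral search ``X <- X* + D.exp(b l) cos(2 pi l)``, and random
exploration around another whale when ``|A| >= 1``. The control factor
``a`` decays linearly from 2 to 0 over the run, shifting the swarm from
exploration to exploitation. Branching follows the canonical scheme:
``p >= 0.5`` spiral; else encircle when ``|A| < 1`` and random-search
otherwise, with A/C drawn per dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WOAConfig", "WOAState", "convergence_factor", "step", "optimize"]


@dataclass
class WOAConfig:
    bounds: list[tuple[float, float]]
    pop_size: int = 10
    t_max: int = 100
    b: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        self.bounds = [(float(lo), float(hi)) for lo, hi in self.bounds]
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"degenerate bounds ({lo}, {hi})")

    @property
    def dim(self) -> int:
        return len(self.bounds)

    def lows_highs(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(self.bounds, dtype=float)
        return arr[:, 0], arr[:, 1]


@dataclass
class WOAState:
    positions: np.ndarray          # (pop_size, dim)
    fitness: np.ndarray            # (pop_size,)
    best_position: np.ndarray
    best_fitness: float
    t: int
    history: list[float] = field(default_factory=list)

    @property
    def a(self) -> float:
        """Current convergence factor (requires t_max via history length)."""
        return self._a

    _a: float = 2.0


def convergence_factor(t: int, t_max: int) -> float:
    """Linear decay a = 2 - 2t/Tmax, from 2 at t=0 to 0 at t=Tmax."""
    return 2.0 - 2.0 * t / t_max


def _evaluate(fitness_fn, positions: np.ndarray) -> np.ndarray:
    vals = np.array([float(fitness_fn(p)) for p in positions])
    if not np.all(np.isfinite(vals)):
        bad = positions[int(np.argmax(~np.isfinite(vals)))]
        raise ValueError(f"fitness function returned non-finite value at "
                         f"position {bad}")
    return vals


def init_state(fitness_fn, cfg: WOAConfig,
               rng: np.random.Generator) -> WOAState:
    lo, hi = cfg.lows_highs()
    pos = rng.uniform(lo, hi, size=(cfg.pop_size, cfg.dim))
    fit = _evaluate(fitness_fn, pos)
    best = int(np.argmin(fit))
    state = WOAState(pos, fit, pos[best].copy(), float(fit[best]), t=0,
                     history=[float(fit[best])])
    state._a = convergence_factor(0, cfg.t_max)
    return state


def step(state: WOAState, fitness_fn, cfg: WOAConfig,
         rng: np.random.Generator) -> WOAState:
    """Advance the swarm one iteration (elitist best is never lost)."""
    lo, hi = cfg.lows_highs()
    a = convergence_factor(state.t, cfg.t_max)
    pos = state.positions.copy()
    best = state.best_position
    for i in range(cfg.pop_size):
        p = rng.uniform()
        r1 = rng.uniform(size=cfg.dim)
        r2 = rng.uniform(size=cfg.dim)
        A = 2.0 * a * r1 - a
        C = 2.0 * r2
        if p >= 0.5:
            l = rng.uniform(-1.0, 1.0)
            D = np.abs(C * best - pos[i])
            pos[i] = best + D * np.exp(cfg.b * l) * np.cos(2 * np.pi * l)
        else:
            shrink = np.abs(A) < 1.0
            D_best = np.abs(C * best - pos[i])
            j = rng.integers(cfg.pop_size)
            x_rand = state.positions[j]
            D_rand = np.abs(C * x_rand - pos[i])
            enc = best - A * D_best
            rnd = x_rand - A * D_rand
            pos[i] = np.where(shrink, enc, rnd)
    np.clip(pos, lo, hi, out=pos)
    fit = _evaluate(fitness_fn, pos)
    b_i = int(np.argmin(fit))
    if fit[b_i] < state.best_fitness:
        best_pos, best_fit = pos[b_i].copy(), float(fit[b_i])
    else:
        best_pos, best_fit = state.best_position, state.best_fitness
    new = WOAState(pos, fit, best_pos, best_fit, t=state.t + 1,
                   history=state.history + [best_fit])
    new._a = convergence_factor(new.t, cfg.t_max)
    return new


def optimize(fitness_fn, cfg: WOAConfig):
    """Run the full WOA loop.

    Returns ``(best_position, best_fitness, history)`` where ``history`` is
    the best-so-far fitness after initialisation and after each of the
    ``t_max`` iterations (length ``t_max + 1``, non-increasing).
    """
    rng = np.random.default_rng(cfg.seed)
    state = init_state(fitness_fn, cfg, rng)
    for _ in range(cfg.t_max):
        state = step(state, fitness_fn, cfg, rng)
    return state.best_position.copy(), state.best_fitness, list(state.history)
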