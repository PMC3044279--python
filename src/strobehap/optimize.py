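"""Search over advance-length distributions for designs maximizing AN50.

The advance distribution is a scaled Beta(alpha, beta); the search space is
the open box (0, 4] per shape parameter. Two strategies:

* simulated annealing — per iteration, one fresh simulation at the current
  point and one at a random neighbor; AN50 observations are pooled per
  visited point and compared by median (the objective is noisy, so pooling
  across revisits stabilizes the comparison); worse moves are accepted with
  probability exp(delta / T) under a linearly decreasing temperature.
* an exhaustive coarse grid (the slow baseline the annealer is checked
  against).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .metrics import an50
from .simulator import DesignParams, simulate_experiment
from .track import VariantTrack

__all__ = [
    "AnnealConfig",
    "SearchTrace",
    "neighbor",
    "anneal",
    "coarse_grid_search",
    "optimize_multi_strobe",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_BETA_GRID",
]

# coarse baseline grid: alpha in (0, 3.4] step 0.2, beta in (0, 3] step 0.1
DEFAULT_ALPHA_GRID: Tuple[float, ...] = tuple(round(0.2 * i, 10) for i in range(1, 18))
DEFAULT_BETA_GRID: Tuple[float, ...] = tuple(round(0.1 * i, 10) for i in range(1, 31))

_T_FLOOR = 1e-6  # keep the acceptance ratio finite at the last iteration

Point = Tuple[float, ...]  # flattened (alpha_1, beta_1, ..., alpha_{k-1}, beta_{k-1})


@dataclass(frozen=True)
class AnnealConfig:
    """Annealing schedule.

    ``T0`` is the initial temperature (default 11,000, on the scale of AN50
    differences in bp); it is reduced by ``T0/iterations`` each iteration.
    The neighbor step is ``step_coarse`` for the first half of the
    iterations and ``step_fine`` afterwards. Each iteration runs two
    simulations, so the default budget is 450 simulations.
    """

    T0: float = 11_000.0
    iterations: int = 225
    step_coarse: float = 0.5
    step_fine: float = 0.1
    domain_max: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T0 <= 0:
            raise ValueError("T0 must be positive")
        if self.iterations < 2:
            raise ValueError("need at least 2 iterations")

    def step(self, i: int) -> float:
        """Step size at iteration ``i`` (0-based)."""
        return self.step_coarse if i < self.iterations / 2 else self.step_fine


@dataclass
class SearchTrace:
    """Everything observed during a search."""

    observations: Dict[Point, List[float]] = field(default_factory=dict)
    path: List[dict] = field(default_factory=list)
    best: Optional[Point] = None

    def record(self, point: Point, value: float) -> None:
        self.observations.setdefault(point, []).append(value)

    def median(self, point: Point) -> float:
        return float(np.median(self.observations[point]))

    @property
    def total_observations(self) -> int:
        return sum(len(v) for v in self.observations.values())

    def finalize_best(self) -> Point:
        self.best = max(self.observations, key=self.median)
        return self.best

    def path_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.path)


def _key(point: Sequence[float]) -> Point:
    # accumulated float steps (0.5/0.1) need a rounded grid key so revisits pool
    return tuple(round(x, 6) for x in point)


def neighbor(
    point: Sequence[float],
    s: float,
    rng: np.random.Generator,
    domain_max: float = 4.0,
) -> Point:
    """One of {(alpha +- s, beta), (alpha, beta +- s)} uniformly at random,
    redrawing any candidate that leaves (0, domain_max].

    Generalizes to flattened multi-advance points: a single coordinate is
    perturbed per move.
    """
    point = list(point)
    n = len(point)
    while True:
        coord = int(rng.integers(n)) if n > 2 else int(rng.integers(2))
        sign = 1.0 if rng.integers(2) else -1.0
        cand = point[coord] + sign * s
        if 0.0 < cand <= domain_max:
            out = list(point)
            out[coord] = cand
            return _key(out)


def _simulation_objective(
    track: VariantTrack, L: int, c: float, A: int, k: int
) -> Callable[[Point, np.random.Generator], float]:
    """AN50 of one fresh simulated experiment at the given design point."""

    def objective(point: Point, rng: np.random.Generator) -> float:
        pairs = tuple(
            (point[2 * i], point[2 * i + 1]) for i in range(len(point) // 2)
        )
        params = DesignParams(
            L=L, c=c, A=A, k=k, beta_params=pairs,
            seed=int(rng.integers(2**31)),
        )
        graph, _ = simulate_experiment(track, params, keep_reads=False)
        return float(an50(graph.connected_components(), track))

    return objective


def anneal(
    track: Optional[VariantTrack],
    L: int,
    c: float,
    A: int,
    k: int = 2,
    config: AnnealConfig = AnnealConfig(),
    objective: Optional[Callable[[Point, np.random.Generator], float]] = None,
    initial: Optional[Sequence[float]] = None,
    n_pairs: int = 1,
) -> SearchTrace:
    """Simulated annealing over (alpha, beta) (or 2*(k-1) coordinates).

    Per iteration: evaluate the objective once at the current point and once
    at a neighbor, pool the observations per point, compare pooled medians,
    cool ``T`` by ``T0/iterations`` and move with probability
    ``min(1, exp(delta/T))`` where ``delta = median' - median``. The best
    point (by pooled median) over all visited points is returned in the
    trace.

    ``objective`` defaults to a fresh simulated experiment's AN50; a
    deterministic stand-in can be injected for calibration.
    """
    rng = np.random.default_rng(config.seed)
    if objective is None:
        if track is None:
            raise ValueError("need a track unless an objective is injected")
        objective = _simulation_objective(track, L, c, A, k)
    dim = 2 * n_pairs
    if initial is None:
        current = _key(rng.uniform(0.0, config.domain_max, size=dim))
        # uniform on (0, domain_max]: a literal 0 draw has measure zero, but guard
        current = tuple(x if x > 0 else config.domain_max for x in current)
    else:
        current = _key(initial)
    trace = SearchTrace()
    T = config.T0
    for i in range(config.iterations):
        s = config.step(i)
        cand = neighbor(current, s, rng, config.domain_max)
        trace.record(current, objective(current, rng))
        trace.record(cand, objective(cand, rng))
        med, med_cand = trace.median(current), trace.median(cand)
        T = max(T - config.T0 / config.iterations, _T_FLOOR)
        delta = med_cand - med
        p_accept = 1.0 if delta >= 0 else math.exp(delta / T)
        accepted = bool(rng.random() < p_accept) if delta < 0 else True
        trace.path.append(
            {
                "iteration": i,
                "T": T,
                "step": s,
                "point": current,
                "candidate": cand,
                "median": med,
                "candidate_median": med_cand,
                "accepted": accepted,
            }
        )
        if accepted:
            current = cand
    trace.finalize_best()
    return trace


def coarse_grid_search(
    track: Optional[VariantTrack],
    L: int,
    c: float,
    A: int,
    k: int = 2,
    replicates: int = 25,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    beta_grid: Sequence[float] = DEFAULT_BETA_GRID,
    objective: Optional[Callable[[Point, np.random.Generator], float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Exhaustive baseline: ``replicates`` simulations per (alpha, beta)
    cell, median AN50 recorded.

    The default grid is alpha in (0, 3.4] step 0.2 and beta in (0, 3] step
    0.1 — 17 x 30 cells, hence 12,750 simulations at 25 replicates. Returns
    a DataFrame with columns (alpha, beta, n_obs, median_AN50).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    if objective is None:
        if track is None:
            raise ValueError("need a track unless an objective is injected")
        objective = _simulation_objective(track, L, c, A, k)
    rows = []
    for a in alpha_grid:
        for b in beta_grid:
            point = _key((a, b))
            obs = [objective(point, rng) for _ in range(replicates)]
            rows.append(
                {
                    "alpha": a,
                    "beta": b,
                    "n_obs": len(obs),
                    "median_AN50": float(np.median(obs)),
                }
            )
    return pd.DataFrame(rows)


def optimize_multi_strobe(
    track: Optional[VariantTrack],
    L: int,
    c: float,
    A: int,
    k: int,
    config: AnnealConfig = AnnealConfig(),
    objective: Optional[Callable[[Point, np.random.Generator], float]] = None,
) -> Tuple[List[Tuple[float, float]], SearchTrace]:
    """Anneal over all ``k - 1`` advance distributions jointly.

    The state is the flattened (alpha_1, beta_1, ..., alpha_{k-1},
    beta_{k-1}) vector; each neighbor move perturbs one coordinate of one
    pair. For ``k = 2`` this reduces exactly to :func:`anneal` on a single
    pair. Returns the best collection and the search trace.
    """
    if k < 2:
        raise ValueError("multi-strobe optimization needs k >= 2")
    trace = anneal(track, L, c, A, k=k, config=config, objective=objective, n_pairs=k - 1)
    best = trace.best
    pairs = [(best[2 * i], best[2 * i + 1]) for i in range(len(best) // 2)]
    return pairs, trace
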