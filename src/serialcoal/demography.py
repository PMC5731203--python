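"""Deterministic forward-in-time demography on the deme lattice.

Each generation applies logistic growth at the deme level, then stepping-stone
emigration: a deme emits a fraction m of its (post-growth) occupants, split
equally among its land neighbors.  Densities are continuous reals; the record
of per-generation densities conditions the backward coalescent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .world import LatticeWorld, ScenarioConfig

__all__ = [
    "SimulationError",
    "ForwardDemography",
    "logistic_step",
    "migration_step",
    "run_forward",
]

NEVER = -1  # colonization_time sentinel for demes never colonized


class SimulationError(RuntimeError):
    """Inconsistent demography encountered during simulation."""


def logistic_step(N: float, r: float, K: float) -> float:
    """One generation of discrete logistic growth, floored at 0.

    Returns N + r*N*(1 - N/K).
    """
    if K <= 0:
        raise ValueError("K must be positive")
    out = N + r * N * (1.0 - N / K)
    return out if out > 0.0 else 0.0


def _grow(dens: np.ndarray, r: float, K: float) -> np.ndarray:
    out = dens + r * dens * (1.0 - dens / K)
    np.maximum(out, 0.0, out=out)
    return out


def migration_step(
    densities: np.ndarray, m: float, world: LatticeWorld
) -> tuple[np.ndarray, np.ndarray]:
    """Redistribute emigrants to adjacent demes.

    Each deme i emits ``m * densities[i]`` individuals in total, split equally
    among its land neighbors; demes with no neighbors emit nothing.  Returns
    the post-migration densities and the directed flow matrix M of shape
    (D, 4), where ``M[i, k]`` is the flow from deme i to ``world.neighbors[i, k]``.
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError("m must lie in [0, 1]")
    dens = np.asarray(densities, dtype=np.float64)
    D = world.D
    if dens.shape != (D,):
        raise ValueError(f"densities must have shape ({D},)")
    deg = world.degree
    has_nbr = deg > 0
    per_edge = np.zeros(D)
    np.divide(m * dens, deg, out=per_edge, where=has_nbr)
    flows = per_edge[:, None] * (world.neighbors >= 0)
    new = dens.copy()
    new[has_nbr] -= m * dens[has_nbr]
    for k in range(4):
        dest = world.neighbors[:, k]
        valid = dest >= 0
        np.add.at(new, dest[valid], per_edge[valid])
    return new, flows


@dataclass
class ForwardDemography:
    """Recorded outcome of the forward demographic simulation.

    Attributes
    ----------
    scenario : ScenarioConfig
    densities : ndarray, shape (T+1, D)
        Post-migration density N(d, t) per land deme and forward generation.
    colonization_time : ndarray of int, shape (D,)
        First forward generation with N > 0 per deme; -1 if never colonized.
    K_gen, m_gen : ndarray, shape (T+1,)
        Schedules expanded per generation (the update producing generation t
        uses K_gen[t], m_gen[t]).
    """

    scenario: ScenarioConfig
    densities: np.ndarray = field(repr=False)
    colonization_time: np.ndarray = field(repr=False)
    K_gen: np.ndarray = field(repr=False)
    m_gen: np.ndarray = field(repr=False)

    @property
    def world(self) -> LatticeWorld:
        return self.scenario.world

    @property
    def T(self) -> int:
        return self.scenario.T

    def grown(self, t: int) -> np.ndarray:
        """Post-growth, pre-migration densities feeding generation t (t >= 1)."""
        if t < 1:
            raise ValueError("t must be >= 1")
        return _grow(self.densities[t - 1], self.scenario.r, float(self.K_gen[t]))

    def emigrants(self, t: int) -> np.ndarray:
        """Directed flows M(i->j, t) into generation t, shape (D, 4).

        ``emigrants(t)[i, k]`` is the number of migrants moving from deme i
        (generation t-1, post-growth) to ``world.neighbors[i, k]``.
        """
        g = self.grown(t)
        _, flows = migration_step(g, float(self.m_gen[t]), self.world)
        return flows

    def to_frame(self):
        """Long-format table (deme_row, deme_col, generation, N); for dumps."""
        import pandas as pd

        T1, D = self.densities.shape
        pos = self.world.positions
        return pd.DataFrame(
            {
                "deme_row": np.tile(pos[:, 0], T1),
                "deme_col": np.tile(pos[:, 1], T1),
                "generation": np.repeat(np.arange(T1), D),
                "N": self.densities.ravel(),
            }
        )


def run_forward(scenario: ScenarioConfig) -> ForwardDemography:
    """Run the deterministic forward demography for a scenario.

    Per generation: logistic growth with K(t), then emigration with m(t).
    Migration conserves the total population exactly (up to float rounding).
    """
    world = scenario.world
    T, D = scenario.T, world.D
    K_gen = scenario.K_schedule.per_generation(T)
    m_gen = scenario.m_schedule.per_generation(T)
    dens = np.zeros((T + 1, D))
    dens[0, world.origin_id] = float(scenario.N0)
    colonized = np.full(D, NEVER, dtype=np.int64)
    colonized[world.origin_id] = 0
    for t in range(1, T + 1):
        g = _grow(dens[t - 1], scenario.r, float(K_gen[t]))
        new, _ = migration_step(g, float(m_gen[t]), world)
        dens[t] = new
        fresh = (colonized == NEVER) & (new > 0.0)
        colonized[fresh] = t
    return ForwardDemography(
        scenario=scenario,
        densities=dens,
        colonization_time=colonized,
        K_gen=K_gen,
        m_gen=m_gen,
    )
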