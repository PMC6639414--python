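"""Adaptive walks on mean-noise fitness landscapes.

Cis-regulatory evolution is abstracted as a Gillespie walk on the landscape
grid with four mutation moves derived from the two-state telegraph model of
transcriptional bursting:

* burst-size mutations (s+, s-) change mean expression by one grid step
  (+-0.05 log2 units) at constant noise;
* burst-frequency mutations (f+, f-) change mean by one step and noise by
  one step in the opposite direction (-+0.025 log2 CV units; the noise axis
  is spaced twice as finely, encoding the inverse square-root coupling of
  noise to burst frequency).

Each move's rate is its fitness gain (clipped at zero — only mutations that
are selected for occur) times an optional relative-likelihood weight;
waiting times are exponential with mean 1/(summed rate). States where no
move has positive gain are absorbing. Fitness along a trajectory is
therefore non-decreasing by construction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import FitnessLandscape


class Move(str, enum.Enum):
    SIZE_UP = "s+"
    SIZE_DOWN = "s-"
    FREQ_UP = "f+"
    FREQ_DOWN = "f-"


#: grid-step deltas (mean index, noise index) per move
MOVE_DELTAS: dict[Move, tuple[int, int]] = {
    Move.SIZE_UP: (1, 0),
    Move.SIZE_DOWN: (-1, 0),
    Move.FREQ_UP: (1, -1),
    Move.FREQ_DOWN: (-1, 1),
}

DEFAULT_WEIGHTS = {m: 1.0 for m in Move}


@dataclass
class Trajectory:
    """One realization of a stochastic walk.

    ``states`` holds grid indices (mean, noise) including the start;
    ``moves`` and ``waiting_times`` have one entry per step; ``fitness``
    parallels ``states``. ``termination`` is "absorbing" or "max_steps".
    """

    states: list[tuple[int, int]] = field(default_factory=list)
    moves: list[Move] = field(default_factory=list)
    waiting_times: list[float] = field(default_factory=list)
    fitness: list[float] = field(default_factory=list)
    termination: str = "absorbing"

    def __len__(self) -> int:
        return len(self.moves)

    def to_frame(self, landscape: FitnessLandscape) -> pd.DataFrame:
        grid = landscape.grid
        mu = [grid.mu[i] for i, _ in self.states]
        eta = [grid.eta[j] for _, j in self.states]
        return pd.DataFrame({
            "step": np.arange(len(self.states)),
            "mu": mu, "eta": eta, "fitness": self.fitness,
            "move": [None] + [m.value for m in self.moves],
            "waiting_time": [np.nan] + list(self.waiting_times),
        })


def _check_state(state: tuple[int, int], landscape: FitnessLandscape) -> None:
    i, j = state
    n_mu, n_eta = landscape.grid.shape
    if not (0 <= i < n_mu and 0 <= j < n_eta):
        raise ValueError(f"state {state} outside the grid")


def move_gains(state: tuple[int, int], landscape: FitnessLandscape
               ) -> dict[Move, float | None]:
    """Fitness gain of each move from ``state``; None where off-grid."""
    _check_state(state, landscape)
    i, j = state
    n_mu, n_eta = landscape.grid.shape
    here = landscape.f[i, j]
    gains: dict[Move, float | None] = {}
    for move, (di, dj) in MOVE_DELTAS.items():
        ti, tj = i + di, j + dj
        if 0 <= ti < n_mu and 0 <= tj < n_eta:
            gains[move] = float(landscape.f[ti, tj] - here)
        else:
            gains[move] = None
    return gains


def gillespie_step(state: tuple[int, int], landscape: FitnessLandscape,
                   likelihood_weights: dict[Move, float] | None = None,
                   rng: np.random.Generator | None = None
                   ) -> tuple[Move | None, tuple[int, int] | None, float]:
    """One Gillespie event: (move, next state, waiting time).

    Rates are ``weight * max(gain, 0)``; when every rate is zero the state
    is absorbing and ``(None, None, inf)`` is returned.
    """
    rng = rng if rng is not None else np.random.default_rng()
    weights = likelihood_weights or DEFAULT_WEIGHTS
    gains = move_gains(state, landscape)
    moves = [m for m in Move if gains[m] is not None]
    rates = np.array([weights.get(m, 1.0) * max(gains[m], 0.0)
                      for m in moves])
    total = rates.sum()
    if total <= 0.0:
        return None, None, float("inf")
    pick = moves[rng.choice(len(moves), p=rates / total)]
    wait = rng.exponential(1.0 / total)
    di, dj = MOVE_DELTAS[pick]
    return pick, (state[0] + di, state[1] + dj), wait


def simulate_walk(start: tuple[int, int], landscape: FitnessLandscape,
                  likelihood_weights: dict[Move, float] | None = None,
                  max_steps: int = 1000,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None) -> Trajectory:
    """Iterate Gillespie steps until absorbing or ``max_steps``."""
    _check_state(start, landscape)
    rng = rng if rng is not None else np.random.default_rng(seed)
    traj = Trajectory()
    state = tuple(start)
    traj.states.append(state)
    traj.fitness.append(float(landscape.f[state]))
    for _ in range(max_steps):
        move, nxt, wait = gillespie_step(state, landscape,
                                         likelihood_weights, rng)
        if move is None:
            traj.termination = "absorbing"
            return traj
        state = nxt
        traj.moves.append(move)
        traj.waiting_times.append(wait)
        traj.states.append(state)
        traj.fitness.append(float(landscape.f[state]))
    traj.termination = "max_steps"
    return traj


def noise_funnel_mask(landscape: FitnessLandscape) -> np.ndarray:
    """Grid points where f+ and s- are simultaneously beneficial.

    In this region the two opposing moves combine to lower noise at
    unchanged mean expression — the noise funnel of peaked landscapes.
    Points whose f+ or s- target leaves the grid are False.
    """
    f = landscape.f
    gain_fp = np.full(f.shape, -np.inf)
    gain_sm = np.full(f.shape, -np.inf)
    gain_fp[:-1, 1:] = f[1:, :-1] - f[:-1, 1:]
    gain_sm[1:, :] = f[:-1, :] - f[1:, :]
    return (gain_fp > 0) & (gain_sm > 0)


def epistasis(landscape: FitnessLandscape, state: tuple[int, int],
              move_a: Move, move_b: Move) -> tuple[float, float, float]:
    """(expected, observed, epistasis) for a pair of mutations.

    expected = f(state) + gain(A) + gain(B); observed = f(state + A + B);
    epistasis = observed - expected. All four states must be on the grid.
    """
    _check_state(state, landscape)
    i, j = state
    da, db = MOVE_DELTAS[move_a], MOVE_DELTAS[move_b]
    targets = [(i + da[0], j + da[1]), (i + db[0], j + db[1]),
               (i + da[0] + db[0], j + da[1] + db[1])]
    for t in targets:
        _check_state(t, landscape)
    here = float(landscape.f[i, j])
    gain_a = float(landscape.f[targets[0]]) - here
    gain_b = float(landscape.f[targets[1]]) - here
    expected = here + gain_a + gain_b
    observed = float(landscape.f[targets[2]])
    return expected, observed, observed - expected


def funnel_mask_frame(landscape: FitnessLandscape) -> pd.DataFrame:
    """Long-format funnel mask (mu, eta, in_funnel)."""
    grid = landscape.grid
    mm, ee = np.meshgrid(grid.mu, grid.eta, indexing="ij")
    return pd.DataFrame({
        "mu": mm.ravel(), "eta": ee.ravel(),
        "in_funnel": noise_funnel_mask(landscape).ravel(),
    })
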