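"""Weighted, self-adaptive teaching-learning phases.

The teacher phase pulls every learner's real-coded dimensions toward the best
learner through the class mean, scaled by a teaching factor; the learner
phase performs pairwise peer learning.  A rank-dependent inertia weight
retains more of a good learner's old position.  Fitness is maximized
throughout; both phases use greedy acceptance (keep the better of old/new).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TLBOParams",
    "TLBOState",
    "inertia_weight",
    "teaching_factor",
    "teacher_phase",
    "learner_phase",
    "rank_population",
]


@dataclass
class TLBOParams:
    """Constants for the weighted/self-adaptive phases.

    ``tf_mode``: ``classic`` draws T_f = round(1 + U[0,1]) in {1, 2};
    ``adaptive`` uses the cosine decay cos(i_omega * it / max_it);
    ``rp_threshold`` returns 2 when the ranking probability is below
    ``rp_epsilon`` and 1 otherwise.
    """

    omega_min: float = 0.4
    omega_max: float = 0.9
    i_omega: float = 0.9
    tf_mode: str = "adaptive"
    rp_epsilon: float = 0.5
    best_gets_max_omega: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.omega_min <= self.omega_max <= 1):
            raise ValueError("require 0 < omega_min <= omega_max <= 1")
        if not (0 <= self.i_omega <= math.pi / 2):
            raise ValueError("i_omega must lie in [0, pi/2]")
        if self.tf_mode not in ("classic", "adaptive", "rp_threshold"):
            raise ValueError(f"unknown tf_mode {self.tf_mode!r}")


@dataclass
class TLBOState:
    """Real-coded population snapshot used by the two phases.

    ``positions`` is (n_learners, n_dims); ``fitnesses`` the matching scores
    (higher is better).  ``n_selected`` feeds the deterministic tie-break
    (fewer features first, then lower index) when selecting the teacher.
    """

    positions: np.ndarray
    fitnesses: np.ndarray
    bounds: np.ndarray  # (n_dims, 2) [lo, hi]
    iteration: int = 0
    max_iterations: int = 1
    n_selected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.fitnesses = np.asarray(self.fitnesses, dtype=float)
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.positions.shape[0] != self.fitnesses.size:
            raise ValueError("positions and fitnesses disagree on population size")
        if not (0 <= self.iteration <= self.max_iterations):
            raise ValueError("iteration must lie in [0, max_iterations]")
        if self.n_selected is None:
            self.n_selected = np.zeros(self.fitnesses.size, dtype=int)

    @property
    def n_learners(self) -> int:
        return self.positions.shape[0]

    @property
    def teacher_index(self) -> int:
        order = sorted(
            range(self.n_learners),
            key=lambda i: (-self.fitnesses[i], self.n_selected[i], i),
        )
        return order[0]

    @property
    def means(self) -> np.ndarray:
        return self.positions.mean(axis=0)


def inertia_weight(rank: int, total_pop: int, params: TLBOParams) -> float:
    """Rank-proportional inertia weight.

    ``omega = (rank / total_pop) * (omega_max - omega_min) + omega_min`` with
    1-based ranks; rank ``total_pop`` yields ``omega_max``.
    """
    if not (1 <= rank <= total_pop):
        raise ValueError("rank must lie in [1, total_pop]")
    return (rank / total_pop) * (params.omega_max - params.omega_min) + params.omega_min


def teaching_factor(
    mode: str,
    rng: np.random.Generator,
    i_omega: float = 0.9,
    it: int = 0,
    max_it: int = 1,
    rp: float = 1.0,
    rp_epsilon: float = 0.5,
) -> float:
    """Teaching factor under the three supported schedules."""
    if not (0 <= it <= max_it):
        raise ValueError("require 0 <= it <= max_it")
    if mode == "classic":
        return float(round(1.0 + rng.random()))
    if mode == "adaptive":
        return math.cos(i_omega * it / max_it)
    if mode == "rp_threshold":
        return 2.0 if rp < rp_epsilon else 1.0
    raise ValueError(f"unknown teaching-factor mode {mode!r}")


def rank_population(state: TLBOState) -> np.ndarray:
    """1-based ranks; the best learner receives rank ``n_learners``.

    Ties are broken by (fewer selected features, lower index), matching the
    teacher-selection convention, so ranks are always a permutation.
    """
    order = sorted(
        range(state.n_learners),
        key=lambda i: (-state.fitnesses[i], state.n_selected[i], i),
    )
    ranks = np.empty(state.n_learners, dtype=int)
    for pos, idx in enumerate(order):
        ranks[idx] = state.n_learners - pos  # best -> total_pop
    return ranks


def _clip(positions: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    return np.clip(positions, bounds[:, 0], bounds[:, 1])


def teacher_phase(
    state: TLBOState,
    params: TLBOParams,
    rng: np.random.Generator,
    fitness_fn: Callable[[np.ndarray], float] | None = None,
) -> TLBOState:
    """Move every learner toward the teacher through the class mean.

    ``X_new = omega_i * X_old + r * (X_teacher - T_f * M)`` with the inertia
    weight from the learner's rank and the configured teaching factor;
    results are clipped to bounds.  With ``fitness_fn`` supplied, greedy
    acceptance keeps the better of old/new; otherwise candidates are
    returned unevaluated (fitnesses copied), for callers that batch their
    evaluations.
    """
    ranks = rank_population(state)
    if not params.best_gets_max_omega:
        ranks = state.n_learners + 1 - ranks
    teacher = state.positions[state.teacher_index]
    mean = state.means
    new_positions = state.positions.copy()
    new_fitnesses = state.fitnesses.copy()
    rp_ranks = ranks / state.n_learners
    for i in range(state.n_learners):
        tf = teaching_factor(
            params.tf_mode,
            rng,
            i_omega=params.i_omega,
            it=state.iteration,
            max_it=state.max_iterations,
            rp=float(rp_ranks[i]),
            rp_epsilon=params.rp_epsilon,
        )
        omega = inertia_weight(int(ranks[i]), state.n_learners, params)
        r = rng.random(state.positions.shape[1])
        cand = omega * state.positions[i] + r * (teacher - tf * mean)
        cand = _clip(cand, state.bounds)
        if fitness_fn is None:
            new_positions[i] = cand
        else:
            f = fitness_fn(cand)
            if f >= state.fitnesses[i]:
                new_positions[i] = cand
                new_fitnesses[i] = f
    return TLBOState(
        new_positions,
        new_fitnesses,
        state.bounds,
        iteration=state.iteration,
        max_iterations=state.max_iterations,
        n_selected=state.n_selected.copy(),
    )


def learner_phase(
    state: TLBOState,
    rng: np.random.Generator,
    fitness_fn: Callable[[np.ndarray], float] | None = None,
) -> TLBOState:
    """Pairwise peer learning on the real dimensions.

    For each learner, two distinct peers p != q are drawn; the learner steps
    toward the fitter of the two: ``X_i + r * (X_better - X_worse)``.
    Greedy acceptance as in :func:`teacher_phase`.
    """
    if state.n_learners < 2:
        raise ValueError("learner phase needs a population of at least 2")
    new_positions = state.positions.copy()
    new_fitnesses = state.fitnesses.copy()
    for i in range(state.n_learners):
        p, q = rng.choice(state.n_learners, size=2, replace=False)
        r = rng.random(state.positions.shape[1])
        if state.fitnesses[p] > state.fitnesses[q]:
            step = state.positions[p] - state.positions[q]
        else:
            step = state.positions[q] - state.positions[p]
        cand = _clip(state.positions[i] + r * step, state.bounds)
        if fitness_fn is None:
            new_positions[i] = cand
        else:
            f = fitness_fn(cand)
            if f >= state.fitnesses[i]:
                new_positions[i] = cand
                new_fitnesses[i] = f
    return TLBOState(
        new_positions,
        new_fitnesses,
        state.bounds,
        iteration=state.iteration,
        max_iterations=state.max_iterations,
        n_selected=state.n_selected.copy(),
    )
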