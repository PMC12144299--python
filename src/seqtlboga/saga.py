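"""Self-adaptive genetic operators.

Crossover and mutation probabilities track the population's fitness spread
instead of staying constant, and can additionally be driven by the quantum
genotype (amplitude-derived crossover rates, overlap-derived mutation
rates).  All formulas assume maximization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from seqtlboga.qpop import BinaryLearner, QubitLearner

__all__ = [
    "SAGAParams",
    "FitnessSummary",
    "adaptive_pc",
    "adaptive_pm",
    "quantum_pc",
    "quantum_pm",
    "crossover",
    "mutate",
    "select",
]

_PC_FLOOR = 0.01
_PM_FLOOR = 0.001

CROSSOVER_KINDS = ("one_point", "two_point", "uniform")
MUTATION_KINDS = ("bit_flip", "gaussian_real")


@dataclass
class SAGAParams:
    """Constants of the adaptive probability formulas and operator choices.

    ``c3`` and ``c6`` anchor the lower branches to the base crossover and
    mutation rates (0.7 and 0.4 by default).
    """

    c1: float = 0.5
    c2: float = 0.0
    c3: float = 0.7
    c4: float = 0.5
    c5: float = 0.0
    c6: float = 0.4
    base_pc: float = 0.7
    base_pm: float = 0.4
    tournament_size: int = 3
    crossover_kind: str = "uniform"
    mutation_kind: str = "bit_flip"

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "c3", "c4", "c5", "c6", "base_pc", "base_pm"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.tournament_size < 2:
            raise ValueError("tournament_size must be >= 2")
        if self.crossover_kind not in CROSSOVER_KINDS:
            raise ValueError(f"unknown crossover kind {self.crossover_kind!r}")
        if self.mutation_kind not in MUTATION_KINDS:
            raise ValueError(f"unknown mutation kind {self.mutation_kind!r}")


@dataclass(frozen=True)
class FitnessSummary:
    """Population fitness statistics feeding the adaptive formulas."""

    f_max: float
    f_min: float
    f_avg: float
    f_b: float  # top value after crossover and mutation among selected learners

    def __post_init__(self) -> None:
        # tolerance absorbs summation roundoff when all fitnesses coincide
        tol = 1e-9 * max(1.0, abs(self.f_max))
        if not (self.f_min - tol <= self.f_avg <= self.f_max + tol):
            raise ValueError("require f_min <= f_avg <= f_max")


def adaptive_pc(s: FitnessSummary, p: SAGAParams) -> float:
    """Fitness-driven crossover probability.

    Upper branch (f_b >= f_avg): ``[1 - c1*(f_max - f_b)/(f_max - f_avg)] - c2``
    clamped to [0.01, 1]; degenerate spread (f_max == f_avg) and the lower
    branch both return ``c3``.
    """
    if s.f_b < s.f_avg:
        return p.c3
    denom = s.f_max - s.f_avg
    if denom <= 0.0:
        return p.c3
    pc = (1.0 - p.c1 * (s.f_max - s.f_b) / denom) - p.c2
    return min(max(pc, _PC_FLOOR), 1.0)


def adaptive_pm(s: FitnessSummary, p: SAGAParams) -> float:
    """Fitness-driven mutation probability.

    Upper branch (f_b >= f_avg): ``[1 - c4*f_b/(f_max - f_min + f_avg)] - c5``
    clamped to [0.001, 1]; zero denominator and the lower branch return
    ``c6``.
    """
    if s.f_b < s.f_avg:
        return p.c6
    denom = s.f_max - s.f_min + s.f_avg
    if denom <= 0.0:
        return p.c6
    pm = (1.0 - p.c4 * s.f_b / denom) - p.c5
    return min(max(pm, _PM_FLOOR), 1.0)


def quantum_pc(q: QubitLearner, position: int) -> float:
    """Amplitude-derived crossover rate: ``beta[position]**2``."""
    if not (0 <= position < q.n_features):
        raise ValueError("position out of range")
    return float(q.beta[position] ** 2)


def quantum_pm(overlap_value: float, scale: float = 1.0) -> float:
    """Overlap-derived mutation rate.

    ``scale * arccos(overlap) / (pi/2)`` clamped to [0, 1]; identical states
    (overlap 1) yield 0, orthogonal states (overlap 0) yield ``scale``.
    """
    if not (0.0 <= overlap_value <= 1.0):
        warnings.warn("overlap outside [0, 1]; clipping", stacklevel=2)
        overlap_value = min(max(overlap_value, 0.0), 1.0)
    pm = scale * math.acos(overlap_value) / (math.pi / 2.0)
    return min(max(pm, 0.0), 1.0)


def _repair(mask: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Force at least one selected bit (lowest index of the template's ones,
    else bit 0)."""
    if mask.sum() > 0:
        return mask
    ones = np.flatnonzero(template)
    mask = mask.copy()
    mask[int(ones[0]) if ones.size else 0] = 1
    return mask


def crossover(
    parent_a: BinaryLearner,
    parent_b: BinaryLearner,
    pc: float,
    kind: str,
    rng: np.random.Generator,
) -> tuple[BinaryLearner, BinaryLearner]:
    """Recombine two learners with probability ``pc``.

    Masks are spliced by the requested kind (one_point / two_point /
    uniform); the real (C, sigma) tails are blended by arithmetic crossover
    in log space with a shared draw.  Empty offspring masks are repaired.
    """
    if parent_a.n_features != parent_b.n_features:
        raise ValueError("parents must have equal mask length")
    if kind not in CROSSOVER_KINDS:
        raise ValueError(f"unknown crossover kind {kind!r}")
    n = parent_a.n_features
    if rng.random() >= pc:
        return parent_a, parent_b

    a, b = parent_a.mask.copy(), parent_b.mask.copy()
    if kind == "one_point":
        cut = int(rng.integers(1, n)) if n > 1 else 1
        a[cut:], b[cut:] = parent_b.mask[cut:], parent_a.mask[cut:]
    elif kind == "two_point":
        if n > 2:
            lo, hi = sorted(rng.choice(np.arange(1, n), size=2, replace=False))
        else:
            lo, hi = 0, n
        a[lo:hi], b[lo:hi] = parent_b.mask[lo:hi], parent_a.mask[lo:hi]
    else:  # uniform
        swap = rng.random(n) < 0.5
        a[swap], b[swap] = parent_b.mask[swap], parent_a.mask[swap]

    gamma = rng.random()
    log_c = np.log([parent_a.c_value, parent_b.c_value])
    log_s = np.log([parent_a.sigma_value, parent_b.sigma_value])
    c_a = float(np.exp(gamma * log_c[0] + (1 - gamma) * log_c[1]))
    c_b = float(np.exp(gamma * log_c[1] + (1 - gamma) * log_c[0]))
    s_a = float(np.exp(gamma * log_s[0] + (1 - gamma) * log_s[1]))
    s_b = float(np.exp(gamma * log_s[1] + (1 - gamma) * log_s[0]))

    a = _repair(a, parent_a.mask)
    b = _repair(b, parent_b.mask)
    return BinaryLearner(a, c_a, s_a), BinaryLearner(b, c_b, s_b)


def mutate(
    learner: BinaryLearner,
    pm: float,
    rng: np.random.Generator,
    real_sigma: float = 0.1,
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> BinaryLearner:
    """Flip each bit independently with probability ``pm``; perturb the real
    tail by a bounded multiplicative log-normal step with the same
    probability.  Empty masks are repaired to the learner's first previously
    selected bit."""
    if not (0.0 <= pm <= 1.0):
        raise ValueError("pm must lie in [0, 1]")
    flips = rng.random(learner.n_features) < pm
    mask = np.where(flips, 1 - learner.mask, learner.mask).astype(np.int8)
    mask = _repair(mask, learner.mask)

    c, s = learner.c_value, learner.sigma_value
    if rng.random() < pm:
        c = float(c * np.exp(rng.normal(0.0, real_sigma)))
    if rng.random() < pm:
        s = float(s * np.exp(rng.normal(0.0, real_sigma)))
    if bounds is not None:
        (c_lo, c_hi), (s_lo, s_hi) = bounds
        c = min(max(c, c_lo), c_hi)
        s = min(max(s, s_lo), s_hi)
    return BinaryLearner(mask, c, s)


def select(
    population: list,
    fitnesses: np.ndarray,
    tournament_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Tournament selection with replacement; returns parent indices.

    Index 0 of the result is always the incumbent best (elitism); ties are
    broken toward the lower index.
    """
    if len(population) == 0:
        raise ValueError("population must be non-empty")
    fitnesses = np.asarray(fitnesses, dtype=float)
    n = len(population)
    k = min(tournament_size, n)
    best = int(np.argmax(fitnesses))  # argmax takes the first maximum
    out = np.empty(n, dtype=int)
    out[0] = best
    for i in range(1, n):
        contenders = rng.choice(n, size=k, replace=False)
        scores = fitnesses[contenders]
        tied = contenders[scores == scores.max()]
        out[i] = tied[rng.integers(0, tied.size)] if tied.size > 1 else tied[0]
    return out
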