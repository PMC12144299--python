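"""Quantum population primitives.

Each candidate solution carries one qubit per feature, stored as a pair of
probability amplitudes ``(alpha, beta)`` with ``alpha**2 + beta**2 == 1``.
``beta[j]**2`` is the probability of observing bit ``j`` as 1 (feature
selected).  The real-coded hyperparameter tail ``(C, sigma)`` rides along
unchanged through quantum operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "QubitLearner",
    "BinaryLearner",
    "RotationPolicy",
    "init_population",
    "observe",
    "rotate",
    "rotation_angles",
    "distance_ratio",
    "overlap",
    "entangle_xor",
]

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class QubitLearner:
    """Qubit-encoded genotype: amplitude pairs plus an (C, sigma) tail."""

    alpha: np.ndarray
    beta: np.ndarray
    c_value: float
    sigma_value: float

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        if alpha.ndim != 1 or alpha.shape != beta.shape:
            raise ValueError("alpha and beta must be 1-D vectors of equal length")
        if alpha.size < 1:
            raise ValueError("need at least one feature qubit")
        norm = alpha**2 + beta**2
        if not np.all(np.abs(norm - 1.0) < 1e-6):
            raise ValueError("amplitude pairs must satisfy alpha^2 + beta^2 = 1")
        if not (self.c_value > 0 and self.sigma_value > 0):
            raise ValueError("c_value and sigma_value must be positive")

    @property
    def n_features(self) -> int:
        return self.alpha.size

    def selection_probabilities(self) -> np.ndarray:
        """Per-position probability of observing a 1 (``beta**2``)."""
        return self.beta**2


@dataclass(frozen=True)
class BinaryLearner:
    """Observed phenotype: feature mask plus decoded (C, sigma)."""

    mask: np.ndarray
    c_value: float
    sigma_value: float

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=np.int8)
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 1 or mask.size < 1:
            raise ValueError("mask must be a non-empty 1-D bit vector")
        if not np.all((mask == 0) | (mask == 1)):
            raise ValueError("mask entries must be 0 or 1")
        if mask.sum() < 1:
            raise ValueError("mask must select at least one feature (repair upstream)")
        if not (self.c_value > 0 and self.sigma_value > 0):
            raise ValueError("c_value and sigma_value must be positive")

    @property
    def n_features(self) -> int:
        return self.mask.size

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def _default_lookup() -> dict:
    # (current_bit, best_bit, current_worse) -> signed multiple of theta_step.
    # Rotation only when bits disagree AND the current learner is worse;
    # sign pushes beta^2 toward the best learner's bit.
    table = {}
    for b in (0, 1):
        for worse in (False, True):
            table[(b, b, worse)] = 0.0
            table[(b, 1 - b, False)] = 0.0
    table[(0, 1, True)] = +1.0  # grow beta^2 toward 1
    table[(1, 0, True)] = -1.0  # shrink beta^2 toward 0
    return table


@dataclass(frozen=True)
class RotationPolicy:
    """Direction table for guided rotation toward a reference learner.

    The default step magnitude is 0.01*pi; entries are signed multiples of
    ``theta_step`` keyed by ``(current_bit, best_bit, current_worse)``.
    """

    theta_step: float = 0.01 * np.pi
    lookup: dict = field(default_factory=_default_lookup)

    def __post_init__(self) -> None:
        if self.theta_step < 0:
            raise ValueError("theta_step must be non-negative")
        for key, mult in self.lookup.items():
            cur, best, _ = key
            if abs(mult) > 1.0 + 1e-12:
                raise ValueError("lookup multiples must not exceed 1 in magnitude")
            if cur == best and mult != 0.0:
                raise ValueError("agreeing bits must map to a zero rotation")


def init_population(
    n_learners: int,
    n_features: int,
    bounds: tuple[tuple[float, float], tuple[float, float]],
    rng: np.random.Generator,
) -> list[QubitLearner]:
    """Equal-superposition quantum population with log-uniform (C, sigma) tails.

    Every amplitude pair starts at ``(1/sqrt(2), 1/sqrt(2))`` so each feature
    is initially selected with probability 1/2.  ``bounds`` is
    ``((c_lo, c_hi), (sigma_lo, sigma_hi))``.
    """
    if n_learners < 2:
        raise ValueError("n_learners must be >= 2")
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    (c_lo, c_hi), (s_lo, s_hi) = bounds
    if not (0 < c_lo <= c_hi and 0 < s_lo <= s_hi):
        raise ValueError("bounds must be positive and ordered")
    amp = np.full(n_features, 1.0 / np.sqrt(2.0))
    pop = []
    for _ in range(n_learners):
        c = float(np.exp(rng.uniform(np.log(c_lo), np.log(c_hi))))
        s = float(np.exp(rng.uniform(np.log(s_lo), np.log(s_hi))))
        pop.append(QubitLearner(amp.copy(), amp.copy(), c, s))
    return pop


def observe(q: QubitLearner, rng: np.random.Generator) -> BinaryLearner:
    """Collapse a qubit string into a concrete bit mask.

    Bit ``j`` is 1 iff ``u_j < beta[j]**2`` with ``u_j ~ U[0,1]``.  An
    all-zero draw is repaired deterministically by setting the single bit
    with maximal ``beta**2`` (ties broken toward the lowest index).
    """
    p1 = q.selection_probabilities()
    mask = (rng.random(q.n_features) < p1).astype(np.int8)
    if mask.sum() == 0:
        mask[int(np.argmax(p1))] = 1
    return BinaryLearner(mask, q.c_value, q.sigma_value)


def rotate(q: QubitLearner, delta_theta: np.ndarray) -> QubitLearner:
    """Apply the 2x2 rotation gate per position.

    ``(a', b') = (a cos t - b sin t, a sin t + b cos t)``; orthogonality
    preserves the amplitude normalization exactly (up to roundoff).
    """
    dt = np.asarray(delta_theta, dtype=float)
    if dt.shape != q.alpha.shape:
        raise ValueError("delta_theta length must match the number of qubits")
    if not np.all(np.isfinite(dt)):
        raise ValueError("delta_theta must be finite")
    c, s = np.cos(dt), np.sin(dt)
    alpha = q.alpha * c - q.beta * s
    beta = q.alpha * s + q.beta * c
    return replace(q, alpha=alpha, beta=beta)


def rotation_angles(
    current: BinaryLearner,
    best: BinaryLearner,
    current_fitness: float,
    best_fitness: float,
    policy: RotationPolicy | None = None,
) -> np.ndarray:
    """Signed rotation angles steering ``current`` toward ``best``.

    Zero where the bits agree; where they disagree and the current learner is
    strictly worse, the angle has magnitude ``theta_step`` signed so that
    ``beta**2`` moves toward the best learner's bit.
    """
    if policy is None:
        policy = RotationPolicy()
    if current.n_features != best.n_features:
        raise ValueError("masks must have equal length")
    worse = bool(current_fitness < best_fitness)
    out = np.empty(current.n_features, dtype=float)
    for j in range(current.n_features):
        mult = policy.lookup.get((int(current.mask[j]), int(best.mask[j]), worse), 0.0)
        out[j] = mult * policy.theta_step
    return out


def _as_mask(b) -> np.ndarray:
    # accept BinaryLearner or a raw bit vector (raw vectors skip the
    # at-least-one-bit repair invariant, matching the printed formula)
    mask = b.mask if isinstance(b, BinaryLearner) else np.asarray(b, dtype=np.int8)
    if mask.ndim != 1 or not np.all((mask == 0) | (mask == 1)):
        raise ValueError("mask must be a 1-D bit vector")
    return mask


def distance_ratio(b1, b2) -> float:
    """Hamming-distance ratio between two binary learners.

    ``d = delta / (2m - sum(b1) - sum(b2))`` where ``delta`` counts
    differing bits and ``m`` is the mask length.  Identical masks return 0
    (covering the 0/0 form of two all-ones masks).  Accepts
    :class:`BinaryLearner` or raw bit vectors.
    """
    m1, m2 = _as_mask(b1), _as_mask(b2)
    if m1.size != m2.size:
        raise ValueError("masks must have equal length")
    delta = int(np.sum(m1 != m2))
    if delta == 0:
        return 0.0
    denom = 2 * m1.size - int(m1.sum()) - int(m2.sum())
    return delta / denom


def overlap(p: QubitLearner, q: QubitLearner) -> float:
    """Mean per-qubit inner-product magnitude, in [0, 1]."""
    if p.n_features != q.n_features:
        raise ValueError("learners must have equal length")
    inner = np.abs(p.alpha * q.alpha + p.beta * q.beta)
    return float(min(np.mean(inner), 1.0))  # guard roundoff above 1


def entangle_xor(teacher_bits, learner_bits) -> np.ndarray:
    """Position-wise XOR of two masks — the disagreement indicator."""
    m1, m2 = _as_mask(teacher_bits), _as_mask(learner_bits)
    if m1.size != m2.size:
        raise ValueError("masks must have equal length")
    return np.bitwise_xor(m1, m2)
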