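"""Optimizer orchestration.

One interface runs the quantum self-adaptive TLBO/GA hybrid and five
baseline wrappers (GA, PSO, CS, DE, GOA) under a strict evaluation-budget
parity contract: every algorithm issues exactly
``population_size * (max_iterations + 1)`` fitness evaluations (the +1 pays
for initialization), so benchmark comparisons are fair by construction.

Continuous-update baselines (PSO, CS, DE, GOA) search a vector of
``n_features + 2`` dimensions; the first ``n`` are mapped to mask bits by a
sigmoid transfer thresholded at a uniform draw, the last two are the
(log C, log sigma) tail.  GOA follows the standard grasshopper update from
the general literature and is excluded from any result-anchored test.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma_fn

from seqtlboga import qpop, saga, tlbo
from seqtlboga.qpop import BinaryLearner, QubitLearner, RotationPolicy
from seqtlboga.saga import SAGAParams, FitnessSummary
from seqtlboga.tlbo import TLBOParams, TLBOState
from seqtlboga.wrapper_fitness import (
    Dataset,
    FitnessResult,
    MetricSet,
    compute_metrics,
    evaluate_fitness,
)

__all__ = [
    "OptimizerConfig",
    "RunRecord",
    "run_seqtlboga",
    "run_baseline",
    "run",
    "levy_sample",
    "ALGORITHMS",
]

ALGORITHMS = ("seqtlboga", "ga", "pso", "cs", "de", "goa")


@dataclass
class OptimizerConfig:
    """All run constants; defaults follow the reference configuration
    (population 30, 100 iterations, rotation step 0.01*pi, tournament 3)."""

    population_size: int = 30
    max_iterations: int = 100
    theta_step: float = 0.01 * math.pi
    tlbo: TLBOParams = field(default_factory=TLBOParams)
    saga: SAGAParams = field(default_factory=SAGAParams)
    kernel: str = "rbf"
    k_folds: int = 10
    c_bounds: tuple[float, float] = (0.01, 100.0)
    sigma_bounds: tuple[float, float] = (0.01, 10.0)
    seed: int = 0
    algorithm: str = "seqtlboga"
    # PSO / CS / DE constants
    pso_w: float = 0.4
    pso_c1: float = 1.4
    pso_c2: float = 1.4
    cs_alpha: float = 1.5  # Levy stability parameter
    cs_accept_alpha: float = 1.0  # acceptance-probability rate
    de_f: float = 0.5
    de_cr: float = 0.9

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        for lo, hi in (self.c_bounds, self.sigma_bounds):
            if not (0 < lo <= hi):
                raise ValueError("bounds must be positive and ordered")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def bounds(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return (self.c_bounds, self.sigma_bounds)


@dataclass
class RunRecord:
    """Outcome of one optimizer run."""

    algorithm: str
    best_learner: BinaryLearner
    best_fitness: float
    best_fitness_trace: np.ndarray
    final_metrics: MetricSet
    n_selected: int
    n_evaluations: int
    wall_seconds: float
    seed: int

    def to_dict(self) -> dict:
        m = self.final_metrics
        return {
            "algorithm": self.algorithm,
            "seed": self.seed,
            "best_fitness": self.best_fitness,
            "best_mask": [int(b) for b in self.best_learner.mask],
            "c_value": self.best_learner.c_value,
            "sigma_value": self.best_learner.sigma_value,
            "n_selected": self.n_selected,
            "n_evaluations": self.n_evaluations,
            "wall_seconds": self.wall_seconds,
            "best_fitness_trace": [float(v) for v in self.best_fitness_trace],
            "metrics": {
                "accuracy": m.accuracy,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "precision": m.precision,
                "f_score": m.f_score,
                "auc_balanced": m.auc_balanced,
                "fpr": m.fpr,
                "fnr": m.fnr,
            },
        }


def levy_sample(alpha: float, rng: np.random.Generator, lam: float = 1.0) -> float:
    """Heavy-tailed step by the Mantegna algorithm.

    ``l = lam * u / |v|**(1/alpha)`` with ``u ~ N(0, sigma_u^2)``,
    ``v ~ N(0, 1)`` and the standard closed-form ``sigma_u``.
    """
    if not (0 < alpha <= 2):
        raise ValueError("alpha must lie in (0, 2]")
    if alpha == 2.0:
        # the alpha = 2 stable law is Gaussian; the Mantegna sigma_u formula
        # degenerates there (sin(pi) = 0), so draw the limit directly
        return float(lam * rng.normal(0.0, math.sqrt(2.0)))
    num = _gamma_fn(1 + alpha) * math.sin(math.pi * alpha / 2)
    den = _gamma_fn((1 + alpha) / 2) * alpha * 2 ** ((alpha - 1) / 2)
    sigma_u = (num / den) ** (1 / alpha)
    u = rng.normal(0.0, sigma_u)
    v = rng.normal(0.0, 1.0)
    return float(lam * u / abs(v) ** (1 / alpha))


class _Evaluator:
    """Counting, caching fitness oracle.

    Every request counts toward the evaluation budget (budget parity is
    about issued evaluations, not SVM fits); repeated (mask, C, sigma)
    triples reuse the cached cross-validation result.  Rounding at 1e-6
    keys the cache.
    """

    def __init__(self, dataset: Dataset, k_folds: int, kernel: str, seed: int):
        self.dataset = dataset
        self.k_folds = k_folds
        self.kernel = kernel
        self.seed = seed
        self.n_evaluations = 0
        self._cache: dict = {}

    def __call__(self, learner: BinaryLearner) -> FitnessResult:
        self.n_evaluations += 1
        key = (
            learner.mask.tobytes(),
            round(learner.c_value, 6),
            round(learner.sigma_value, 6),
        )
        if key not in self._cache:
            self._cache[key] = evaluate_fitness(
                learner, self.dataset, self.k_folds, self.kernel, self.seed
            )
        return self._cache[key]


class _BestTracker:
    """Incumbent best with the (higher fitness, fewer features, earlier) order."""

    def __init__(self) -> None:
        self.learner: BinaryLearner | None = None
        self.result: FitnessResult | None = None

    def offer(self, learner: BinaryLearner, result: FitnessResult) -> None:
        if self.result is None:
            self.learner, self.result = learner, result
            return
        better = result.fitness > self.result.fitness or (
            result.fitness == self.result.fitness
            and learner.n_selected < self.learner.n_selected
        )
        if better:
            self.learner, self.result = learner, result

    @property
    def fitness(self) -> float:
        return self.result.fitness


def _log_bounds(config: OptimizerConfig) -> np.ndarray:
    (c_lo, c_hi), (s_lo, s_hi) = config.bounds
    return np.log(np.array([[c_lo, c_hi], [s_lo, s_hi]]))


def _finish(
    algorithm: str,
    best: _BestTracker,
    trace: list[float],
    evaluator: _Evaluator,
    seed: int,
    t0: float,
) -> RunRecord:
    return RunRecord(
        algorithm=algorithm,
        best_learner=best.learner,
        best_fitness=best.fitness,
        best_fitness_trace=np.asarray(trace, dtype=float),
        final_metrics=compute_metrics(best.result.confusion),
        n_selected=best.learner.n_selected,
        n_evaluations=evaluator.n_evaluations,
        wall_seconds=time.perf_counter() - t0,
        seed=seed,
    )


# --------------------------------------------------------------------------
# hybrid quantum TLBO/GA
# --------------------------------------------------------------------------


def run_seqtlboga(dataset: Dataset, config: OptimizerConfig) -> RunRecord:
    """Run the quantum self-adaptive TLBO/GA hybrid.

    Per iteration and per learner: rotate the qubits toward the teacher
    (XOR-guided directions), update the real (log C, log sigma) dimensions
    by the weighted teacher phase and the peer-learning phase, observe the
    rotated qubits, then apply self-adaptive crossover (gated per position
    by ``max(Pc, beta^2)``) and mutation (rate ``max(Pm, overlap-derived)``
    spread over the mask), evaluate once, and keep the better of old/new.
    Exactly ``population_size`` evaluations per iteration plus one
    initialization round.
    """
    t0 = time.perf_counter()
    rng = np.random.default_rng(config.seed)
    evaluator = _Evaluator(dataset, config.k_folds, config.kernel, config.seed)
    n = dataset.n_features
    pop_size = config.population_size
    policy = RotationPolicy(theta_step=config.theta_step)
    lb = _log_bounds(config)

    qubits = qpop.init_population(pop_size, n, config.bounds, rng)
    binaries = [qpop.observe(q, rng) for q in qubits]
    results = [evaluator(b) for b in binaries]
    fitnesses = np.array([r.fitness for r in results])

    best = _BestTracker()
    for b, r in zip(binaries, results):
        best.offer(b, r)

    trace: list[float] = []
    for it in range(1, config.max_iterations + 1):
        n_sel = np.array([b.n_selected for b in binaries])
        state = TLBOState(
            positions=np.array(
                [[math.log(b.c_value), math.log(b.sigma_value)] for b in binaries]
            ),
            fitnesses=fitnesses,
            bounds=lb,
            iteration=it,
            max_iterations=config.max_iterations,
            n_selected=n_sel,
        )
        teacher_idx = state.teacher_index
        teacher_bin = binaries[teacher_idx]
        teacher_q = qubits[teacher_idx]

        # real-dimension candidates from the two TLBO phases (unevaluated;
        # acceptance is folded into the single end-of-iteration evaluation)
        cand = tlbo.teacher_phase(state, config.tlbo, rng, fitness_fn=None)
        cand = tlbo.learner_phase(
            TLBOState(
                cand.positions,
                fitnesses,
                lb,
                iteration=it,
                max_iterations=config.max_iterations,
                n_selected=n_sel,
            ),
            rng,
            fitness_fn=None,
        )
        real_cands = cand.positions

        summary = FitnessSummary(
            f_max=float(fitnesses.max()),
            f_min=float(fitnesses.min()),
            f_avg=float(fitnesses.mean()),
            f_b=best.fitness,
        )
        pc_global = saga.adaptive_pc(summary, config.saga)
        pm_global = saga.adaptive_pm(summary, config.saga)

        for i in range(pop_size):
            # quantum movement toward the teacher
            dtheta = qpop.rotation_angles(
                binaries[i],
                teacher_bin,
                float(fitnesses[i]),
                float(fitnesses[teacher_idx]),
                policy,
            )
            qubits[i] = qpop.rotate(qubits[i], dtheta)

            c_value = float(np.exp(real_cands[i, 0]))
            s_value = float(np.exp(real_cands[i, 1]))
            observed = qpop.observe(
                qpop.QubitLearner(qubits[i].alpha, qubits[i].beta, c_value, s_value),
                rng,
            )

            # per-position crossover with the teacher mask, gated by
            # max(global Pc, amplitude-derived rate)
            mask = observed.mask.copy()
            gates = np.maximum(pc_global, qubits[i].beta ** 2)
            cross = (rng.random(n) < gates) & (rng.random(n) < 0.5)
            mask[cross] = teacher_bin.mask[cross]

            # mutation: blended rate spread over the mask length
            pm_i = max(pm_global, saga.quantum_pm(qpop.overlap(qubits[i], teacher_q)))
            candidate = saga.mutate(
                BinaryLearner(saga._repair(mask, observed.mask), c_value, s_value),
                pm_i / n,
                rng,
                real_sigma=0.1,
                bounds=config.bounds,
            )

            result = evaluator(candidate)
            if result.fitness >= fitnesses[i]:
                binaries[i] = candidate
                fitnesses[i] = result.fitness
                results[i] = result
                best.offer(candidate, result)
        trace.append(best.fitness)

    return _finish("seqtlboga", best, trace, evaluator, config.seed, t0)


# --------------------------------------------------------------------------
# baselines
# --------------------------------------------------------------------------


def _random_binary(
    n: int, config: OptimizerConfig, rng: np.random.Generator
) -> BinaryLearner:
    mask = (rng.random(n) < 0.5).astype(np.int8)
    if mask.sum() == 0:
        mask[int(rng.integers(0, n))] = 1
    (c_lo, c_hi), (s_lo, s_hi) = config.bounds
    c = float(np.exp(rng.uniform(math.log(c_lo), math.log(c_hi))))
    s = float(np.exp(rng.uniform(math.log(s_lo), math.log(s_hi))))
    return BinaryLearner(mask, c, s)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class _Transfer:
    """Continuous (n+2)-dimensional representation for PSO/CS/DE/GOA."""

    def __init__(self, n_features: int, config: OptimizerConfig):
        self.n = n_features
        self.lb_mask = -4.0
        self.ub_mask = 4.0
        self.log_bounds = _log_bounds(config)
        self.bounds = config.bounds

    @property
    def dim(self) -> int:
        return self.n + 2

    def lower(self) -> np.ndarray:
        return np.concatenate(
            [np.full(self.n, self.lb_mask), self.log_bounds[:, 0]]
        )

    def upper(self) -> np.ndarray:
        return np.concatenate(
            [np.full(self.n, self.ub_mask), self.log_bounds[:, 1]]
        )

    def random_position(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower(), self.upper())

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower(), self.upper())

    def decode(self, x: np.ndarray, rng: np.random.Generator) -> BinaryLearner:
        prob = _sigmoid(x[: self.n])
        mask = (rng.random(self.n) < prob).astype(np.int8)
        if mask.sum() == 0:
            mask[int(np.argmax(prob))] = 1
        c = float(np.exp(x[self.n]))
        s = float(np.exp(x[self.n + 1]))
        (c_lo, c_hi), (s_lo, s_hi) = self.bounds
        return BinaryLearner(mask, min(max(c, c_lo), c_hi), min(max(s, s_lo), s_hi))


def _run_ga(dataset: Dataset, config: OptimizerConfig) -> RunRecord:
    """Canonical GA wrapper: tournament selection, fixed-rate crossover and
    mutation, elitist replacement."""
    t0 = time.perf_counter()
    rng = np.random.default_rng(config.seed)
    evaluator = _Evaluator(dataset, config.k_folds, config.kernel, config.seed)
    n = dataset.n_features
    pop_size = config.population_size
    p = config.saga

    pop = [_random_binary(n, config, rng) for _ in range(pop_size)]
    results = [evaluator(b) for b in pop]
    fitnesses = np.array([r.fitness for r in results])
    best = _BestTracker()
    for b, r in zip(pop, results):
        best.offer(b, r)

    trace: list[float] = []
    for _ in range(config.max_iterations):
        parents = saga.select(pop, fitnesses, p.tournament_size, rng)
        offspring: list[BinaryLearner] = []
        for j in range(0, pop_size - 1, 2):
            a, b = saga.crossover(
                pop[parents[j]], pop[parents[j + 1]], p.base_pc, p.crossover_kind, rng
            )
            offspring.extend([a, b])
        if len(offspring) < pop_size:  # odd population
            offspring.append(pop[parents[-1]])
        offspring = [
            saga.mutate(o, p.base_pm / n, rng, bounds=config.bounds) for o in offspring
        ]
        results = [evaluator(o) for o in offspring]
        fit_new = np.array([r.fitness for r in results])
        # elitism: reinsert the incumbent best over the worst offspring
        if fit_new.max() < best.fitness:
            worst = int(np.argmin(fit_new))
            offspring[worst] = best.learner
            results[worst] = best.result
            fit_new[worst] = best.fitness
        pop, fitnesses = offspring, fit_new
        for o, r in zip(pop, results):
            best.offer(o, r)
        trace.append(best.fitness)

    return _finish("ga", best, trace, evaluator, config.seed, t0)


def _run_pso(dataset: Dataset, config: OptimizerConfig) -> RunRecord:
    t0 = time.perf_counter()
    rng = np.random.default_rng(config.seed)
    evaluator = _Evaluator(dataset, config.k_folds, config.kernel, config.seed)
    tr = _Transfer(dataset.n_features, config)
    pop_size = config.population_size

    pos = np.array([tr.random_position(rng) for _ in range(pop_size)])
    vel = np.zeros_like(pos)
    learners = [tr.decode(x, rng) for x in pos]
    results = [evaluator(b) for b in learners]
    fitnesses = np.array([r.fitness for r in results])
    pbest_pos, pbest_fit = pos.copy(), fitnesses.copy()
    gbest_idx = int(np.argmax(fitnesses))
    gbest_pos = pos[gbest_idx].copy()

    best = _BestTracker()
    for b, r in zip(learners, results):
        best.offer(b, r)

    trace: list[float] = []
    for _ in range(config.max_iterations):
        for i in range(pop_size):
            r1, r2 = rng.random(tr.dim), rng.random(tr.dim)
            vel[i] = (
                config.pso_w * vel[i]
                + config.pso_c1 * r1 * (pbest_pos[i] - pos[i])
                + config.pso_c2 * r2 * (gbest_pos - pos[i])
            )
            pos[i] = tr.clip(pos[i] + vel[i])
            learner = tr.decode(pos[i], rng)
            result = evaluator(learner)
            if result.fitness > pbest_fit[i]:
                pbest_fit[i] = result.fitness
                pbest_pos[i] = pos[i].copy()
            best.offer(learner, result)
        gbest_idx = int(np.argmax(pbest_fit))
        gbest_pos = pbest_pos[gbest_idx].copy()
        trace.append(best.fitness)

    return _finish("pso", best, trace, evaluator, config.seed, t0)


def _run_cs(dataset: Dataset, config: OptimizerConfig) -> RunRecord:
    t0 = time.perf_counter()
    rng = np.random.default_rng(config.seed)
    evaluator = _Evaluator(dataset, config.k_folds, config.kernel, config.seed)
    tr = _Transfer(dataset.n_features, config)
    pop_size = config.population_size

    nests = np.array([tr.random_position(rng) for _ in range(pop_size)])
    learners = [tr.decode(x, rng) for x in nests]
    results = [evaluator(b) for b in learners]
    fitnesses = np.array([r.fitness for r in results])
    best = _BestTracker()
    for b, r in zip(learners, results):
        best.offer(b, r)
    gbest = nests[int(np.argmax(fitnesses))].copy()

    trace: list[float] = []
    for _ in range(config.max_iterations):
        for i in range(pop_size):
            step = np.array(
                [levy_sample(config.cs_alpha, rng, lam=0.1) for _ in range(tr.dim)]
            )
            cuckoo = tr.clip(nests[i] + step * (nests[i] - gbest))
            learner = tr.decode(cuckoo, rng)
            result = evaluator(learner)
            # replace a random nest if strictly better, else probabilistic
            # acceptance Pa = exp(-alpha * fitness_cuckoo)
            j = int(rng.integers(0, pop_size))
            if result.fitness > fitnesses[j]:
                nests[j], fitnesses[j] = cuckoo, result.fitness
            elif rng.random() < math.exp(-config.cs_accept_alpha * result.fitness):
                nests[j], fitnesses[j] = cuckoo, result.fitness
            best.offer(learner, result)
        gbest = nests[int(np.argmax(fitnesses))].copy()
        trace.append(best.fitness)

    return _finish("cs", best, trace, evaluator, config.seed, t0)


def _run_de(dataset: Dataset, config: OptimizerConfig) -> RunRecord:
    """DE/rand/1/bin with F = 0.5, CR = 0.9."""
    t0 = time.perf_counter()
    rng = np.random.default_rng(config.seed)
    evaluator = _Evaluator(dataset, config.k_folds, config.kernel, config.seed)
    tr = _Transfer(dataset.n_features, config)
    pop_size = config.population_size

    pos = np.array([tr.random_position(rng) for _ in range(pop_size)])
    learners = [tr.decode(x, rng) for x in pos]
    results = [evaluator(b) for b in learners]
    fitnesses = np.array([r.fitness for r in results])
    best = _BestTracker()
    for b, r in zip(learners, results):
        best.offer(b, r)

    trace: list[float] = []
    for _ in range(config.max_iterations):
        for i in range(pop_size):
            choices = [k for k in range(pop_size) if k != i]
            a, b, c = rng.choice(choices, size=3, replace=False)
            mutant = pos[a] + config.de_f * (pos[b] - pos[c])
            cross = rng.random(tr.dim) < config.de_cr
            cross[rng.integers(0, tr.dim)] = True
            trial = tr.clip(np.where(cross, mutant, pos[i]))
            learner = tr.decode(trial, rng)
            result = evaluator(learner)
            if result.fitness >= fitnesses[i]:
                pos[i], fitnesses[i] = trial, result.fitness
            best.offer(learner, result)
        trace.append(best.fitness)

    return _finish("de", best, trace, evaluator, config.seed, t0)


def _run_goa(dataset: Dataset, config: OptimizerConfig) -> RunRecord:
    """Standard grasshopper update (general literature form; shipped as a
    clearly labeled out-of-source baseline)."""
    t0 = time.perf_counter()
    rng = np.random.default_rng(config.seed)
    evaluator = _Evaluator(dataset, config.k_folds, config.kernel, config.seed)
    tr = _Transfer(dataset.n_features, config)
    pop_size = config.population_size
    f_attr, l_attr = 0.5, 1.5
    c_max, c_min = 1.0, 4e-5

    pos = np.array([tr.random_position(rng) for _ in range(pop_size)])
    learners = [tr.decode(x, rng) for x in pos]
    results = [evaluator(b) for b in learners]
    fitnesses = np.array([r.fitness for r in results])
    best = _BestTracker()
    for b, r in zip(learners, results):
        best.offer(b, r)
    target = pos[int(np.argmax(fitnesses))].copy()

    lower, upper = tr.lower(), tr.upper()
    span = (upper - lower) / 2.0
    trace: list[float] = []
    for it in range(1, config.max_iterations + 1):
        c = c_max - it * (c_max - c_min) / config.max_iterations
        new_pos = pos.copy()
        for i in range(pop_size):
            social = np.zeros(tr.dim)
            for j in range(pop_size):
                if j == i:
                    continue
                diff = pos[j] - pos[i]
                dist = float(np.linalg.norm(diff))
                if dist < 1e-12:
                    continue
                s = f_attr * math.exp(-dist / l_attr) - math.exp(-dist)
                social += c * span * s * diff / dist
            new_pos[i] = tr.clip(c * social + target)
            learner = tr.decode(new_pos[i], rng)
            result = evaluator(learner)
            if result.fitness > fitnesses[i]:
                fitnesses[i] = result.fitness
            best.offer(learner, result)
        pos = new_pos
        target = pos[int(np.argmax(fitnesses))].copy()
        trace.append(best.fitness)

    return _finish("goa", best, trace, evaluator, config.seed, t0)


_BASELINES = {
    "ga": _run_ga,
    "pso": _run_pso,
    "cs": _run_cs,
    "de": _run_de,
    "goa": _run_goa,
}


def run_baseline(dataset: Dataset, config: OptimizerConfig) -> RunRecord:
    """Run one of the baseline optimizers named by ``config.algorithm``."""
    if config.algorithm not in _BASELINES:
        raise ValueError(f"unknown baseline algorithm {config.algorithm!r}")
    return _BASELINES[config.algorithm](dataset, config)


def run(dataset: Dataset, config: OptimizerConfig) -> RunRecord:
    """Dispatch on ``config.algorithm``."""
    if config.algorithm == "seqtlboga":
        return run_seqtlboga(dataset, config)
    return run_baseline(dataset, config)
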