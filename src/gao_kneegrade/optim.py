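"""Aquila Optimizer variants for bounded continuous minimisation.

Implements the classic Aquila Optimizer (AQO) — a population metaheuristic
whose four update rules mimic the hunting strategies of the Aquila eagle
(high soar, contour flight, low descent, walk-and-grab) — and the Gaussian
Aquila Optimizer (GAO), which augments AQO with a decaying, sign-randomised
momentum control factor in the middle search phases and a Gaussian mutation
of the incumbent best at the end of every generation.

Both optimizers are elitist: the global best position is tracked separately
and every candidate move is accepted greedily (only on fitness improvement),
so the best-fitness trace is monotonically non-increasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ObjectiveSpec",
    "GAOConfig",
    "Candidate",
    "OptimizationResult",
    "initialize_population",
    "mean_position",
    "momentum_control_factor",
    "levy_flight",
    "spiral_shape",
    "expanded_exploration",
    "narrowed_exploration",
    "improved_narrowed_exploration",
    "expanded_exploitation",
    "improved_expanded_exploitation",
    "narrowed_exploitation",
    "gaussian_mutation",
    "GaussianAquilaOptimizer",
    "ClassicAquilaOptimizer",
    "gao_optimize",
    "classic_aqo_optimize",
    "BENCHMARKS",
    "benchmark_objective",
]


# ---------------------------------------------------------------------------
# problem / configuration containers


@dataclass
class ObjectiveSpec:
    """A bounded continuous minimisation problem.

    Parameters
    ----------
    evaluate : callable
        Maps a position vector of length ``dim`` to a finite scalar fitness
        (lower is better).
    dim : int
        Number of decision variables.
    lower_bound, upper_bound : array-like
        Elementwise box bounds, ``lower_bound < upper_bound``.
    """

    evaluate: Callable[[np.ndarray], float]
    dim: int
    lower_bound: np.ndarray
    upper_bound: np.ndarray

    def __post_init__(self) -> None:
        self.lower_bound = np.asarray(self.lower_bound, dtype=float)
        self.upper_bound = np.asarray(self.upper_bound, dtype=float)
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.lower_bound.shape != (self.dim,) or self.upper_bound.shape != (self.dim,):
            raise ValueError("bounds must be vectors of length dim")
        if not (np.isfinite(self.lower_bound).all() and np.isfinite(self.upper_bound).all()):
            raise ValueError("bounds must be finite")
        if np.any(self.lower_bound > self.upper_bound):
            raise ValueError("lower_bound must be <= upper_bound elementwise")

    def clamp(self, position: np.ndarray) -> np.ndarray:
        return np.clip(position, self.lower_bound, self.upper_bound)

    def fitness(self, position: np.ndarray) -> float:
        value = float(self.evaluate(position))
        if not math.isfinite(value):
            raise ValueError(
                f"objective returned non-finite fitness {value!r} at position {position!r}"
            )
        return value


@dataclass
class GAOConfig:
    """Optimizer settings shared by AQO and GAO.

    ``position_constant`` (M0) scales the momentum control factor; ``lam``
    and ``mu`` are the exploitation tuning factors; the Levy-flight step uses
    the constants ``levy_r`` and ``levy_alpha`` with tail exponent
    ``levy_beta``.  The run terminates when the best fitness improves by less
    than ``convergence_tol`` over ``convergence_window`` consecutive
    generations, or after ``max_iterations`` generations.
    """

    population_size: int = 60
    position_constant: float = 1.2
    lam: float = 0.1
    mu: float = 0.1
    levy_beta: float = 1.5
    levy_r: float = 0.1
    levy_alpha: float = 0.5
    convergence_tol: float = 1e-6
    convergence_window: int = 20
    max_iterations: int = 500
    exploration_fraction: float = 2.0 / 3.0
    mutate_all: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.position_constant <= 0:
            raise ValueError("position_constant must be > 0")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if not 0.0 < self.exploration_fraction < 1.0:
            raise ValueError("exploration_fraction must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class Candidate:
    position: np.ndarray
    fitness: float

    def copy(self) -> "Candidate":
        return Candidate(self.position.copy(), self.fitness)


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    generations_elapsed: int
    fitness_trace: np.ndarray
    terminated_by: str  # "converged" | "max_iterations"


# ---------------------------------------------------------------------------
# primitive update rules


def initialize_population(
    objective: ObjectiveSpec, config: GAOConfig, rng: np.random.Generator
) -> list[Candidate]:
    """Uniformly sample ``population_size`` candidates inside the bounds."""
    span = objective.upper_bound - objective.lower_bound
    positions = objective.lower_bound + rng.random((config.population_size, objective.dim)) * span
    return [Candidate(p, objective.fitness(p)) for p in positions]


def mean_position(population: Sequence[Candidate]) -> np.ndarray:
    """Arithmetic mean position S_A of the population."""
    if len(population) == 0:
        raise ValueError("population is empty")
    return np.mean([c.position for c in population], axis=0)


def momentum_control_factor(
    j: int, J: int, M0: float, rng: np.random.Generator
) -> float:
    """MCF(j) = M0 * exp(1 - j/J) * N_s with N_s = +1 w.p. 0.6 else -1.

    |MCF| decays from M0*e at j=0 to M0 at j=J, shrinking step sizes as the
    search matures; the random sign keeps the perturbation direction-free.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    if not 0 <= j <= J:
        raise ValueError("j must satisfy 0 <= j <= J")
    sign = 1.0 if rng.random() < 0.6 else -1.0
    return M0 * math.exp(1.0 - j / J) * sign


def levy_flight(dim: int, config: GAOConfig, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed Levy step vector, r*(l*beta)/|x|^(1/alpha) per component.

    ``l`` and ``x`` are fresh uniform(0,1) draws per component; the raw
    expression is non-negative, so each component's sign is symmetrised with
    probability 0.5.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    l = rng.random(dim)
    x = rng.random(dim)
    x = np.where(x == 0.0, np.finfo(float).tiny, x)
    step = config.levy_r * (l * config.levy_beta) / np.abs(x) ** (1.0 / config.levy_alpha)
    signs = np.where(rng.random(dim) < 0.5, 1.0, -1.0)
    return step * signs


def spiral_shape(l: float, phi: float) -> tuple[float, float]:
    """Spiral search coordinates a = l*sin(phi), b = l*cos(phi)."""
    return l * math.sin(phi), l * math.cos(phi)


def _quality(j: int, rng: np.random.Generator) -> float:
    # quality function j^((2r-1)/(1-j)^2); the j=1 singularity is resolved by
    # the limit convention quality(1) = 1
    if j <= 1:
        return 1.0
    return float(j) ** ((2.0 * rng.random() - 1.0) / (1.0 - j) ** 2)


def expanded_exploration(
    best: np.ndarray,
    mean_pos: np.ndarray,
    j: int,
    J: int,
    objective: ObjectiveSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """High soar with vertical stoop: S1 = S_best*(1-j/J) + (S_A - S_best*rand)."""
    rand = rng.random()
    new = best * (1.0 - j / J) + (mean_pos - best * rand)
    return objective.clamp(new)


def narrowed_exploration(
    best: np.ndarray,
    random_candidate: np.ndarray,
    config: GAOConfig,
    objective: ObjectiveSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Contour flight with short glide (classic): S2 = S_best*levy + (S_rd + (a-b)*rand)."""
    levy = levy_flight(objective.dim, config, rng)
    a, b = spiral_shape(rng.random(), rng.random() * 2.0 * math.pi)
    rand = rng.random()
    new = best * levy + (random_candidate + (a - b) * rand)
    return objective.clamp(new)


def improved_narrowed_exploration(
    best: np.ndarray,
    present: np.ndarray,
    random_candidate: np.ndarray,
    mcf: float,
    config: GAOConfig,
    objective: ObjectiveSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """GAO contour flight: S2n = (S_best - S_present)*MCF + (S_rd + (a-b)*rand)."""
    a, b = spiral_shape(rng.random(), rng.random() * 2.0 * math.pi)
    rand = rng.random()
    new = (best - present) * mcf + (random_candidate + (a - b) * rand)
    return objective.clamp(new)


def expanded_exploitation(
    best: np.ndarray,
    mean_pos: np.ndarray,
    config: GAOConfig,
    objective: ObjectiveSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Low flight with slow descent (classic).

    S3 = (S_best * S_A) * (lam - rand) + ((UB - LB)*rand + LB) * mu, with one
    shared rand draw per expression instance.
    """
    rand = rng.random()
    span = objective.upper_bound - objective.lower_bound
    new = (best * mean_pos) * (config.lam - rand) + (
        span * rand + objective.lower_bound
    ) * config.mu
    return objective.clamp(new)


def improved_expanded_exploitation(
    best: np.ndarray,
    present: np.ndarray,
    mean_pos: np.ndarray,
    mcf: float,
    j: int,
    J: int,
    config: GAOConfig,
    objective: ObjectiveSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """GAO plunge-and-encircle.

    S3n = ((S_best - S_present) * S_A * MCF * (1 - j/J)) * (lam - rand)
          + ((UB - LB)*rand + LB) * mu,
    products elementwise, one shared rand draw.
    """
    rand = rng.random()
    span = objective.upper_bound - objective.lower_bound
    new = ((best - present) * mean_pos * mcf * (1.0 - j / J)) * (config.lam - rand) + (
        span * rand + objective.lower_bound
    ) * config.mu
    return objective.clamp(new)


def narrowed_exploitation(
    best: np.ndarray,
    current: np.ndarray,
    j: int,
    J: int,
    config: GAOConfig,
    objective: ObjectiveSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Walk-and-grab attack.

    S4 = quality(j)*S_best - (H1*S*rand) - (H2*levy + rand*H2), with
    H1 = 2*rand' - 1 (own draw), H2 = 2*(1 - j/J), and one rand shared
    between the second and third terms.
    """
    eps = _quality(j, rng)
    h1 = 2.0 * rng.random() - 1.0
    h2 = 2.0 * (1.0 - j / J)
    rand = rng.random()
    levy = levy_flight(objective.dim, config, rng)
    new = eps * best - (h1 * current * rand) - (h2 * levy + rand * h2)
    return objective.clamp(new)


def gaussian_mutation(
    position: np.ndarray, objective: ObjectiveSpec | None = None
) -> np.ndarray:
    """Elementwise mutation S * (1 + exp(-S^2)).

    The mutation factor lies in (1, 2]: it doubles coordinates near zero and
    vanishes (factor -> 1) for large coordinates, nudging near-origin
    components out of local traps while leaving converged large-magnitude
    components alone.
    """
    mutated = position * (1.0 + np.exp(-(position**2)))
    if objective is not None:
        mutated = objective.clamp(mutated)
    return mutated


# ---------------------------------------------------------------------------
# generational loops


class _AquilaBase:
    """Shared generational loop; subclasses pick the four update rules."""

    use_mcf = False
    use_mutation = False

    def __init__(self, config: GAOConfig | None = None, **overrides):
        if config is None:
            config = GAOConfig(**overrides)
        elif overrides:
            raise TypeError("pass either a GAOConfig or keyword overrides, not both")
        self.config = config

    # sklearn-style param plumbing so the optimizer composes with grid tools
    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params) -> "_AquilaBase":
        if "config" in params:
            self.config = params.pop("config")
        if params:
            raise ValueError(f"unknown parameters: {sorted(params)}")
        return self

    def _explore(self, i, pop, best, mean_pos, mcf, j, J, objective, rng):
        raise NotImplementedError

    def _exploit(self, i, pop, best, mean_pos, mcf, j, J, objective, rng):
        raise NotImplementedError

    def optimize(
        self,
        objective: ObjectiveSpec,
        seed_positions: Sequence[np.ndarray] | None = None,
    ) -> OptimizationResult:
        """Run the generational loop on ``objective``.

        ``seed_positions`` optionally replaces the first candidates of the
        random initial population (e.g. an incumbent solution to refine);
        elitism then guarantees the result is never worse than the best
        seed.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        J = cfg.max_iterations
        pop = initialize_population(objective, cfg, rng)
        if seed_positions is not None:
            if len(seed_positions) > len(pop):
                raise ValueError("more seed positions than population slots")
            for i, pos in enumerate(seed_positions):
                p = objective.clamp(np.asarray(pos, dtype=float))
                pop[i] = Candidate(p, objective.fitness(p))
        best = min(pop, key=lambda c: c.fitness).copy()
        trace: list[float] = []
        explore_until = cfg.exploration_fraction * J
        terminated_by = "max_iterations"
        generations = 0

        for j in range(1, J + 1):
            mean_pos = mean_position(pop)
            mcf = (
                momentum_control_factor(j, J, cfg.position_constant, rng)
                if self.use_mcf
                else 0.0
            )
            for i in range(cfg.population_size):
                if j <= explore_until:
                    new = self._explore(i, pop, best, mean_pos, mcf, j, J, objective, rng)
                else:
                    new = self._exploit(i, pop, best, mean_pos, mcf, j, J, objective, rng)
                f = objective.fitness(new)
                if f < pop[i].fitness:
                    pop[i] = Candidate(new, f)
                if f < best.fitness:
                    best = Candidate(new.copy(), f)
            if self.use_mutation:
                targets = pop if cfg.mutate_all else [best]
                for cand in targets:
                    mutated = gaussian_mutation(cand.position, objective)
                    fm = objective.fitness(mutated)
                    if fm < cand.fitness:
                        cand.position = mutated
                        cand.fitness = fm
                    if fm < best.fitness:
                        best = Candidate(mutated.copy(), fm)
            trace.append(best.fitness)
            generations = j
            # The stall window only arms once the exploitation phase has run
            # for a full window: exploration phases plateau by design under
            # greedy acceptance, and a plateau there is not convergence.
            if (
                j >= explore_until + cfg.convergence_window
                and trace[-cfg.convergence_window] - trace[-1] < cfg.convergence_tol
            ):
                terminated_by = "converged"
                break

        return OptimizationResult(
            best_position=best.position.copy(),
            best_fitness=best.fitness,
            generations_elapsed=generations,
            fitness_trace=np.asarray(trace),
            terminated_by=terminated_by,
        )


class GaussianAquilaOptimizer(_AquilaBase):
    """Aquila Optimizer with momentum control factor and Gaussian mutation."""

    use_mcf = True
    use_mutation = True

    def _explore(self, i, pop, best, mean_pos, mcf, j, J, objective, rng):
        if rng.random() < 0.5:
            return expanded_exploration(best.position, mean_pos, j, J, objective, rng)
        rd = pop[rng.integers(len(pop))].position
        return improved_narrowed_exploration(
            best.position, pop[i].position, rd, mcf, self.config, objective, rng
        )

    def _exploit(self, i, pop, best, mean_pos, mcf, j, J, objective, rng):
        if rng.random() < 0.5:
            return improved_expanded_exploitation(
                best.position, pop[i].position, mean_pos, mcf, j, J, self.config, objective, rng
            )
        return narrowed_exploitation(
            best.position, pop[i].position, j, J, self.config, objective, rng
        )


class ClassicAquilaOptimizer(_AquilaBase):
    """The unmodified four-rule Aquila Optimizer baseline."""

    use_mcf = False
    use_mutation = False

    def _explore(self, i, pop, best, mean_pos, mcf, j, J, objective, rng):
        if rng.random() < 0.5:
            return expanded_exploration(best.position, mean_pos, j, J, objective, rng)
        rd = pop[rng.integers(len(pop))].position
        return narrowed_exploration(best.position, rd, self.config, objective, rng)

    def _exploit(self, i, pop, best, mean_pos, mcf, j, J, objective, rng):
        if rng.random() < 0.5:
            return expanded_exploitation(
                best.position, mean_pos, self.config, objective, rng
            )
        return narrowed_exploitation(
            best.position, pop[i].position, j, J, self.config, objective, rng
        )


def gao_optimize(objective: ObjectiveSpec, config: GAOConfig | None = None) -> OptimizationResult:
    """Run the Gaussian Aquila Optimizer on ``objective``."""
    return GaussianAquilaOptimizer(config).optimize(objective)


def classic_aqo_optimize(
    objective: ObjectiveSpec, config: GAOConfig | None = None
) -> OptimizationResult:
    """Run the classic Aquila Optimizer on ``objective``."""
    return ClassicAquilaOptimizer(config).optimize(objective)


# ---------------------------------------------------------------------------
# analytic benchmark functions


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(x * x))


def _rosenbrock(x: np.ndarray) -> float:
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def _rastrigin(x: np.ndarray) -> float:
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * math.pi * x)))


BENCHMARKS: dict[str, dict] = {
    "sphere": {"fn": _sphere, "bounds": (-10.0, 10.0)},
    "rosenbrock": {"fn": _rosenbrock, "bounds": (-5.0, 10.0)},
    "rastrigin": {"fn": _rastrigin, "bounds": (-5.12, 5.12)},
}


def benchmark_objective(name: str, dim: int) -> ObjectiveSpec:
    """Build an ObjectiveSpec for a named analytic benchmark."""
    try:
        entry = BENCHMARKS[name]
    except KeyError:
        raise ValueError(f"unknown benchmark {name!r}; choose from {sorted(BENCHMARKS)}")
    lo, hi = entry["bounds"]
    return ObjectiveSpec(
        evaluate=entry["fn"],
        dim=dim,
        lower_bound=np.full(dim, lo),
        upper_bound=np.full(dim, hi),
    )
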