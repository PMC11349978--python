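"""Unit and property tests for the Aquila optimizer variants."""

import math

import numpy as np
import pytest

from gao_kneegrade.optim import (
    BENCHMARKS,
    Candidate,
    ClassicAquilaOptimizer,
    GAOConfig,
    GaussianAquilaOptimizer,
    ObjectiveSpec,
    benchmark_objective,
    classic_aqo_optimize,
    expanded_exploration,
    gao_optimize,
    gaussian_mutation,
    improved_expanded_exploitation,
    improved_narrowed_exploration,
    initialize_population,
    levy_flight,
    mean_position,
    momentum_control_factor,
    narrowed_exploitation,
    spiral_shape,
)


class ScriptedRng:
    """Feeds a fixed sequence of uniform draws to pin stochastic formulas."""

    def __init__(self, values):
        self.values = list(values)

    def random(self, size=None):
        if size is None:
            return self.values.pop(0)
        return np.array([self.values.pop(0) for _ in range(int(np.prod(size)))]).reshape(size)

    def integers(self, *a, **k):  # pragma: no cover - not used in scripted paths
        raise AssertionError("unexpected integer draw")


def _objective(dim=1, lb=-10.0, ub=10.0):
    return ObjectiveSpec(
        evaluate=lambda x: float(np.sum(x**2)),
        dim=dim,
        lower_bound=np.full(dim, lb),
        upper_bound=np.full(dim, ub),
    )


# ---------------------------------------------------------------------------
# initialisation and bookkeeping


def test_degenerate_interval_population_collapses_to_bound():
    obj = ObjectiveSpec(lambda x: 0.0, 1, np.array([0.0]), np.array([0.0]))
    pop = initialize_population(obj, GAOConfig(seed=1), np.random.default_rng(1))
    assert all(c.position[0] == 0.0 for c in pop)


def test_population_is_reproducible_for_a_seed():
    obj = _objective(dim=2)
    cfg = GAOConfig(seed=7)
    p1 = initialize_population(obj, cfg, np.random.default_rng(7))
    p2 = initialize_population(obj, cfg, np.random.default_rng(7))
    assert all((a.position == b.position).all() for a, b in zip(p1, p2))


def test_uniform_sampler_mean_matches_law_of_large_numbers():
    obj = _objective(dim=3, lb=-5.0, ub=5.0)
    pop = initialize_population(
        obj, GAOConfig(population_size=10000, seed=0), np.random.default_rng(0)
    )
    positions = np.array([c.position for c in pop])
    assert np.abs(positions.mean(axis=0)).max() < 0.2


def test_non_finite_bounds_are_rejected():
    with pytest.raises(ValueError):
        ObjectiveSpec(lambda x: 0.0, 1, np.array([np.nan]), np.array([1.0]))


def test_mean_position_matches_direct_summation(rng):
    pop = [Candidate(rng.random(4), 0.0) for _ in range(60)]
    brute = sum(c.position for c in pop) / 60
    assert np.abs(mean_position(pop) - brute).max() < 1e-12
    assert (mean_position([pop[0]]) == pop[0].position).all()
    with pytest.raises(ValueError):
        mean_position([])


# ---------------------------------------------------------------------------
# closed-form update-rule oracles


def test_momentum_control_factor_closed_forms():
    # exp(0) = 1 at the final generation; exp(1) = e at generation zero
    assert abs(momentum_control_factor(10, 10, 1.2, ScriptedRng([0.1]))) == pytest.approx(1.2)
    assert abs(momentum_control_factor(0, 10, 1.2, ScriptedRng([0.9]))) == pytest.approx(
        1.2 * math.e, abs=1e-5
    )
    with pytest.raises(ValueError):
        momentum_control_factor(0, 0, 1.2, ScriptedRng([0.5]))


def test_momentum_magnitude_strictly_decreases_in_generation():
    mags = [abs(momentum_control_factor(j, 100, 1.2, ScriptedRng([0.0]))) for j in range(101)]
    assert all(a > b for a, b in zip(mags, mags[1:]))


def test_momentum_sign_is_bernoulli_point_six():
    rng = np.random.default_rng(5)
    draws = [momentum_control_factor(1, 2, 1.0, rng) > 0 for _ in range(10000)]
    assert abs(np.mean(draws) - 0.6) < 0.02


def test_levy_flight_substitution_oracle():
    # l=0.5, x=0.25, sign draw 0.9 (negative branch avoided by <0.5 rule)
    cfg = GAOConfig()
    value = levy_flight(1, cfg, ScriptedRng([0.5, 0.25, 0.4]))
    # 0.1 * (0.5*1.5) / 0.25^(1/0.5) = 0.075 / 0.0625 = 1.2, positive sign
    assert value[0] == pytest.approx(1.2)


def test_levy_flight_reproducible_and_heavy_tailed():
    cfg = GAOConfig()
    v1 = levy_flight(8, cfg, np.random.default_rng(3))
    v2 = levy_flight(8, cfg, np.random.default_rng(3))
    assert (v1 == v2).all()
    sample = np.abs(levy_flight(100000, cfg, np.random.default_rng(4)))
    assert sample.max() > 100 * np.median(sample)


def test_spiral_shape_trivial_points_and_radius_identity(rng):
    assert spiral_shape(1.0, 0.0) == pytest.approx((0.0, 1.0))
    assert spiral_shape(2.0, math.pi / 2) == pytest.approx((2.0, 0.0), abs=1e-12)
    for _ in range(50):
        l, phi = rng.random() * 5, rng.random() * 2 * math.pi
        a, b = spiral_shape(l, phi)
        assert a * a + b * b == pytest.approx(l * l)


def test_expanded_exploration_scalar_oracles():
    obj = _objective()
    best, mean = np.array([2.0]), np.array([0.5])
    # j = J with rand = 0: only the mean survives
    out = expanded_exploration(best, mean, 10, 10, obj, ScriptedRng([0.0]))
    assert out[0] == pytest.approx(0.5)
    # zeros stay zeros
    z = np.zeros(1)
    assert expanded_exploration(z, z, 3, 10, obj, ScriptedRng([0.7]))[0] == 0.0
    # j = 0 with rand = 0.5: best + mean - 0.5*best
    out = expanded_exploration(best, mean, 0, 10, obj, ScriptedRng([0.5]))
    assert out[0] == pytest.approx(2.0 + 0.5 - 0.5 * 2.0)


def test_improved_narrowed_exploration_scalar_oracle():
    obj = _objective()
    cfg = GAOConfig()
    rd = np.array([0.3])
    # best == present: the difference term vanishes
    x = np.array([1.5])
    out = improved_narrowed_exploration(x, x, rd, 2.0, cfg, obj, ScriptedRng([0.5, 0.0, 0.25]))
    a, b = spiral_shape(0.5, 0.0)
    assert out[0] == pytest.approx(rd[0] + (a - b) * 0.25)
    # mcf = 0 makes the result independent of best/present
    o1 = improved_narrowed_exploration(
        np.array([9.0]), np.array([-9.0]), rd, 0.0, cfg, obj, ScriptedRng([0.5, 0.1, 0.25])
    )
    o2 = improved_narrowed_exploration(
        np.array([1.0]), np.array([2.0]), rd, 0.0, cfg, obj, ScriptedRng([0.5, 0.1, 0.25])
    )
    assert o1[0] == pytest.approx(o2[0])
    # full scalar substitution
    best, present = np.array([2.0]), np.array([0.5])
    out = improved_narrowed_exploration(best, present, rd, 1.7, cfg, obj, ScriptedRng([0.4, 0.2, 0.6]))
    a, b = spiral_shape(0.4, 0.2 * 2 * math.pi)
    assert out[0] == pytest.approx((2.0 - 0.5) * 1.7 + (0.3 + (a - b) * 0.6))


def test_improved_expanded_exploitation_scalar_oracles():
    cfg = GAOConfig()
    obj = ObjectiveSpec(lambda x: float(x[0] ** 2), 1, np.array([0.0]), np.array([1.0]))
    # j = J: the first term vanishes; rand = 1, mu = 0.1 -> ((1-0)*1+0)*0.1
    out = improved_expanded_exploitation(
        np.array([0.7]), np.array([0.7]), np.array([0.2]), 1.3, 10, 10, cfg, obj, ScriptedRng([1.0])
    )
    assert out[0] == pytest.approx(0.1)
    # full substitution at j = 5, J = 10
    best, present, mean = np.array([0.8]), np.array([0.1]), np.array([0.4])
    out = improved_expanded_exploitation(best, present, mean, 1.5, 5, 10, cfg, obj, ScriptedRng([0.3]))
    expected = ((0.8 - 0.1) * 0.4 * 1.5 * 0.5) * (0.1 - 0.3) + (1.0 * 0.3 + 0.0) * 0.1
    assert out[0] == pytest.approx(np.clip(expected, 0, 1))


def test_narrowed_exploitation_scalar_oracles():
    cfg = GAOConfig()
    obj = _objective()
    best, cur = np.array([1.0]), np.array([0.4])
    # j = J: H2 = 0 kills the third term; draws: quality, H1, shared rand, levy(l, x, sign)
    out = narrowed_exploitation(best, cur, 10, 10, cfg, obj,
                                ScriptedRng([0.5, 0.75, 0.2, 0.5, 0.5, 0.1]))
    eps = 10.0 ** ((2 * 0.5 - 1) / (1 - 10) ** 2)
    assert out[0] == pytest.approx(eps * 1.0 - (2 * 0.75 - 1) * 0.4 * 0.2)
    # H1 rand = 0.5 makes H1 = 0 and the second term vanish
    out = narrowed_exploitation(best, cur, 5, 10, cfg, obj,
                                ScriptedRng([0.5, 0.5, 0.3, 0.5, 0.5, 0.9]))
    eps = 5.0 ** ((2 * 0.5 - 1) / (1 - 5) ** 2)
    h2 = 2 * (1 - 0.5)
    levy = -(0.1 * (0.5 * 1.5) / 0.5**2)  # sign draw 0.9 -> negative
    assert out[0] == pytest.approx(eps * 1.0 - (h2 * levy + 0.3 * h2))


def test_quality_function_is_defined_at_generation_one():
    cfg = GAOConfig()
    obj = _objective()
    out = narrowed_exploitation(
        np.array([1.0]), np.array([1.0]), 1, 10, cfg, obj,
        ScriptedRng([0.9, 0.5, 0.0, 0.5, 0.5, 0.1]),
    )
    assert np.isfinite(out).all()


def test_gaussian_mutation_closed_forms():
    assert gaussian_mutation(np.zeros(3)).max() == 0.0
    assert gaussian_mutation(np.array([1.0]))[0] == pytest.approx(1.0 + math.exp(-1.0), abs=1e-5)
    # mutation factor lies in (1, 2] and tends to 1 for large coordinates
    s = np.linspace(-5, 5, 1001)
    s = s[s != 0]
    factor = gaussian_mutation(s) / s
    assert (factor > 1.0).all() and (factor <= 2.0).all()
    assert gaussian_mutation(np.array([50.0]))[0] == pytest.approx(50.0, abs=1e-6)


# ---------------------------------------------------------------------------
# full optimizer runs


def test_gao_reaches_sphere_optimum():
    obj = benchmark_objective("sphere", 5)
    result = gao_optimize(obj, GAOConfig(seed=1))
    assert result.best_fitness < 1e-6


def test_constant_objective_terminates_by_convergence():
    obj = ObjectiveSpec(lambda x: 3.0, 2, np.full(2, -1.0), np.full(2, 1.0))
    result = gao_optimize(obj, GAOConfig(seed=2, max_iterations=60, convergence_window=10))
    assert result.best_fitness == 3.0
    assert result.terminated_by == "converged"


def test_classic_aqo_reaches_sphere_optimum():
    obj = benchmark_objective("sphere", 5)
    result = classic_aqo_optimize(obj, GAOConfig(seed=1))
    assert result.best_fitness < 1e-3


@pytest.mark.parametrize("runner", [gao_optimize, classic_aqo_optimize])
def test_runs_are_bit_reproducible(runner):
    obj = benchmark_objective("rosenbrock", 2)
    cfg = GAOConfig(seed=11, max_iterations=50, convergence_window=50)
    r1, r2 = runner(obj, cfg), runner(obj, cfg)
    assert (r1.best_position == r2.best_position).all()
    assert (r1.fitness_trace == r2.fitness_trace).all()


@pytest.mark.parametrize("cls", [GaussianAquilaOptimizer, ClassicAquilaOptimizer])
def test_elitism_and_bound_feasibility(cls):
    evaluated = []

    def f(x):
        evaluated.append(x.copy())
        return float(np.sum(x**2))

    obj = ObjectiveSpec(f, 3, np.full(3, -2.0), np.full(3, 2.0))
    result = cls(GAOConfig(seed=3, max_iterations=40, convergence_window=40)).optimize(obj)
    trace = result.fitness_trace
    assert (np.diff(trace) <= 0).all()
    assert len(trace) == result.generations_elapsed
    pts = np.array(evaluated)
    assert (pts >= -2.0).all() and (pts <= 2.0).all()


def test_non_finite_fitness_raises_with_position():
    obj = ObjectiveSpec(lambda x: float("nan"), 1, np.array([-1.0]), np.array([1.0]))
    with pytest.raises(ValueError, match="non-finite"):
        gao_optimize(obj, GAOConfig(seed=0, max_iterations=5))


def test_seed_positions_guarantee_elitist_floor():
    obj = benchmark_objective("sphere", 4)
    incumbent = np.full(4, 1e-8)
    result = GaussianAquilaOptimizer(
        GAOConfig(seed=9, max_iterations=10, convergence_window=10)
    ).optimize(obj, seed_positions=[incumbent])
    assert result.best_fitness <= float(np.sum(incumbent**2))


def test_gao_solves_separable_linear_classification():
    # a separating hyperplane exists; GAO must drive the error to zero
    rng = np.random.default_rng(0)
    X = np.concatenate([rng.normal(-2, 0.5, (20, 2)), rng.normal(2, 0.5, (20, 2))])
    y = np.array([0] * 20 + [1] * 20)

    def err(w):
        pred = (X @ w[:2] + w[2] > 0).astype(int)
        return float((pred != y).mean())

    obj = ObjectiveSpec(err, 3, np.full(3, -5.0), np.full(3, 5.0))
    result = gao_optimize(obj, GAOConfig(seed=1, max_iterations=100, convergence_window=100))
    assert result.best_fitness == 0.0


def test_benchmark_registry_rejects_unknown_names():
    assert set(BENCHMARKS) == {"sphere", "rosenbrock", "rastrigin"}
    with pytest.raises(ValueError):
        benchmark_objective("ackley", 2)
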