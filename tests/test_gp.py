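"""GP engine: evaluation oracle, operator closure, selection, evolution."""

from dataclasses import replace

import numpy as np
import pytest

from rpgp.exceptions import EvaluationError
from rpgp.gp import (
    DESK_PROFILE,
    FUNCTIONS,
    GPConfig,
    Population,
    classify,
    eval_tree,
    evolve,
    init_population,
    parse_sexpr,
    random_tree,
    subtree_crossover,
    subtree_mutate,
    to_sexpr,
    tournament_select,
    tree_depth,
    tree_size,
)


def random_program(gen, k, max_depth):
    method = "full" if gen.random() < 0.5 else "grow"
    return random_tree(gen, k, max_depth, method)


def naive_eval(tree, x):
    """Independent scalar evaluator used as the oracle.

    Implements the same documented conventions (protected division; final
    output NaN -> 0, +/-inf -> +/-1e300) with plain Python recursion over
    one sample at a time.
    """
    def rec(node):
        if isinstance(node, int):
            return float(x[node])
        op, left, right = node
        a, b = rec(left), rec(right)
        if op == "add":
            return a + b
        if op == "sub":
            return a - b
        if op == "mul":
            return a * b
        if op == "div":
            return 1.0 if abs(b) < 1e-9 else a / b
        raise AssertionError(op)

    with np.errstate(all="ignore"):
        v = rec(tree)
    if np.isnan(v):
        return 0.0
    if np.isinf(v):
        return 1e300 if v > 0 else -1e300
    return float(v)


class TestEvalTree:
    def test_addition(self):
        assert eval_tree(("add", 0, 1), np.array([2.0, 3.0])) == 5.0

    def test_protected_division_by_zero_is_one(self):
        assert eval_tree(("div", 0, 1), np.array([4.0, 0.0])) == 1.0

    def test_protected_division_near_zero(self):
        assert eval_tree(("div", 0, 1), np.array([4.0, 5e-10])) == 1.0

    def test_ordinary_division(self):
        assert eval_tree(("div", 0, 1), np.array([6.0, 3.0])) == 2.0

    def test_vectorized_matches_per_sample(self, rng):
        tree = ("mul", ("sub", 0, 2), ("div", 1, 0))
        X = rng.normal(size=(20, 3))
        out = eval_tree(tree, X)
        for i in range(20):
            assert out[i] == pytest.approx(eval_tree(tree, X[i]), abs=1e-15)

    def test_index_out_of_range(self):
        with pytest.raises(EvaluationError):
            eval_tree(("add", 0, 5), np.array([1.0, 2.0]))

    def test_matches_naive_oracle_on_random_trees(self):
        gen = np.random.default_rng(99)
        for _ in range(200):
            k = int(gen.integers(1, 8))
            tree = random_program(gen, k, 5)
            for _ in range(5):
                x = gen.normal(size=k) * 10
                assert eval_tree(tree, x) == pytest.approx(
                    naive_eval(tree, x), abs=1e-12, rel=1e-12
                )

    def test_output_always_finite_under_overflow(self):
        # x0^(2^depth) overflows float64 for |x0| large
        tree = 0
        for _ in range(8):
            tree = ("mul", tree, tree)
        v = eval_tree(tree, np.array([1e30, 0.0]))
        assert np.isfinite(v)


class TestClassify:
    def test_positive_margin(self):
        assert classify(("sub", 0, 1), np.array([5.0, 1.0])) == 1

    def test_negative_margin(self):
        assert classify(("sub", 0, 1), np.array([1.0, 5.0])) == 0

    def test_zero_output_is_positive_class(self):
        # boundary inclusive: output >= 0 -> 1
        assert classify(("sub", 0, 0), np.array([3.0, 1.0])) == 1


class TestInitPopulation:
    def test_depths_within_ramp(self):
        cfg = GPConfig(population_size=210, seed=5)
        pop = init_population(cfg, k=10)
        depths = [tree_depth(t) for t in pop.individuals]
        assert min(depths) >= 2 and max(depths) <= 8

    def test_deterministic(self):
        cfg = GPConfig(population_size=64, seed=6)
        a = init_population(cfg, k=5)
        b = init_population(cfg, k=5)
        assert a.individuals == b.individuals

    def test_ramp_levels_uniform(self):
        """Individuals are spread over the 7 ramp levels within rounding."""
        cfg = GPConfig(population_size=1024, seed=7)
        pop = init_population(cfg, k=10)
        levels = list(range(2, 9))
        # reconstruct assignment: individual i gets level i % 7
        per_level = {lv: 0 for lv in levels}
        for i in range(cfg.population_size):
            per_level[levels[i % 7]] += 1
        counts = np.array(list(per_level.values()))
        assert counts.max() - counts.min() <= 1
        # 'full' trees at level lv actually reach depth lv
        full_trees = [pop.individuals[i] for i in range(0, 14, 7)]
        assert tree_depth(full_trees[0]) == 2

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GPConfig(crossover_prob=0.9, mutation_prob=0.2)
        with pytest.raises(ValueError):
            GPConfig(init_depth_min=5, init_depth_max=3)
        with pytest.raises(ValueError):
            GPConfig(init_depth_max=10, max_depth=8)


class TestTournament:
    def test_single_strong_individual_selected_at_closed_form_rate(self):
        """One individual of fitness 1 among n of fitness 0 is selected with
        probability 1 - (1 - 1/n)^size (sampling with replacement)."""
        gen = np.random.default_rng(21)
        n, size, draws = 40, 7, 10_000
        pop = Population(
            individuals=list(range(n)),
            fitnesses=np.array([1.0] + [0.0] * (n - 1)),
        )
        hits = sum(
            tournament_select(pop, size, gen) == 0 for _ in range(draws)
        )
        p = 1 - (1 - 1 / n) ** size
        se = np.sqrt(p * (1 - p) / draws)
        assert abs(hits / draws - p) < 3 * se

    def test_size_one_is_uniform(self):
        """Tournament of size 1 ignores fitness: chi-square goodness of fit."""
        gen = np.random.default_rng(22)
        n, draws = 10, 10_000
        pop = Population(
            individuals=list(range(n)), fitnesses=np.linspace(0, 1, n)
        )
        counts = np.zeros(n)
        for _ in range(draws):
            counts[tournament_select(pop, 1, gen)] += 1
        expected = draws / n
        chi2 = ((counts - expected) ** 2 / expected).sum()
        from scipy.stats import chi2 as chi2_dist
        assert chi2 < chi2_dist.ppf(0.999, df=n - 1)

    def test_equal_fitness_ties_spread_uniformly(self):
        gen = np.random.default_rng(23)
        n = 5
        pop = Population(individuals=list(range(n)), fitnesses=np.ones(n))
        counts = np.zeros(n)
        for _ in range(5000):
            counts[tournament_select(pop, 3, gen)] += 1
        assert counts.min() > 0.8 * counts.max()

    def test_empty_population_rejected(self):
        pop = Population(individuals=[], fitnesses=np.array([]))
        with pytest.raises(ValueError):
            tournament_select(pop, 3, np.random.default_rng(0))


class TestOperators:
    def test_crossover_of_terminals_yields_terminal(self):
        gen = np.random.default_rng(31)
        child = subtree_crossover(3, 7, gen, max_depth=8)
        assert child in (3, 7)

    def test_crossover_respects_depth_cap(self):
        gen = np.random.default_rng(32)
        for _ in range(2000):
            a = random_program(gen, 5, 8)
            b = random_program(gen, 5, 8)
            child = subtree_crossover(a, b, gen, max_depth=8)
            assert tree_depth(child) <= 8

    def test_crossover_node_count_bound(self):
        gen = np.random.default_rng(33)
        for _ in range(200):
            a = random_program(gen, 5, 6)
            b = random_program(gen, 5, 6)
            child = subtree_crossover(a, b, gen, max_depth=12)
            assert tree_size(child) <= tree_size(a) - 1 + tree_size(b)

    def test_mutation_respects_depth_cap(self):
        gen = np.random.default_rng(34)
        for _ in range(2000):
            a = random_program(gen, 5, 8)
            child = subtree_mutate(a, gen, k=5, max_depth=8)
            assert tree_depth(child) <= 8

    def test_mutation_of_terminal_is_fresh_tree(self):
        gen = np.random.default_rng(35)
        out = {tree_depth(subtree_mutate(2, gen, k=4, max_depth=8))
               for _ in range(100)}
        assert max(out) <= 8
        assert len(out) > 1  # sometimes deeper than a terminal

    def test_operators_produce_valid_trees(self):
        """Closure: every node is a known function or in-range terminal."""
        def valid(t, k):
            if isinstance(t, int):
                return 0 <= t < k
            op, l, r = t
            return op in FUNCTIONS and valid(l, k) and valid(r, k)

        gen = np.random.default_rng(36)
        for _ in range(500):
            a = random_program(gen, 6, 8)
            b = random_program(gen, 6, 8)
            assert valid(subtree_crossover(a, b, gen, 8), 6)
            assert valid(subtree_mutate(a, gen, 6, 8), 6)


class TestEvolve:
    def test_trace_is_non_decreasing(self, separable_dataset):
        X, y = separable_dataset
        cfg = GPConfig(population_size=64, max_generations=15, seed=1)
        res = evolve(X, y, cfg)
        assert all(b >= a for a, b in zip(res.trace, res.trace[1:]))
        assert len(res.trace) == cfg.max_generations + 1

    def test_deterministic_under_fixed_seed(self, separable_dataset):
        X, y = separable_dataset
        cfg = GPConfig(population_size=64, max_generations=10, seed=42)
        r1 = evolve(X, y, cfg)
        r2 = evolve(X, y, cfg)
        assert r1.best_tree == r2.best_tree
        assert r1.trace == r2.trace

    def test_recovers_planted_separable_rule(self, separable_dataset):
        """class = [x0 - x1 >= 0] is exactly expressible; evolution should
        reach fitness 1.0 within 50 generations in >= 9/10 seeded runs."""
        X, y = separable_dataset
        hits = 0
        for seed in range(10):
            cfg = GPConfig(population_size=256, max_generations=50, seed=seed)
            res = evolve(X, y, cfg)
            hits += res.best_fitness == 1.0
        assert hits >= 9

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="single class"):
            evolve(X, np.ones(10, dtype=int), GPConfig(population_size=16))

    def test_best_fitness_matches_tree(self, separable_dataset):
        """The reported fitness is reproducible from the reported tree."""
        from rpgp.metrics import confusion, mcc, standardized_fitness

        X, y = separable_dataset
        res = evolve(X, y, replace(DESK_PROFILE, max_generations=5, seed=3))
        preds = classify(res.best_tree, X)
        refit = standardized_fitness(mcc(confusion(preds, y)))
        assert refit == pytest.approx(res.best_fitness, abs=1e-15)


def test_trace_tsv_round_trips(tmp_path, separable_dataset):
    from rpgp.gp import write_trace

    X, y = separable_dataset
    res = evolve(X, y, GPConfig(population_size=32, max_generations=6, seed=2))
    path = tmp_path / "trace.tsv"
    write_trace(res, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "generation\tbest_fitness"
    assert len(lines) == len(res.trace) + 1
    back = [float(l.split("\t")[1]) for l in lines[1:]]
    assert back == res.trace


class TestSexpr:
    def test_round_trip(self):
        gen = np.random.default_rng(44)
        for _ in range(100):
            t = random_program(gen, 20, 6)
            assert parse_sexpr(to_sexpr(t)) == t

    def test_example_format(self):
        t = ("div", ("add", 3, 17), ("sub", 4, 9))
        assert to_sexpr(t) == "(div (add x3 x17) (sub x4 x9))"
        assert parse_sexpr("(div (add x3 x17) (sub x4 x9))") == t

    @pytest.mark.parametrize("bad", ["(foo x1 x2)", "(add x1", "x1 x2", "(add x1 x2 x3)"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_sexpr(bad)
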