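"""Tree-based genetic-programming binary classifier.

A program is an arithmetic expression tree: internal nodes are drawn from
the function set ``{+, -, x, ÷}`` (all binary), leaves are feature indices
into the current feature space. A program classifies a sample by
evaluating the expression on its feature values and thresholding at zero
(output >= 0 -> positive class).

Trees are represented as immutable nested tuples::

    terminal         ->  int feature index
    function node    ->  (symbol, left, right),  symbol in FUNCTIONS

Immutability makes genetic operators cheap (structural sharing instead of
deep copies) and lets fitness be memoised by tree identity.

Evolution follows the classical generational scheme: ramped half-and-half
initialization, tournament selection, subtree crossover/mutation applied
as an exclusive per-offspring choice, elitism, fixed generation count.
Fitness is the standardized MCC of the program's predictions on the
training data. All randomness flows from a single seeded generator, so a
run is fully reproducible from its configuration.

Closure conventions (documented because both the evaluator and any
independent re-implementation must share them):

* protected division: ``a ÷ b = 1`` whenever ``|b| < 1e-9``;
* non-finite intermediates arising from overflow propagate through the
  tree unchanged; the final program output is forced finite by mapping
  NaN -> 0 and ±inf -> ±1e300.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .exceptions import EvaluationError
from .metrics import confusion, mcc, standardized_fitness

__all__ = [
    "FUNCTIONS",
    "DIV_EPS",
    "GPConfig",
    "DESK_PROFILE",
    "Population",
    "EvolutionResult",
    "eval_tree",
    "classify",
    "tree_depth",
    "tree_size",
    "random_tree",
    "init_population",
    "tournament_select",
    "subtree_crossover",
    "subtree_mutate",
    "evolve",
    "write_trace",
    "to_sexpr",
    "parse_sexpr",
]

FUNCTIONS = ("add", "sub", "mul", "div")

DIV_EPS = 1e-9
_BIG = 1e300


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPConfig:
    """Run configuration for the evolutionary loop.

    Defaults follow the standard setup for this classifier: population
    1024, tournament size 7, crossover/mutation probabilities 0.8/0.2
    (exclusive per-offspring choice; the remainder is reproduction),
    ramped half-and-half initialization over depths 2-8 with a hard depth
    cap of 8, single-individual elitism.
    """

    population_size: int = 1024
    tournament_size: int = 7
    crossover_prob: float = 0.8
    mutation_prob: float = 0.2
    init_depth_min: int = 2
    init_depth_max: int = 8
    max_depth: int = 8
    elites: int = 1
    max_generations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crossover_prob < 0 or self.mutation_prob < 0:
            raise ValueError("operator probabilities must be non-negative")
        if self.crossover_prob + self.mutation_prob > 1.0 + 1e-12:
            raise ValueError(
                "crossover_prob + mutation_prob must be <= 1 "
                "(the remainder is reproduction)"
            )
        for name in (
            "population_size",
            "tournament_size",
            "init_depth_min",
            "init_depth_max",
            "max_depth",
            "max_generations",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.elites < 0:
            raise ValueError("elites must be non-negative")
        if self.elites >= self.population_size:
            raise ValueError("elites must be smaller than the population")
        if not (self.init_depth_min <= self.init_depth_max <= self.max_depth):
            raise ValueError(
                "need init_depth_min <= init_depth_max <= max_depth"
            )


#: Reduced-budget profile for desk-scale experiments and tests.
DESK_PROFILE = GPConfig(population_size=256, max_generations=30)


# ---------------------------------------------------------------------------
# tree structure and evaluation
# ---------------------------------------------------------------------------

def is_terminal(tree) -> bool:
    return not isinstance(tree, tuple)


def tree_depth(tree) -> int:
    """Depth of the tree; a single terminal has depth 0."""
    if is_terminal(tree):
        return 0
    return 1 + max(tree_depth(tree[1]), tree_depth(tree[2]))


def tree_size(tree) -> int:
    """Total node count (internal + leaves)."""
    if is_terminal(tree):
        return 1
    return 1 + tree_size(tree[1]) + tree_size(tree[2])


def _finite(v):
    return np.nan_to_num(v, nan=0.0, posinf=_BIG, neginf=-_BIG)


def _eval_node(node, x, k, cache=None):
    """Recursive evaluator; ``cache`` memoises subtree outputs by identity
    (immutable tuples make structurally shared subtrees hashable)."""
    if is_terminal(node):
        idx = int(node)
        if not 0 <= idx < k:
            raise EvaluationError(
                f"terminal feature index {idx} out of range for k={k}"
            )
        return x[..., idx]
    if cache is not None:
        hit = cache.get(node)
        if hit is not None:
            return hit
    op, left, right = node
    a = _eval_node(left, x, k, cache)
    b = _eval_node(right, x, k, cache)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        if op == "add":
            out = a + b
        elif op == "sub":
            out = a - b
        elif op == "mul":
            out = a * b
        elif op == "div":
            unsafe = np.abs(b) < DIV_EPS
            out = np.where(unsafe, 1.0, a / np.where(unsafe, 1.0, b))
        else:  # pragma: no cover - trees are built from FUNCTIONS only
            raise EvaluationError(f"unknown function symbol {op!r}")
    if cache is not None:
        cache[node] = out
    return out


def eval_tree(tree, x):
    """Evaluate a program on feature values.

    ``x`` may be a single length-k vector (returns a float) or an
    ``(n, k)`` array (returns a length-n array); evaluation is vectorized
    over samples. Division is protected, and the program output is forced
    finite (NaN from overflowing subexpressions maps to 0, ±inf to ±1e300).
    """
    x = np.asarray(x, dtype=float)
    k = x.shape[-1]
    result = _finite(_eval_node(tree, x, k))
    if x.ndim == 1:
        return float(result)
    return np.asarray(result, dtype=float)


def classify(tree, x):
    """Binary decision: program output >= 0 maps to class 1, else 0."""
    out = eval_tree(tree, x)
    return np.asarray(np.asarray(out) >= 0.0, dtype=int) if np.ndim(out) else int(out >= 0.0)


# ---------------------------------------------------------------------------
# random tree generation
# ---------------------------------------------------------------------------

def _grow(rng, depth_budget: int, k: int, p_function: float = 0.5):
    """'Grow' construction: internal node with probability p_function until
    the depth budget is exhausted."""
    if depth_budget <= 0 or rng.random() >= p_function:
        return int(rng.integers(k))
    op = FUNCTIONS[rng.integers(len(FUNCTIONS))]
    return (op, _grow(rng, depth_budget - 1, k), _grow(rng, depth_budget - 1, k))


def _full(rng, depth: int, k: int):
    """'Full' construction: every leaf sits at exactly ``depth``."""
    if depth <= 0:
        return int(rng.integers(k))
    op = FUNCTIONS[rng.integers(len(FUNCTIONS))]
    return (op, _full(rng, depth - 1, k), _full(rng, depth - 1, k))


def random_tree(rng, k: int, max_depth: int, method: str = "grow",
                min_depth: int = 0, max_tries: int = 50):
    """Generate one random tree of depth <= max_depth (and >= min_depth).

    ``method`` is ``"grow"`` or ``"full"``. If grow cannot reach
    ``min_depth`` within ``max_tries`` attempts the full method is used as
    a fallback, which always attains the requested depth.
    """
    if k < 1:
        raise ValueError("need at least one feature")
    if method == "full":
        return _full(rng, max_depth, k)
    if method != "grow":
        raise ValueError(f"unknown construction method {method!r}")
    for _ in range(max_tries):
        t = _grow(rng, max_depth, k)
        if tree_depth(t) >= min_depth:
            return t
    return _full(rng, max_depth, k)


# ---------------------------------------------------------------------------
# population containers
# ---------------------------------------------------------------------------

@dataclass
class Population:
    """Individuals with cached fitness values for one generation."""

    individuals: list
    fitnesses: np.ndarray
    generation: int = 0
    best_tree: object = None
    best_fitness: float = -np.inf

    @property
    def size(self) -> int:
        return len(self.individuals)


@dataclass
class EvolutionResult:
    """Best-ever program of a run plus the per-generation fitness trace."""

    best_tree: object
    best_fitness: float
    trace: list = field(default_factory=list)
    generations: int = 0

    @property
    def sexpr(self) -> str:
        return to_sexpr(self.best_tree)


def init_population(cfg: GPConfig, k: int, rng=None) -> Population:
    """Ramped half-and-half initialization.

    Ramp depths cycle uniformly over ``[init_depth_min, init_depth_max]``;
    within each depth level individuals alternate between the full and the
    grow method. Fitness values are initialized to NaN (unevaluated).
    """
    if k < 1:
        raise ValueError("need at least one feature")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    levels = list(range(cfg.init_depth_min, cfg.init_depth_max + 1))
    individuals = []
    for i in range(cfg.population_size):
        depth = levels[i % len(levels)]
        method = "full" if (i // len(levels)) % 2 == 0 else "grow"
        individuals.append(
            random_tree(rng, k, depth, method, min_depth=cfg.init_depth_min)
        )
    return Population(
        individuals=individuals,
        fitnesses=np.full(cfg.population_size, np.nan),
    )


# ---------------------------------------------------------------------------
# genetic operators
# ---------------------------------------------------------------------------

def _positions(tree, path=(), level=0):
    """Preorder list of (path, subtree, level) for every node."""
    out = [(path, tree, level)]
    if not is_terminal(tree):
        out.extend(_positions(tree[1], path + (1,), level + 1))
        out.extend(_positions(tree[2], path + (2,), level + 1))
    return out


def _replace_at(tree, path, new):
    if not path:
        return new
    op, left, right = tree
    if path[0] == 1:
        return (op, _replace_at(left, path[1:], new), right)
    return (op, left, _replace_at(right, path[1:], new))


def tournament_select(pop: Population, size: int, rng) -> int:
    """Index of the fittest among ``size`` uniform draws (with replacement).

    Ties are broken uniformly at random among the drawn maxima.
    """
    n = pop.size
    if n == 0:
        raise ValueError("cannot select from an empty population")
    if size < 1:
        raise ValueError("tournament size must be positive")
    contenders = rng.integers(0, n, size=size)
    fits = pop.fitnesses[contenders]
    best = fits.max()
    winners = contenders[fits == best]
    return int(winners[rng.integers(winners.size)])


def subtree_crossover(a, b, rng, max_depth: int = 8, max_retries: int = 10):
    """Replace a uniformly chosen node of ``a`` by a uniformly chosen
    subtree of ``b``; children exceeding ``max_depth`` are rejected and the
    choice retried, falling back to (a copy of) ``a``."""
    pos_b = _positions(b)
    pos_a = _positions(a)
    for _ in range(max_retries):
        path, _, _ = pos_a[rng.integers(len(pos_a))]
        _, donor, _ = pos_b[rng.integers(len(pos_b))]
        child = _replace_at(a, path, donor)
        if tree_depth(child) <= max_depth:
            return child
    return a  # trees are immutable; a is its own copy


def subtree_mutate(a, rng, k: int, max_depth: int = 8):
    """Replace a uniformly chosen node by a freshly grown random subtree
    whose depth budget respects the overall ``max_depth`` cap."""
    pos = _positions(a)
    path, _, level = pos[rng.integers(len(pos))]
    budget = max_depth - level
    fresh = _grow(rng, budget, k)
    return _replace_at(a, path, fresh)


# ---------------------------------------------------------------------------
# evolutionary loop
# ---------------------------------------------------------------------------

def _fitness_of(tree, X, y, cache, eval_cache=None):
    fit = cache.get(tree)
    if fit is None:
        out = _finite(_eval_node(tree, X, X.shape[1], eval_cache))
        preds = np.asarray(out >= 0.0, dtype=int)
        fit = standardized_fitness(mcc(confusion(preds, y)))
        cache[tree] = fit
    return fit


def _elite_order(fitnesses: np.ndarray, rng) -> np.ndarray:
    """Indices sorted by decreasing fitness, ties shuffled uniformly."""
    jitter = rng.random(fitnesses.size)
    return np.lexsort((jitter, -fitnesses))


def evolve(train_X, train_y, cfg: GPConfig) -> EvolutionResult:
    """Run the generational GP loop on training data.

    Parameters
    ----------
    train_X
        ``(n_samples, k)`` feature array (samples in rows).
    train_y
        Length-n 0/1 label vector; both classes must be present.
    cfg
        :class:`GPConfig`; ``cfg.seed`` drives all randomness.

    Returns
    -------
    EvolutionResult
        Best-ever program, its standardized-MCC training fitness, and the
        best-fitness trace (one entry for the initial population plus one
        per generational update; non-decreasing by elitism).
    """
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y, dtype=int)
    if X.ndim != 2:
        raise ValueError("train_X must be 2-D (samples x features)")
    if y.shape[0] != X.shape[0]:
        raise ValueError("train_X and train_y disagree on sample count")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError(
            "training data contains a single class; MCC fitness is degenerate"
        )
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class in training data")
    k = X.shape[1]

    rng = np.random.default_rng(cfg.seed)
    cache: dict = {}

    pop = init_population(cfg, k, rng)
    # subtree outputs are memoised per generation: crossover offspring share
    # large subtrees, so structural sharing pays for the dict lookups
    eval_cache: dict = {}
    pop.fitnesses = np.array(
        [_fitness_of(t, X, y, cache, eval_cache) for t in pop.individuals]
    )

    best_idx = int(_elite_order(pop.fitnesses, rng)[0])
    best_tree = pop.individuals[best_idx]
    best_fit = float(pop.fitnesses[best_idx])
    trace = [best_fit]

    cx_hi = cfg.crossover_prob
    mut_hi = cfg.crossover_prob + cfg.mutation_prob

    for gen in range(1, cfg.max_generations + 1):
        order = _elite_order(pop.fitnesses, rng)
        offspring = [pop.individuals[i] for i in order[: cfg.elites]]
        while len(offspring) < cfg.population_size:
            r = rng.random()
            if r < cx_hi:
                pa = pop.individuals[tournament_select(pop, cfg.tournament_size, rng)]
                pb = pop.individuals[tournament_select(pop, cfg.tournament_size, rng)]
                child = subtree_crossover(pa, pb, rng, cfg.max_depth)
            elif r < mut_hi:
                pa = pop.individuals[tournament_select(pop, cfg.tournament_size, rng)]
                child = subtree_mutate(pa, rng, k, cfg.max_depth)
            else:
                child = pop.individuals[tournament_select(pop, cfg.tournament_size, rng)]
            offspring.append(child)
        if len(eval_cache) > 100_000:
            eval_cache.clear()
        pop = Population(
            individuals=offspring,
            fitnesses=np.array(
                [_fitness_of(t, X, y, cache, eval_cache) for t in offspring]
            ),
            generation=gen,
        )
        gen_best = int(_elite_order(pop.fitnesses, rng)[0])
        if pop.fitnesses[gen_best] > best_fit:
            best_fit = float(pop.fitnesses[gen_best])
            best_tree = pop.individuals[gen_best]
        trace.append(best_fit)

    return EvolutionResult(
        best_tree=best_tree,
        best_fitness=best_fit,
        trace=trace,
        generations=cfg.max_generations,
    )


def write_trace(result: EvolutionResult, path) -> None:
    """Write the best-fitness trace as two-column TSV (generation, best_fitness)."""
    with open(path, "w") as fh:
        fh.write("generation\tbest_fitness\n")
        for gen, fit in enumerate(result.trace):
            fh.write(f"{gen}\t{fit:.17g}\n")


# ---------------------------------------------------------------------------
# S-expression serialization
# ---------------------------------------------------------------------------

def to_sexpr(tree) -> str:
    """Serialize a program as e.g. ``(div (add x3 x17) (sub x4 x9))``."""
    if is_terminal(tree):
        return f"x{int(tree)}"
    op, left, right = tree
    return f"({op} {to_sexpr(left)} {to_sexpr(right)})"


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_sexpr(text: str):
    """Parse the S-expression format written by :func:`to_sexpr`."""
    tokens = _TOKEN.findall(text)
    pos = 0

    def parse():
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError(f"unexpected end of S-expression: {text!r}")
        tok = tokens[pos]
        pos += 1
        if tok == "(":
            op = tokens[pos]
            pos += 1
            if op not in FUNCTIONS:
                raise ValueError(f"unknown function symbol {op!r}")
            left = parse()
            right = parse()
            if pos >= len(tokens) or tokens[pos] != ")":
                raise ValueError(f"missing ')' in {text!r}")
            pos += 1
            return (op, left, right)
        if tok == ")":
            raise ValueError(f"unexpected ')' in {text!r}")
        m = re.fullmatch(r"x(\d+)", tok)
        if not m:
            raise ValueError(f"bad terminal token {tok!r}")
        return int(m.group(1))

    tree = parse()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in {text!r}")
    return tree
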