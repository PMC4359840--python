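"""Genetic-algorithm search for a near-minimal reduct of a decision table.

Chromosomes are bit vectors over the condition attributes ("1" = selected);
positions belonging to the core are pinned to 1 for the whole run, since the
search starts from the core.  Fitness rewards both parsimony and preserved
classification power:

    F(x) = beta * (1 - card(x)/card(C)) + |POS_x(D)| / |POS_C(D)|

with the second term defined as 1 on degenerate tables where the full
condition set has an empty positive region.  beta (default 0.5) keeps the
dependency term dominant, so gamma-preservation is never traded away for a
shorter chromosome unless the loss is tiny.

The loop is: dependency of the full set -> core (early exit when the core
already preserves gamma) -> random core-pinned initialisation -> repeated
tournament selection, one-point crossover, single-gene mutation and elitism,
stopping at a generation cap or when the best fitness has been flat for a
stagnation window.  Elitism copies the top fraction of each generation
unaltered, so the best-fitness trajectory is non-decreasing and every run is
reproducible from its seed.

``GARoughSetSelector`` exposes the search as an sklearn feature selector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted, column_or_1d

from .roughsets import _pos_count
from .table import DecisionTable, table_from_arrays

__all__ = [
    "GAError",
    "Chromosome",
    "GAConfig",
    "ReductResult",
    "fitness",
    "tournament_select",
    "one_point_crossover",
    "uniform_crossover",
    "mutate",
    "run_ga",
    "GARoughSetSelector",
]


class GAError(ValueError):
    pass


@dataclass
class Chromosome:
    """Fixed-length bit vector over condition attributes; fitness is cached."""

    bits: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)

    @property
    def card(self) -> int:
        return int(self.bits.sum())

    def copy(self) -> "Chromosome":
        return Chromosome(self.bits.copy(), self.fitness)


@dataclass
class GAConfig:
    population_size: int = 1000
    max_generations: int = 500
    crossover_prob: float = 0.5
    mutation_prob: float = 0.03
    elite_fraction: float = 0.2
    beta: float = 0.5
    tournament_size: int = 2
    stagnation_window: int = 50
    crossover: str = "one_point"  # or "uniform"
    seed: int | None = None

    def validate(self) -> None:
        for name in ("crossover_prob", "mutation_prob", "elite_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GAError(f"{name} must be in [0, 1], got {v}")
        for name in ("population_size", "max_generations", "tournament_size",
                     "stagnation_window"):
            v = getattr(self, name)
            if int(v) < 1:
                raise GAError(f"{name} must be >= 1, got {v}")
        if self.beta < 0:
            raise GAError(f"beta must be >= 0, got {self.beta}")
        if self.crossover not in ("one_point", "uniform"):
            raise GAError(f"unknown crossover mode {self.crossover!r}")


@dataclass
class ReductResult:
    selected: tuple[str, ...]
    fitness: float
    gamma_selected: float
    gamma_full: float
    generations_run: int
    history: list[float] = field(default_factory=list)
    core: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# genetic operators (spec surface; the loop uses the same routines)
# ---------------------------------------------------------------------------

def fitness(chrom: Chromosome, table: DecisionTable, beta: float = 0.5) -> float:
    """F(x) = beta*(1 - card(x)/card(C)) + |POS_x(D)|/|POS_C(D)|."""
    bits = np.asarray(chrom.bits, dtype=np.uint8)
    conds = table.condition_attributes
    if len(bits) != len(conds):
        raise GAError(
            f"chromosome length {len(bits)} != number of condition "
            f"attributes {len(conds)}"
        )
    if bits.sum() == 0:
        raise GAError("all-zero chromosome has no attributes to condition on")
    codes, cards, ycodes, k = table.encoded()
    pos_full = _pos_count(codes, cards, ycodes, k, list(range(len(conds))))
    pos_x = _pos_count(codes, cards, ycodes, k, list(np.flatnonzero(bits)))
    p = 1.0 if pos_full == 0 else pos_x / pos_full
    return beta * (1.0 - bits.sum() / len(bits)) + p


def _better(a: Chromosome, b: Chromosome) -> bool:
    """True when a strictly beats b: higher fitness, then fewer attributes."""
    return (a.fitness, -a.card) > (b.fitness, -b.card)


def tournament_select(
    population: Sequence[Chromosome], rng: np.random.Generator, k: int = 2
) -> Chromosome:
    """Winner of a size-k uniform draw (with replacement); highest fitness
    wins, ties broken by fewer selected attributes then lower index."""
    if not population:
        raise GAError("empty population")
    idx = rng.integers(0, len(population), size=k)
    best = None
    for i in sorted(int(i) for i in idx):
        c = population[i]
        if best is None or _better(c, best):
            best = c
    return best


def _pin_core(bits: np.ndarray, core_mask: np.ndarray | None) -> np.ndarray:
    if core_mask is not None:
        bits[core_mask] = 1
    return bits


def one_point_crossover(
    parent1: Chromosome,
    parent2: Chromosome,
    rng: np.random.Generator,
    core_mask: np.ndarray | None = None,
) -> tuple[Chromosome, Chromosome]:
    """Swap tails at a uniform cut point in 1..len-1; core bits re-pinned."""
    b1, b2 = parent1.bits, parent2.bits
    if len(b1) != len(b2):
        raise GAError("parent length mismatch")
    n = len(b1)
    if n < 2:
        return parent1.copy(), parent2.copy()
    cut = int(rng.integers(1, n))
    c1 = np.concatenate([b1[:cut], b2[cut:]])
    c2 = np.concatenate([b2[:cut], b1[cut:]])
    return (
        Chromosome(_pin_core(c1, core_mask)),
        Chromosome(_pin_core(c2, core_mask)),
    )


def uniform_crossover(
    parent1: Chromosome,
    parent2: Chromosome,
    rng: np.random.Generator,
    core_mask: np.ndarray | None = None,
) -> tuple[Chromosome, Chromosome]:
    """Per-gene fair-coin exchange; core bits re-pinned."""
    b1, b2 = parent1.bits, parent2.bits
    if len(b1) != len(b2):
        raise GAError("parent length mismatch")
    swap = rng.integers(0, 2, size=len(b1)).astype(bool)
    c1 = np.where(swap, b2, b1)
    c2 = np.where(swap, b1, b2)
    return (
        Chromosome(_pin_core(c1.copy(), core_mask)),
        Chromosome(_pin_core(c2.copy(), core_mask)),
    )


def mutate(
    chrom: Chromosome,
    mutation_prob: float,
    rng: np.random.Generator,
    core_mask: np.ndarray | None = None,
) -> Chromosome:
    """With probability P_m flip one uniformly chosen non-core gene."""
    out = Chromosome(chrom.bits.copy())
    if rng.random() >= mutation_prob:
        out.fitness = chrom.fitness
        return out
    if core_mask is None:
        free = np.arange(len(out.bits))
    else:
        free = np.flatnonzero(~core_mask)
    if free.size == 0:
        out.fitness = chrom.fitness
        return out
    j = int(free[rng.integers(0, free.size)])
    out.bits[j] ^= 1
    return out


# ---------------------------------------------------------------------------
# the full search
# ---------------------------------------------------------------------------

def run_ga(table: DecisionTable, config: GAConfig | None = None) -> ReductResult:
    """Run the GA reduct search on a decision table (steps: full-set
    dependency, core + early exit, init, select/crossover/mutate/elite loop,
    stagnation or generation-cap stop, decode best)."""
    config = config or GAConfig()
    config.validate()
    conds = table.condition_attributes
    m = len(conds)
    codes, cards, ycodes, kc = table.encoded()
    n = table.n_objects
    all_cols = list(range(m))
    pos_full = _pos_count(codes, cards, ycodes, kc, all_cols)
    gamma_full = pos_full / n
    if pos_full == 0:
        warnings.warn(
            "full condition set has empty positive region (gamma_C = 0); "
            "attribute selection is driven by parsimony only",
            stacklevel=2,
        )

    def pos_of(bits: np.ndarray) -> int:
        return _pos_count(codes, cards, ycodes, kc, list(np.flatnonzero(bits)))

    cache: dict[bytes, float] = {}

    def fit_of(bits: np.ndarray) -> float:
        key = bits.tobytes()
        got = cache.get(key)
        if got is None:
            card = int(bits.sum())
            p = 1.0 if pos_full == 0 else pos_of(bits) / pos_full
            got = config.beta * (1.0 - card / m) + p
            cache[key] = got
        return got

    # core by single-removal test
    core_idx = [
        j for j in all_cols
        if _pos_count(codes, cards, ycodes, kc, [c for c in all_cols if c != j])
        != pos_full
    ]
    core_mask = np.zeros(m, dtype=bool)
    core_mask[core_idx] = True
    core_names = tuple(conds[j] for j in core_idx)

    pos_core = _pos_count(codes, cards, ycodes, kc, core_idx)
    if pos_core == pos_full:
        # the core alone is already a minimal reduction
        bits = core_mask.astype(np.uint8)
        card = int(bits.sum())
        p = 1.0 if pos_full == 0 else pos_core / pos_full
        return ReductResult(
            selected=core_names,
            fitness=config.beta * (1.0 - card / m) + p,
            gamma_selected=pos_core / n,
            gamma_full=gamma_full,
            generations_run=0,
            history=[],
            core=core_names,
        )

    rng = np.random.default_rng(config.seed)
    N = config.population_size

    def repair(bits: np.ndarray) -> np.ndarray:
        if bits.sum() == 0:  # only possible with an empty core
            bits[int(rng.integers(0, m))] = 1
        return bits

    pop: list[Chromosome] = []
    for _ in range(N):
        bits = (rng.random(m) < 0.5).astype(np.uint8)
        bits[core_mask] = 1
        pop.append(Chromosome(repair(bits)))
    for c in pop:
        c.fitness = fit_of(c.bits)

    n_elite = max(1, int(round(config.elite_fraction * N)))
    n_elite = min(n_elite, N)
    history: list[float] = []
    best = max(pop, key=lambda c: (c.fitness, -c.card))
    history.append(best.fitness)

    generations = 0
    cross = one_point_crossover if config.crossover == "one_point" else uniform_crossover
    for _gen in range(config.max_generations):
        if (
            len(history) > config.stagnation_window
            and history[-1] == history[-1 - config.stagnation_window]
        ):
            break
        parents = [
            tournament_select(pop, rng, config.tournament_size) for _ in range(N)
        ]
        offspring: list[Chromosome] = []
        i = 0
        while i + 1 < N:
            p1, p2 = parents[i], parents[i + 1]
            if rng.random() < config.crossover_prob:
                c1, c2 = cross(p1, p2, rng, core_mask)
            else:
                c1, c2 = p1.copy(), p2.copy()
            offspring.extend([c1, c2])
            i += 2
        if i < N:
            offspring.append(parents[i].copy())
        offspring = [mutate(c, config.mutation_prob, rng, core_mask) for c in offspring]
        for c in offspring:
            c.bits = repair(c.bits)
            c.fitness = fit_of(c.bits)
        elites = sorted(pop, key=lambda c: (-c.fitness, c.card))[:n_elite]
        pop = [e.copy() for e in elites] + offspring[: N - n_elite]
        generations += 1
        best = max(pop, key=lambda c: (c.fitness, -c.card))
        history.append(best.fitness)

    selected_idx = np.flatnonzero(best.bits)
    pos_sel = pos_of(best.bits)
    return ReductResult(
        selected=tuple(conds[j] for j in selected_idx),
        fitness=float(best.fitness),
        gamma_selected=pos_sel / n,
        gamma_full=gamma_full,
        generations_run=generations,
        history=history,
        core=core_names,
    )


# ---------------------------------------------------------------------------
# sklearn-style selector
# ---------------------------------------------------------------------------

class GARoughSetSelector(SelectorMixin, BaseEstimator):
    """Feature selector: GA search for a near-minimal rough-set reduct.

    Treats every feature as categorical (values compared by equality only)
    and keeps a subset whose dependency degree matches that of the full
    feature set while minimising subset size.

    Parameters mirror :class:`GAConfig`; ``random_state`` seeds the search.

    Attributes
    ----------
    support_mask_ : bool array of shape (n_features,)
    selected_attributes_ : tuple of selected feature names
    result_ : ReductResult with gamma values, fitness history and the core.
    """

    def __init__(
        self,
        population_size: int = 1000,
        max_generations: int = 500,
        crossover_prob: float = 0.5,
        mutation_prob: float = 0.03,
        elite_fraction: float = 0.2,
        beta: float = 0.5,
        tournament_size: int = 2,
        stagnation_window: int = 50,
        crossover: str = "one_point",
        random_state: int | None = None,
    ):
        self.population_size = population_size
        self.max_generations = max_generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.elite_fraction = elite_fraction
        self.beta = beta
        self.tournament_size = tournament_size
        self.stagnation_window = stagnation_window
        self.crossover = crossover
        self.random_state = random_state

    def fit(self, X, y):
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray([str(c) for c in X.columns], dtype=object)
        X = check_array(X, dtype=None, ensure_2d=True)
        y = column_or_1d(y)
        self.n_features_in_ = X.shape[1]
        names = (
            list(self.feature_names_in_)
            if hasattr(self, "feature_names_in_")
            else [f"x{j}" for j in range(X.shape[1])]
        )
        table = table_from_arrays(X, y, feature_names=names)
        cfg = GAConfig(
            population_size=self.population_size,
            max_generations=self.max_generations,
            crossover_prob=self.crossover_prob,
            mutation_prob=self.mutation_prob,
            elite_fraction=self.elite_fraction,
            beta=self.beta,
            tournament_size=self.tournament_size,
            stagnation_window=self.stagnation_window,
            crossover=self.crossover,
            seed=self.random_state,
        )
        result = run_ga(table, cfg)
        mask = np.zeros(X.shape[1], dtype=bool)
        sel = set(result.selected)
        for j, name in enumerate(names):
            mask[j] = name in sel
        self.support_mask_ = mask
        self.selected_attributes_ = result.selected
        self.result_ = result
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_

    def _more_tags(self):  # pragma: no cover - sklearn compat shim
        return {"X_types": ["2darray", "string"], "allow_nan": False}
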