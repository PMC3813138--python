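"""Genetic function approximation: evolving descriptor subsets by LOF.

A population of candidate equations — each a subset of the descriptor pool,
fitted by OLS (or PLS in G/PLS mode) — is evolved with tournament
selection, single-point union crossover and add/remove/swap mutation.
Fitness is the Friedman lack-of-fit score (lower is better), which
penalises equation size and so resists the over-fitting that plain SSE
selection invites when descriptors outnumber compounds.  The best
individual is always carried over (elitism of one), so the best LOF is
monotone non-increasing across generations.

Termination mirrors the usage-stability idea of the GFA literature: the
run stops when the per-descriptor usage histogram over the whole
population has not changed for ``convergence_window`` consecutive
generations, or at ``generations_max``.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import IO, Sequence

import numpy as np

from .datasets import DescriptorTable
from .errors import ConfigError, GfaQsarError, SearchFailureError
from .pls import fit_pls
from .regression import FitStats, LinearModel, fit_ols


@dataclass
class GFAConfig:
    """Hyperparameters of one GFA run.

    The population size (1000) and smoothing factor d (0.5) follow the
    study this package reproduces; everything else is an explicit choice
    documented in the methods note.
    """

    population_size: int = 1000
    smoothing_d: float = 0.5
    min_terms: int = 3
    max_terms: int = 12
    generations_max: int = 500
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    fitting_mode: str = "ols"  # "ols" | "pls"
    pls_components: int = 4
    seed: int = 0
    convergence_window: int = 50

    def validate(self, pool_size: int) -> None:
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        if not (1 <= self.min_terms <= self.max_terms):
            raise ConfigError(
                f"need 1 <= min_terms <= max_terms, got [{self.min_terms}, {self.max_terms}]"
            )
        if self.min_terms > pool_size:
            raise ConfigError(
                f"min_terms={self.min_terms} exceeds descriptor pool size {pool_size}"
            )
        for name in ("crossover_rate", "mutation_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {r}")
        if self.fitting_mode not in ("ols", "pls"):
            raise ConfigError(f"fitting_mode must be 'ols' or 'pls', got {self.fitting_mode!r}")


@dataclass
class GFAIndividual:
    """One candidate equation: term subset + fitted model + LOF fitness."""

    term_set: tuple[str, ...]
    model: LinearModel | None
    stats: FitStats | None
    fitness: float  # = stats.lof; math.inf for singular candidates

    def sort_key(self) -> tuple:
        # ties: fewer terms first, then lexicographic names (determinism)
        return (self.fitness, len(self.term_set), self.term_set)


@dataclass
class GFAResult(Sequence):
    """Ranked final population plus run diagnostics.

    Behaves as a sequence of :class:`GFAIndividual`, best (lowest LOF)
    first.
    """

    population: list[GFAIndividual]
    best_history: list[float]
    generations_run: int
    converged: bool

    def __len__(self) -> int:
        return len(self.population)

    def __getitem__(self, i):
        return self.population[i]

    @property
    def best(self) -> GFAIndividual:
        return self.population[0]


# ---------------------------------------------------------------------------
# Genetic operators


def crossover(
    parent_a: Sequence[str],
    parent_b: Sequence[str],
    rng: np.random.Generator,
    pool: Sequence[str],
    min_terms: int,
    max_terms: int,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Single-point union crossover with repair.

    A split point is drawn; offspring 1 takes parent A's head and parent
    B's tail, offspring 2 the converse.  Duplicates are removed preserving
    order; offspring outside [min_terms, max_terms] are repaired by random
    trimming or padding from the pool.
    """
    a, b = list(parent_a), list(parent_b)
    hi = min(len(a), len(b))
    s = int(rng.integers(1, hi)) if hi > 1 else 1
    child1 = _dedupe(a[:s] + b[s:])
    child2 = _dedupe(b[:s] + a[s:])
    return (
        _repair(child1, rng, pool, min_terms, max_terms),
        _repair(child2, rng, pool, min_terms, max_terms),
    )


def mutate(
    term_set: Sequence[str],
    pool: Sequence[str],
    rng: np.random.Generator,
    rate: float,
    min_terms: int,
    max_terms: int,
) -> tuple[str, ...]:
    """With probability ``rate``, add, remove or swap one term.

    The move is drawn uniformly among *feasible* moves: "add" needs head
    room and an unused pool descriptor, "remove" needs spare terms,
    "swap" needs an unused pool descriptor.  With no feasible move the
    term set is returned unchanged.
    """
    terms = list(term_set)
    if rng.random() >= rate:
        return tuple(terms)
    outside = [t for t in pool if t not in terms]
    moves = []
    if len(terms) < max_terms and outside:
        moves.append("add")
    if len(terms) > min_terms:
        moves.append("remove")
    if outside and terms:
        moves.append("swap")
    if not moves:
        return tuple(terms)
    move = moves[int(rng.integers(len(moves)))]
    if move == "add":
        terms.append(outside[int(rng.integers(len(outside)))])
    elif move == "remove":
        terms.pop(int(rng.integers(len(terms))))
    else:
        terms[int(rng.integers(len(terms)))] = outside[int(rng.integers(len(outside)))]
    return tuple(terms)


def _dedupe(terms: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for t in terms:
        if t not in seen:
            seen.add(t)
            out.append(t)
    return out


def _repair(
    terms: list[str],
    rng: np.random.Generator,
    pool: Sequence[str],
    min_terms: int,
    max_terms: int,
) -> tuple[str, ...]:
    terms = list(terms)
    while len(terms) > max_terms:
        terms.pop(int(rng.integers(len(terms))))
    if len(terms) < min_terms:
        outside = [t for t in pool if t not in terms]
        need = min_terms - len(terms)
        if need > len(outside):
            raise ConfigError("pool too small to repair offspring to min_terms")
        picks = rng.choice(len(outside), size=need, replace=False)
        terms.extend(outside[int(i)] for i in picks)
    return tuple(terms)


# ---------------------------------------------------------------------------
# Search


def gfa_search(
    table: DescriptorTable,
    response: str = "pIC50_obs",
    config: GFAConfig | None = None,
    *,
    pool: Sequence[str] | None = None,
    log_stream: IO[str] | None = None,
) -> GFAResult:
    """Evolve descriptor subsets; returns the final population ranked by LOF.

    ``pool`` restricts the search to a subset of the table's schema
    (defaults to the full schema).  Reproducible from ``config.seed``;
    candidates whose design is singular receive infinite fitness instead
    of aborting the run.
    """
    config = config or GFAConfig()
    pool = tuple(pool) if pool is not None else tuple(table.schema)
    config.validate(len(pool))
    max_terms = min(config.max_terms, len(pool))
    n_train = table.n_training
    if n_train <= max_terms + 1:
        max_terms = n_train - 2
        if max_terms < config.min_terms:
            raise ConfigError(
                f"{n_train} training records cannot support min_terms={config.min_terms}"
            )
    rng = np.random.default_rng(config.seed)
    cache: dict[frozenset, GFAIndividual] = {}

    def evaluate(term_set: tuple[str, ...]) -> GFAIndividual:
        key = frozenset(term_set)
        hit = cache.get(key)
        if hit is not None:
            if hit.term_set != term_set:
                hit = replace(hit, term_set=term_set)
            return hit
        try:
            if config.fitting_mode == "pls":
                ncomp = min(config.pls_components, len(term_set))
                model, stats = fit_pls(
                    table, term_set, response, n_components=ncomp,
                    smoothing_d=config.smoothing_d, compute_loo=False,
                )
            else:
                model, stats = fit_ols(
                    table, term_set, response,
                    smoothing_d=config.smoothing_d, compute_loo=False,
                )
            ind = GFAIndividual(term_set, model, stats, stats.lof)
        except GfaQsarError:
            ind = GFAIndividual(term_set, None, None, math.inf)
        cache[key] = ind
        return ind

    # initial population: uniform random sizes, terms without replacement
    population: list[GFAIndividual] = []
    for _ in range(config.population_size):
        size = int(rng.integers(config.min_terms, max_terms + 1))
        picks = rng.choice(len(pool), size=size, replace=False)
        population.append(evaluate(tuple(pool[int(i)] for i in sorted(picks))))

    best_history: list[float] = []
    stable = 0
    prev_hist: tuple[int, ...] | None = None
    gen = 0
    converged = False
    for gen in range(1, config.generations_max + 1):
        population.sort(key=GFAIndividual.sort_key)
        best = population[0]
        best_history.append(best.fitness)
        hist = _usage_histogram(population, pool)
        if log_stream is not None:
            finite = [p.fitness for p in population if math.isfinite(p.fitness)]
            med = float(np.median(finite)) if finite else math.inf
            log_stream.write(
                f"gen {gen:4d}  best_lof {best.fitness:.6g}  median_lof {med:.6g}  "
                f"usage {_hist_hash(hist)}\n"
            )
        if hist == prev_hist:
            stable += 1
            if stable >= config.convergence_window:
                converged = True
                break
        else:
            stable = 0
        prev_hist = hist

        nxt: list[GFAIndividual] = [best]  # elitism of one
        while len(nxt) < config.population_size:
            pa = _tournament(population, rng)
            pb = _tournament(population, rng)
            if rng.random() < config.crossover_rate:
                off1, off2 = crossover(
                    pa.term_set, pb.term_set, rng, pool, config.min_terms, max_terms
                )
            else:
                off1, off2 = pa.term_set, pb.term_set
            for off in (off1, off2):
                off = mutate(off, pool, rng, config.mutation_rate, config.min_terms, max_terms)
                nxt.append(evaluate(off))
                if len(nxt) >= config.population_size:
                    break
        population = nxt

    population.sort(key=GFAIndividual.sort_key)
    if not math.isfinite(population[0].fitness):
        raise SearchFailureError("every candidate model in the search was singular")
    return GFAResult(
        population=population,
        best_history=best_history,
        generations_run=gen,
        converged=converged,
    )


def _tournament(population: list[GFAIndividual], rng: np.random.Generator) -> GFAIndividual:
    i, j = rng.integers(len(population)), rng.integers(len(population))
    a, b = population[int(i)], population[int(j)]
    return a if a.sort_key() <= b.sort_key() else b


def _usage_histogram(population: list[GFAIndividual], pool: tuple[str, ...]) -> tuple[int, ...]:
    counts = dict.fromkeys(pool, 0)
    for ind in population:
        for t in ind.term_set:
            counts[t] += 1
    return tuple(counts[t] for t in pool)


def _hist_hash(hist: tuple[int, ...]) -> str:
    return hashlib.sha1(repr(hist).encode()).hexdigest()[:12]


def exhaustive_best_lof(
    table: DescriptorTable,
    response: str = "pIC50_obs",
    *,
    pool: Sequence[str] | None = None,
    min_terms: int = 1,
    max_terms: int = 3,
    smoothing_d: float = 0.5,
) -> tuple[tuple[str, ...], float]:
    """Brute-force minimum LOF over all admissible subsets (small pools).

    Intended as an independent check of :func:`gfa_search` on pools small
    enough to enumerate; cost grows combinatorially with pool size.
    """
    from itertools import combinations

    pool = tuple(pool) if pool is not None else tuple(table.schema)
    best: tuple[tuple[str, ...], float] | None = None
    for k in range(min_terms, min(max_terms, len(pool)) + 1):
        for combo in combinations(pool, k):
            try:
                _, stats = fit_ols(
                    table, combo, response, smoothing_d=smoothing_d, compute_loo=False
                )
            except GfaQsarError:
                continue
            key = (stats.lof, len(combo), combo)
            if best is None or key < (best[1], len(best[0]), best[0]):
                best = (combo, stats.lof)
    if best is None:
        raise SearchFailureError("no admissible subset could be fitted")
    return best
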