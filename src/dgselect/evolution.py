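"""The deep-gene-selection loop.

The search couples a standard gene-expression-programming engine with a
shrinking attribute pool (the terminal set):

* every generation is scored by size-penalized cross-validated accuracy,
  ranked, and modified by weight-guided mutation and strict-improvement
  recombination;
* the next terminal set is the union of the attributes carried by the top
  half of the ranked population, so the pool can only contract;
* the next population is reproduced from the top half by
  fitness-proportionate (roulette) copying — which lets good chromosomes
  take over and the pool collapse onto their attributes — topped up with
  fresh random chromosomes over the new pool, with the head size recomputed
  from the pool's size;
* accuracies are re-estimated with fresh cross-validation folds each
  generation, so a subset that scored well by fold luck must keep proving
  itself, while genuinely informative subsets keep their rank.

The loop stops when the pool and the best chromosome's expressed subset
have been stable for ``patience`` consecutive generations, or at a
generation cap; the reported selection is the best chromosome of the last
generation — the solution the population converged to.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

from . import fitness as fitness_mod
from . import sizing
from .karva import (
    DEFAULT_FUNCTIONS,
    Chromosome,
    FunctionSet,
    Gene,
    expressed_terminals,
    gene_terminals,
    random_gene,
    to_karva_string,
)
from .weighting import WeightTable, compute_weights

__all__ = [
    "TerminalSet",
    "RunConfig",
    "GenerationLog",
    "RunResult",
    "init_population",
    "rank_population",
    "extract_terminal_set",
    "mutate",
    "recombine",
    "run",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TerminalSet:
    """Ordered, duplicate-free pool of candidate attribute IDs."""

    ids: tuple[str, ...]
    _members: frozenset = field(repr=False, compare=False, default=frozenset())

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("terminal set must not be empty")
        members = frozenset(self.ids)
        if len(members) != len(self.ids):
            raise ValueError("terminal set contains duplicate attribute IDs")
        object.__setattr__(self, "_members", members)

    @property
    def size(self) -> int:
        return len(self.ids)

    def __contains__(self, attribute_id: object) -> bool:
        return attribute_id in self._members

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class RunConfig:
    """Run parameters.

    Defaults follow the method's standard setting: 200 chromosomes of 2
    genes each, mutation rate 0.044 (per position, folded into a
    per-chromosome trigger), recombination rate 0.3, at most 200
    generations, and a size-penalty weight r = 0.2.
    """

    ch: int = 200
    n_genes: int = 2
    r: float = 0.2
    mutation_rate: float = 0.044
    recombination_rate: float = 0.3
    max_generations: int = 200
    patience: int = 3
    cv_folds: int = 5
    h_min: int = 3
    seed: int = 0
    top_fraction: float = 0.5
    extraction: str = "all_positions"  # or "expressed"
    functions: FunctionSet = DEFAULT_FUNCTIONS
    classifier: object | None = None

    def __post_init__(self) -> None:
        if self.ch < 2:
            raise ValueError(f"ch must be >= 2, got {self.ch}")
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        if not 0.0 <= self.r < 0.5:
            raise ValueError(f"r must lie in [0, 0.5), got {self.r}")
        for name in ("mutation_rate", "recombination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.extraction not in ("expressed", "all_positions"):
            raise ValueError(
                f"extraction must be 'expressed' or 'all_positions', "
                f"got {self.extraction!r}"
            )


@dataclass(frozen=True)
class GenerationLog:
    generation: int
    T: int
    h: int
    best_f: float
    best_AC: float
    best_s: int


@dataclass(frozen=True)
class RunResult:
    """Outcome of a selection run."""

    selected: tuple[str, ...]
    best: fitness_mod.FitnessRecord
    best_chromosome: str  # karva string of the reported chromosome
    best_ever: fitness_mod.FitnessRecord
    log: tuple[GenerationLog, ...]
    termination: str  # "stagnation" or "max_generations"
    weights: WeightTable
    seed: int

    @property
    def generations(self) -> int:
        return len(self.log)


def init_population(
    ts: TerminalSet, h: int, config: RunConfig, rng
) -> list[Chromosome]:
    """CH random chromosomes of ``n_genes`` genes each over ``ts``."""
    return [
        Chromosome(
            genes=tuple(
                random_gene(ts.ids, config.functions, h, rng)
                for _ in range(config.n_genes)
            )
        )
        for _ in range(config.ch)
    ]


def rank_population(population: Sequence[Chromosome]) -> list[Chromosome]:
    """Sort descending by fitness; ties go to the smaller expressed subset,
    then to the earlier position (stable)."""
    for i, ch in enumerate(population):
        if ch.fitness is None:
            raise ValueError(f"chromosome {i} has no fitness record")
    order = sorted(
        range(len(population)),
        key=lambda i: (-population[i].fitness.f, population[i].fitness.s, i),
    )
    return [population[i] for i in order]


def _chromosome_terminals(
    chromosome: Chromosome, functions: FunctionSet, mode: str
) -> set[str]:
    if mode == "expressed":
        return expressed_terminals(chromosome, functions)
    out: set[str] = set()
    for gene in chromosome.genes:
        out |= {s for s in gene.symbols if s not in functions}
    return out


def extract_terminal_set(
    sorted_population: Sequence[Chromosome],
    weights: WeightTable,
    functions: FunctionSet = DEFAULT_FUNCTIONS,
    fraction: float = 0.5,
    mode: str = "all_positions",
) -> TerminalSet:
    """Union of the attributes carried by the top ``fraction`` of a ranked
    population, ordered by descending weight — the next generation's pool.

    ``mode="all_positions"`` (default) takes every terminal symbol at any
    head or tail position, so attributes that a chromosome carries silently
    stay in the running; ``"expressed"`` takes only each chromosome's
    expressed terminals, which contracts the pool more aggressively.
    """
    k = math.ceil(fraction * len(sorted_population))
    union: set[str] = set()
    for ch in sorted_population[:k]:
        union |= _chromosome_terminals(ch, functions, mode)
    ordered = sorted(union, key=lambda a: (-weights.weight(a), a))
    return TerminalSet(ids=tuple(ordered))


def _terminal_positions(
    chromosome: Chromosome, functions: FunctionSet
) -> list[tuple[int, int, str]]:
    """All (gene_index, position_within_gene, symbol) holding terminals."""
    out = []
    for gi, gene in enumerate(chromosome.genes):
        for pos, sym in enumerate(gene.symbols):
            if sym not in functions:
                out.append((gi, pos, sym))
    return out


def _replace_symbol(
    chromosome: Chromosome, gi: int, pos: int, symbol: str
) -> Chromosome:
    gene = chromosome.genes[gi]
    syms = list(gene.symbols)
    syms[pos] = symbol
    new_gene = Gene(head=tuple(syms[: gene.h]), tail=tuple(syms[gene.h :]))
    genes = list(chromosome.genes)
    genes[gi] = new_gene
    return Chromosome(genes=tuple(genes))


def mutate(
    chromosome: Chromosome,
    weights: WeightTable,
    functions: FunctionSet,
    ts: TerminalSet,
    rng,
) -> Chromosome:
    """Replace the chromosome's weakest terminal by a stronger symbol.

    The terminal position (head or tail, any gene) whose attribute has the
    lowest weight is located; a head occurrence is replaced half the time by
    a uniformly chosen function and otherwise by a uniformly chosen
    strictly-higher-weight terminal from ``ts``; a tail occurrence only ever
    takes a stronger terminal. When no stronger terminal exists the head
    falls back to a function and the tail leaves the chromosome unchanged.
    Exactly one position changes (or none in the degenerate case).
    """
    positions = _terminal_positions(chromosome, functions)
    weakest = positions[0]
    w_weak = weights.weight(weakest[2])
    for item in positions[1:]:  # first occurrence wins ties
        w = weights.weight(item[2])
        if w < w_weak:
            weakest, w_weak = item, w
    gi, pos, weak = weakest
    stronger = [a for a in ts.ids if weights.weight(a) > w_weak]

    in_head = pos < chromosome.genes[gi].h
    if in_head:
        if not stronger or rng.random() < 0.5:
            names = functions.names
            new_symbol = names[int(rng.integers(0, len(names)))]
        else:
            new_symbol = stronger[int(rng.integers(0, len(stronger)))]
    else:
        if not stronger:
            return chromosome
        new_symbol = stronger[int(rng.integers(0, len(stronger)))]
    return _replace_symbol(chromosome, gi, pos, new_symbol)


def _gene_weight_sum(
    gene: Gene, weights: WeightTable, functions: FunctionSet, mode: str
) -> float:
    if mode == "expressed":
        return sum(weights.weight(a) for a in gene_terminals(gene, functions))
    return sum(weights.weight(s) for s in gene.symbols if s not in functions)


def recombine(
    parent_a: Chromosome,
    parent_b: Chromosome,
    weights: WeightTable,
    fitness_evaluator: Callable[[Chromosome], fitness_mod.FitnessRecord],
    rng=None,
    max_tries: int | None = None,
    functions: FunctionSet = DEFAULT_FUNCTIONS,
    mode: str = "all_positions",
) -> tuple[Chromosome, Chromosome]:
    """Strict-improvement gene exchange between two evaluated parents.

    The lower-fitness parent (lc) donates its strongest gene — the gene with
    the highest summed attribute weight — into the weakest gene slot of the
    higher-fitness parent (hc). The candidate child replaces hc only if its
    fitness strictly exceeds both parents'; otherwise lc's next-strongest
    gene is tried, up to ``max_tries`` (defaults to the gene count). On
    failure both parents are returned unchanged, in their original order.

    Donor genes whose head/tail structure differs from the slot they would
    fill are skipped, so every chromosome keeps a uniform gene structure.
    """
    if parent_a.fitness is None or parent_b.fitness is None:
        raise ValueError("both parents must be evaluated before recombination")
    a_first = parent_a.fitness.f >= parent_b.fitness.f
    hc, lc = (parent_a, parent_b) if a_first else (parent_b, parent_a)
    f_bar = max(parent_a.fitness.f, parent_b.fitness.f)

    hc_sums = [
        _gene_weight_sum(g, weights, functions, mode) for g in hc.genes
    ]
    weak_slot = min(range(len(hc_sums)), key=lambda i: (hc_sums[i], i))
    slot_gene = hc.genes[weak_slot]
    lc_order = sorted(
        range(len(lc.genes)),
        key=lambda i: (-_gene_weight_sum(lc.genes[i], weights, functions, mode), i),
    )
    tries = len(lc.genes) if max_tries is None else max_tries

    for gi in lc_order[:tries]:
        donor = lc.genes[gi]
        if donor.h != slot_gene.h or donor.t != slot_gene.t:
            continue
        genes = list(hc.genes)
        genes[weak_slot] = donor
        child = Chromosome(genes=tuple(genes))
        record = fitness_evaluator(child)
        if record.f > f_bar:
            child.fitness = record
            return (child, lc) if a_first else (lc, child)
    return parent_a, parent_b


def _resolve_data(data, labels, attribute_ids):
    """Accept an ExpressionDataset-like object or a raw matrix + labels."""
    if hasattr(data, "X") and hasattr(data, "labels"):
        return (
            np.asarray(data.X, dtype=float),
            np.asarray(data.labels),
            tuple(data.attribute_ids),
        )
    X = np.asarray(data, dtype=float)
    if labels is None:
        raise ValueError("labels are required when passing a raw matrix")
    labels = np.asarray(labels)
    if attribute_ids is None:
        attribute_ids = tuple(f"a{i}" for i in range(X.shape[1]))
    return X, labels, tuple(attribute_ids)


def run(
    data,
    labels=None,
    attribute_ids=None,
    config: RunConfig = RunConfig(),
) -> RunResult:
    """Execute the full selection loop on a samples × attributes matrix.

    ``data`` may be an ``ExpressionDataset`` or a numeric matrix with
    ``labels`` (one class per sample) and optional ``attribute_ids``.

    Per generation: score everything (accuracies cached per expressed
    subset, folds reseeded each generation), rank, mutate (the rank-0
    elite is left untouched), recombine random disjoint pairs from the top
    half, re-rank, log, extract the next terminal set from the top half,
    then reproduce — roulette copies from the top half plus fresh random
    chromosomes over the new pool with the recomputed head size. The run
    stops when the pool and the best expressed subset are unchanged for
    ``patience`` consecutive generations, or at ``max_generations``.

    A run is bit-reproducible given (data, config): every stochastic choice
    flows from a single generator seeded with ``config.seed``.
    """
    X, y, ids = _resolve_data(data, labels, attribute_ids)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("matrix must be samples x attributes, one label per sample")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    if np.all(np.ptp(X, axis=0) == 0):
        raise ValueError("constant matrix: no attribute varies across samples")

    rng = np.random.default_rng(config.seed)
    cv_base = int(rng.integers(0, 2**30))
    n = config.functions.n
    col = {a: j for j, a in enumerate(ids)}

    weights = compute_weights(X, y, ids)

    cache: dict[frozenset, float] = {}
    gen_seed = cv_base

    def evaluate(chromosome: Chromosome, T: int) -> fitness_mod.FitnessRecord:
        terms = expressed_terminals(chromosome, config.functions)
        key = frozenset(terms)
        if key not in cache:
            sub = X[:, [col[a] for a in sorted(terms)]]
            ac, _ = fitness_mod.estimate_accuracy(
                sub,
                y,
                cv_folds=config.cv_folds,
                classifier=config.classifier,
                seed=gen_seed,
                return_counts=False,
            )
            cache[key] = ac
        ac = cache[key]
        s = len(terms)
        f = fitness_mod.fitness(ac, s, T, config.r)
        record = fitness_mod.FitnessRecord(AC=ac, s=s, f=f)
        chromosome.fitness = record
        return record

    # first generation draws from the full attribute universe,
    # ordered strongest-first like every later terminal set
    ts = TerminalSet(ids=weights.attribute_ids)
    T = ts.size
    h = sizing.head_size(T, config.ch, n, config.h_min)
    population = init_population(ts, h, config, rng)
    for chromo in population:
        evaluate(chromo, T)
    population = rank_population(population)

    best_record: fitness_mod.FitnessRecord | None = None
    log: list[GenerationLog] = []
    termination = "max_generations"
    stagnant = 0
    prev_state: tuple | None = None

    for generation in range(1, config.max_generations + 1):
        L = sizing.chromosome_length(h, n, config.n_genes)

        # weight-guided mutation: per-position rate folded into a
        # per-chromosome trigger probability; the elite stays untouched
        p_mut = min(1.0, config.mutation_rate * L)
        for i in range(1, len(population)):
            if rng.random() < p_mut:
                mutant = mutate(
                    population[i], weights, config.functions, ts, rng
                )
                if mutant is not population[i]:
                    evaluate(mutant, T)
                    population[i] = mutant

        # strict-improvement recombination over random disjoint pairs from
        # the ranked top half
        half = math.ceil(config.top_fraction * len(population))
        candidates = list(rng.permutation(half))
        evaluator = lambda c: evaluate(c, T)  # noqa: E731
        for i, j in zip(candidates[0::2], candidates[1::2]):
            if rng.random() < config.recombination_rate:
                population[i], population[j] = recombine(
                    population[i],
                    population[j],
                    weights,
                    evaluator,
                    rng=rng,
                    functions=config.functions,
                    mode=config.extraction,
                )

        population = rank_population(population)
        gen_best = population[0]
        log.append(
            GenerationLog(
                generation=generation,
                T=T,
                h=h,
                best_f=gen_best.fitness.f,
                best_AC=gen_best.fitness.AC,
                best_s=gen_best.fitness.s,
            )
        )
        logger.info(
            "gen %d\tT=%d\th=%d\tbest_f=%.4f\tbest_AC=%.4f\tbest_s=%d",
            generation,
            T,
            h,
            gen_best.fitness.f,
            gen_best.fitness.AC,
            gen_best.fitness.s,
        )
        if best_record is None or gen_best.fitness.f > best_record.f:
            best_record = gen_best.fitness

        next_ts = extract_terminal_set(
            population,
            weights,
            config.functions,
            fraction=config.top_fraction,
            mode=config.extraction,
        )
        state = (
            next_ts.ids,
            frozenset(expressed_terminals(gen_best, config.functions)),
        )
        if state == prev_state:
            stagnant += 1
        else:
            stagnant = 0
        prev_state = state
        ts = next_ts
        T = ts.size
        if stagnant >= config.patience:
            termination = "stagnation"
            break
        if generation == config.max_generations:
            break

        # reproduction: fitness-proportionate copies from the top half
        # (with replacement) plus fresh chromosomes over the new pool
        h = sizing.head_size(T, config.ch, n, config.h_min)
        f_top = np.array([c.fitness.f for c in population[:half]])
        f_top = f_top - f_top.min() + 1e-9
        picks = rng.choice(half, size=half, p=f_top / f_top.sum())
        copies = [Chromosome(genes=population[k].genes) for k in picks]
        fresh = init_population(ts, h, config, rng)[: len(population) - half]
        population = copies + fresh

        # re-score everything against the new pool with fresh folds, so
        # fold-luck from earlier generations cannot lock in
        cache.clear()
        gen_seed = (cv_base + generation) % (2**31 - 1)
        for chromo in population:
            evaluate(chromo, T)
        population = rank_population(population)

    final_best = population[0]
    selected = sorted(
        expressed_terminals(final_best, config.functions),
        key=lambda a: (-weights.weight(a), a),
    )
    return RunResult(
        selected=tuple(selected),
        best=final_best.fitness,
        best_chromosome=to_karva_string(final_best),
        best_ever=best_record,
        log=tuple(log),
        termination=termination,
        weights=weights,
        seed=config.seed,
    )
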