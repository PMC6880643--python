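import dataclasses

import numpy as np
import pytest

from dgselect import data_io, evolution
from dgselect.evolution import (
    RunConfig,
    TerminalSet,
    extract_terminal_set,
    init_population,
    mutate,
    rank_population,
    recombine,
    run,
)
from dgselect.fitness import FitnessRecord
from dgselect.karva import (
    DEFAULT_FUNCTIONS,
    Chromosome,
    Gene,
    expressed_terminals,
    validate,
)
from dgselect.weighting import WeightTable


def _record(f, s=2, AC=None):
    return FitnessRecord(AC=f if AC is None else AC, s=s, f=f)


class TestTerminalSet:
    def test_rejects_empty_and_duplicates(self):
        with pytest.raises(ValueError):
            TerminalSet(())
        with pytest.raises(ValueError):
            TerminalSet(("a1", "a1"))

    def test_membership_and_order(self):
        ts = TerminalSet(("a2", "a0", "a1"))
        assert ts.size == 3 and "a0" in ts and "zz" not in ts
        assert list(ts) == ["a2", "a0", "a1"]


class TestRunConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ch": 1},
            {"r": 0.5},
            {"r": -0.1},
            {"mutation_rate": 1.5},
            {"patience": 0},
            {"extraction": "sideways"},
        ],
    )
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            RunConfig(**kwargs)

    def test_reference_defaults(self):
        cfg = RunConfig()
        assert (cfg.ch, cfg.n_genes, cfg.mutation_rate, cfg.recombination_rate,
                cfg.max_generations) == (200, 2, 0.044, 0.3, 200)


class TestInitPopulation:
    def test_population_shape(self, rng):
        ts = TerminalSet(tuple(f"a{i}" for i in range(13)))
        cfg = RunConfig(ch=10, n_genes=1)
        population = init_population(ts, h=3, config=cfg, rng=rng)
        assert len(population) == 10
        assert all(c.length == 7 for c in population)
        assert all(validate(c, ts) == [] for c in population)

    def test_singleton_pool_selects_that_attribute(self, rng):
        ts = TerminalSet(("a0",))
        population = init_population(ts, 3, RunConfig(ch=5, n_genes=2), rng)
        assert all(expressed_terminals(c) == {"a0"} for c in population)

    def test_seeded_reproducibility(self):
        ts = TerminalSet(tuple(f"a{i}" for i in range(20)))
        cfg = RunConfig(ch=8)
        p1 = init_population(ts, 4, cfg, np.random.default_rng(5))
        p2 = init_population(ts, 4, cfg, np.random.default_rng(5))
        assert p1 == p2


class TestRankPopulation:
    def test_descending_by_fitness(self):
        pop = [Chromosome((Gene(("a0",), ("a0", "a0")),), _record(f))
               for f in (0.7, 0.9, 0.8)]
        ranked = rank_population(pop)
        assert [c.fitness.f for c in ranked] == [0.9, 0.8, 0.7]

    def test_tie_goes_to_smaller_subset_then_original_order(self):
        a = Chromosome((Gene(("a0",), ("a0", "a0")),), _record(0.9, s=4))
        b = Chromosome((Gene(("a1",), ("a1", "a1")),), _record(0.9, s=2))
        c = Chromosome((Gene(("a2",), ("a2", "a2")),), _record(0.9, s=2))
        ranked = rank_population([a, b, c])
        assert ranked == [b, c, a]

    def test_sorted_input_unchanged(self):
        pop = [Chromosome((Gene(("a0",), ("a0", "a0")),), _record(f))
               for f in (0.9, 0.8, 0.7)]
        assert rank_population(pop) == pop

    def test_requires_evaluation(self):
        with pytest.raises(ValueError):
            rank_population([Chromosome((Gene(("a0",), ("a0", "a0")),))])


class TestExtractTerminalSet:
    def _random_ranked_population(self, rng, ts, ch=20):
        cfg = RunConfig(ch=ch, n_genes=2)
        population = init_population(ts, 3, cfg, rng)
        for i, c in enumerate(population):
            c.fitness = _record(float(rng.random()), s=2)
        return rank_population(population)

    def test_result_is_subset_ordered_by_weight(self, rng):
        ids = tuple(f"a{i}" for i in range(30))
        weights = WeightTable.from_ranks(ids, np.arange(1, 31, dtype=float))
        ts = TerminalSet(weights.attribute_ids)
        population = self._random_ranked_population(rng, ts)
        out = extract_terminal_set(population, weights)
        assert set(out.ids) <= set(ts.ids)
        assert out.size <= ts.size
        ws = [weights.weight(a) for a in out.ids]
        assert ws == sorted(ws, reverse=True)

    def test_identical_population_gives_its_support(self, rng):
        ids = tuple(f"a{i}" for i in range(8))
        weights = WeightTable.from_ranks(ids, np.arange(1, 9, dtype=float))
        gene = Gene(("+", "a3", "a1"), ("a5", "a2", "a3", "a1"))
        chromo = Chromosome((gene,), _record(0.9))
        out = extract_terminal_set([chromo] * 6, weights)
        assert set(out.ids) == {"a1", "a2", "a3", "a5"}

    def test_expressed_mode_only_counts_expressed(self, rng):
        ids = tuple(f"a{i}" for i in range(8))
        weights = WeightTable.from_ranks(ids, np.arange(1, 9, dtype=float))
        # root is a terminal: only a3 is expressed, the rest is silent
        gene = Gene(("a3", "a1", "a2"), ("a5", "a6", "a7", "a0"))
        chromo = Chromosome((gene,), _record(0.9))
        out = extract_terminal_set([chromo] * 4, weights, mode="expressed")
        assert set(out.ids) == {"a3"}

    def test_fraction_counts_ceil(self, rng):
        ids = tuple(f"a{i}" for i in range(10))
        weights = WeightTable.from_ranks(ids, np.arange(1, 11, dtype=float))
        g1 = Chromosome((Gene(("a0",), ("a1", "a1")),), _record(0.9))
        g2 = Chromosome((Gene(("a2",), ("a3", "a3")),), _record(0.8))
        g3 = Chromosome((Gene(("a4",), ("a5", "a5")),), _record(0.7))
        out = extract_terminal_set([g1, g2, g3], weights, fraction=0.5)
        # ceil(0.5 * 3) = 2 chromosomes contribute
        assert set(out.ids) == {"a0", "a1", "a2", "a3"}


class TestMutate:
    def test_weakest_terminal_is_upgraded(self, rng):
        ids = ("a3", "a9", "a0", "a2", "a7", "a6", "a8")
        # a8 weakest overall; within the chromosome a6 is the weakest
        weights = WeightTable.from_ranks(ids, [7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        ts = TerminalSet(weights.attribute_ids)
        chromo = Chromosome((Gene(("-", "/", "a6"), ("a2", "a0", "a9", "a7")),))
        seen_symbols = set()
        for seed in range(50):
            out = mutate(chromo, weights, DEFAULT_FUNCTIONS, ts,
                         np.random.default_rng(seed))
            # exactly the weakest position (head slot 2) changed
            assert out.genes[0].tail == chromo.genes[0].tail
            assert out.genes[0].head[:2] == ("-", "/")
            replacement = out.genes[0].head[2]
            assert replacement != "a6"
            seen_symbols.add(replacement)
            if replacement not in DEFAULT_FUNCTIONS:
                assert weights.weight(replacement) > weights.weight("a6")
            assert validate(out, ts) == []
        # both options (function and stronger terminal) occur
        assert any(s in DEFAULT_FUNCTIONS for s in seen_symbols)
        assert any(s not in DEFAULT_FUNCTIONS for s in seen_symbols)

    def test_tail_weakest_without_stronger_terminal_is_noop(self):
        # all terminal positions sit in the tail and the pool offers nothing
        # stronger than what is already there -> degenerate no-op
        weights = WeightTable.from_ranks(("a0",), [1.0])
        ts = TerminalSet(("a0",))
        chromo = Chromosome((Gene(("+", "-", "*"), ("a0", "a0", "a0", "a0")),))
        out = mutate(chromo, weights, DEFAULT_FUNCTIONS, ts, np.random.default_rng(0))
        assert out is chromo

    def test_head_weakest_without_stronger_terminal_becomes_function(self):
        weights = WeightTable.from_ranks(("a0",), [1.0])
        ts = TerminalSet(("a0",))
        chromo = Chromosome((Gene(("a0", "-", "*"), ("a0", "a0", "a0", "a0")),))
        out = mutate(chromo, weights, DEFAULT_FUNCTIONS, ts, np.random.default_rng(0))
        assert out.genes[0].head[0] in DEFAULT_FUNCTIONS
        assert out.genes[0].tail == chromo.genes[0].tail

    def test_ten_thousand_mutations_stay_valid(self):
        rng = np.random.default_rng(13)
        ids = tuple(f"a{i}" for i in range(25))
        weights = WeightTable.from_ranks(ids, rng.random(25) + 0.1)
        ts = TerminalSet(weights.attribute_ids)
        cfg = RunConfig(ch=2, n_genes=2)
        for _ in range(10_000):
            chromo = init_population(ts, 3, cfg, rng)[0]
            out = mutate(chromo, weights, DEFAULT_FUNCTIONS, ts, rng)
            assert validate(out, ts) == []
            diff = [
                (gi, pi)
                for gi in range(2)
                for pi in range(7)
                if out.genes[gi].symbols[pi] != chromo.genes[gi].symbols[pi]
            ]
            assert len(diff) <= 1


class TestRecombine:
    @staticmethod
    def _toy_evaluator(weights):
        def evaluate(chromosome):
            terms = expressed_terminals(chromosome)
            score = sum(weights.weight(a) for a in terms) / max(len(terms), 1)
            return FitnessRecord(AC=score, s=len(terms), f=score)
        return evaluate

    def test_identical_parents_unchanged(self):
        ids = tuple(f"a{i}" for i in range(6))
        weights = WeightTable.from_ranks(ids, np.arange(1, 7, dtype=float))
        gene = Gene(("+", "a4", "a5"), ("a1", "a2", "a3", "a0"))
        a = Chromosome((gene, gene), _record(0.8))
        b = Chromosome((gene, gene), _record(0.8))
        out = recombine(a, b, weights, self._toy_evaluator(weights))
        assert out == (a, b)

    def test_requires_evaluated_parents(self):
        gene = Gene(("a0",), ("a0", "a0"))
        with pytest.raises(ValueError):
            recombine(Chromosome((gene,)), Chromosome((gene,), _record(0.5)),
                      WeightTable.from_ranks(("a0",), [1.0]), lambda c: _record(0.5))

    def test_child_replaces_higher_fitness_parent_slot(self):
        ids = ("a0", "a1", "a2", "a3")
        weights = WeightTable.from_ranks(ids, [4.0, 3.0, 2.0, 1.0])
        strong_gene = Gene(("a0", "+", "a1"), ("a1", "a0", "a0", "a1"))
        weak_gene = Gene(("a3", "+", "a3"), ("a3", "a3", "a3", "a3"))
        mid_gene = Gene(("a2", "+", "a2"), ("a2", "a2", "a2", "a2"))
        hc = Chromosome((mid_gene, weak_gene), _record(0.25))
        lc = Chromosome((strong_gene, mid_gene), _record(0.20))
        evaluate = self._toy_evaluator(weights)
        out_a, out_b = recombine(hc, lc, weights, evaluate)
        # hc's weakest slot (the a3 gene) received lc's strongest (a0/a1) gene
        assert out_b == lc
        assert out_a.genes == (mid_gene, strong_gene)
        assert out_a.fitness.f > 0.25

    def test_accepted_children_strictly_beat_both_parents(self):
        rng = np.random.default_rng(31)
        ids = tuple(f"a{i}" for i in range(15))
        weights = WeightTable.from_ranks(ids, rng.random(15) + 0.1)
        ts = TerminalSet(weights.attribute_ids)
        cfg = RunConfig(ch=2, n_genes=2)
        evaluate = self._toy_evaluator(weights)
        accepted = 0
        for _ in range(1000):
            a, b = init_population(ts, 3, cfg, rng)
            a.fitness = evaluate(a)
            b.fitness = evaluate(b)
            out_a, out_b = recombine(a, b, weights, evaluate, rng=rng)
            if (out_a, out_b) != (a, b):
                accepted += 1
                child = out_a if out_a is not a else out_b
                assert child.fitness.f > max(a.fitness.f, b.fitness.f)
        assert accepted > 0  # the rule fires on a meaningful fraction


class TestRun:
    def test_recovers_planted_signal_and_contracts(self, small_planted_dataset):
        dataset, truth = small_planted_dataset
        cfg = RunConfig(ch=40, seed=2, max_generations=120)
        result = run(dataset, config=cfg)
        assert result.selected
        assert set(result.selected) <= set(dataset.attribute_ids)
        Ts = [entry.T for entry in result.log]
        assert all(a >= b for a, b in zip(Ts, Ts[1:]))
        assert Ts[0] == dataset.n_attributes
        assert result.termination in ("stagnation", "max_generations")
        # the planted attributes dominate the selection on this easy problem
        assert len(set(result.selected) & set(truth)) >= 1
        assert result.best.AC >= 0.8

    def test_log_reports_sizing_law(self, small_planted_dataset):
        from dgselect import sizing

        dataset, _ = small_planted_dataset
        cfg = RunConfig(ch=40, seed=4, max_generations=30)
        result = run(dataset, config=cfg)
        for entry in result.log:
            assert entry.h == sizing.head_size(entry.T, cfg.ch, 2, cfg.h_min)

    def test_bit_reproducible(self, small_planted_dataset):
        dataset, _ = small_planted_dataset
        cfg = RunConfig(ch=30, seed=9, max_generations=40)
        r1 = run(dataset, config=cfg)
        r2 = run(dataset, config=cfg)
        assert r1.selected == r2.selected
        assert r1.best == r2.best
        assert r1.log == r2.log
        assert r1.termination == r2.termination

    def test_stagnation_termination_on_easy_problem(self, small_planted_dataset):
        dataset, _ = small_planted_dataset
        result = run(dataset, config=RunConfig(ch=40, seed=2, max_generations=200))
        assert result.termination == "stagnation"
        # converged: the last generations agree on pool size
        assert result.log[-1].T == result.log[-2].T

    def test_generation_cap(self, small_planted_dataset):
        dataset, _ = small_planted_dataset
        result = run(dataset, config=RunConfig(ch=30, seed=1, max_generations=3))
        assert result.generations == 3
        assert result.termination == "max_generations"

    def test_best_ever_is_at_least_final(self, small_planted_dataset):
        dataset, _ = small_planted_dataset
        result = run(dataset, config=RunConfig(ch=30, seed=6, max_generations=25))
        assert result.best_ever.f == pytest.approx(
            max(entry.best_f for entry in result.log)
        )

    def test_expressed_extraction_contracts_harder(self, small_planted_dataset):
        dataset, _ = small_planted_dataset
        base = RunConfig(ch=40, seed=3, max_generations=60)
        r_pos = run(dataset, config=base)
        r_exp = run(dataset, config=dataclasses.replace(base, extraction="expressed"))
        assert r_exp.log[-1].T <= r_pos.log[-1].T

    def test_degenerate_inputs_fail_before_loop(self, rng):
        X = np.ones((10, 5))
        labels = np.array(["A", "B"] * 5)
        with pytest.raises(ValueError, match="constant"):
            run(X, labels)
        X2 = rng.normal(size=(10, 5))
        with pytest.raises(ValueError, match="class"):
            run(X2, np.array(["A"] * 10))
        with pytest.raises(ValueError, match="2 samples"):
            run(X2, np.array(["A"] * 9 + ["B"]))

    def test_accepts_raw_matrix_with_labels(self, rng):
        X = rng.normal(size=(30, 20))
        labels = np.array(["A", "B"] * 15)
        X[labels == "B", 3] += 3.0
        result = run(X, labels, config=RunConfig(ch=20, seed=0, max_generations=15))
        assert all(a.startswith("a") for a in result.selected)
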