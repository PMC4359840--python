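import numpy as np
import pandas as pd
import pytest

from adscreen import (
    Chromosome,
    DecisionTable,
    GAConfig,
    GARoughSetSelector,
    dependency,
    enumerate_reducts,
    fitness,
    generate_planted_table,
    mutate,
    one_point_crossover,
    run_ga,
    tournament_select,
    uniform_crossover,
    PlantedTableSpec,
)
from adscreen.ga import GAError


class _FixedCutRng:
    """Stub rng returning a predetermined cut point."""

    def __init__(self, cut):
        self.cut = cut

    def integers(self, lo, hi=None, size=None):
        return self.cut


def _chrom(bits):
    return Chromosome(np.asarray(list(bits), dtype=np.uint8))


def _consistent_table_34(seed=0):
    """34 condition attributes; the first 10 fully determine the decision."""
    rng = np.random.default_rng(seed)
    rel = rng.integers(0, 3, size=(60, 10))
    frame = pd.DataFrame({f"r{j}": rel[:, j].astype(str) for j in range(10)})
    for j in range(24):
        frame[f"n{j}"] = rng.integers(0, 3, size=60).astype(str)
    frame["d"] = (rel.sum(axis=1) % 3).astype(str)
    return DecisionTable(frame, "d")


class TestFitness:
    def test_full_chromosome_on_consistent_table(self):
        t = _consistent_table_34()
        full = _chrom([1] * 34)
        assert fitness(full, t, beta=0.7) == pytest.approx(1.0)

    def test_ten_of_thirty_four_with_full_dependency(self):
        t = _consistent_table_34()
        bits = [1] * 10 + [0] * 24
        # the 10 relevant attributes preserve gamma, so p(x) = 1
        assert fitness(_chrom(bits), t, beta=0.5) == pytest.approx(
            0.5 * (1 - 10 / 34) + 1.0
        )
        assert fitness(_chrom(bits), t, beta=0.5) == pytest.approx(1.3529, abs=1e-4)

    def test_t1_single_attribute(self, t1):
        assert fitness(_chrom([1, 0]), t1, beta=0.5) == pytest.approx(0.75)

    def test_all_zero_rejected(self, t1):
        with pytest.raises(GAError):
            fitness(_chrom([0, 0]), t1)


class TestOperators:
    def test_tournament_single_individual(self):
        c = _chrom([1, 0])
        c.fitness = 1.0
        assert tournament_select([c], np.random.default_rng(0), k=2) is c

    def test_tournament_prefers_higher_fitness(self):
        a, b = _chrom([1, 1]), _chrom([1, 0])
        a.fitness, b.fitness = 1.2, 0.9
        winner = tournament_select([a, b], np.random.default_rng(0), k=5)
        assert winner is a

    def test_tournament_tie_prefers_fewer_attributes(self):
        a, b = _chrom([1, 1, 1, 0, 0]), _chrom([1, 1, 1, 1, 1])
        a.fitness = b.fitness = 1.0
        winner = tournament_select([a, b], np.random.default_rng(0), k=6)
        assert winner is a

    def test_crossover_identical_parents(self):
        p = _chrom([1, 0, 1, 0])
        c1, c2 = one_point_crossover(p, p, np.random.default_rng(0))
        assert np.array_equal(c1.bits, p.bits) and np.array_equal(c2.bits, p.bits)

    def test_crossover_cut_after_two(self):
        c1, c2 = one_point_crossover(_chrom("0000"), _chrom("1111"), _FixedCutRng(2))
        assert list(c1.bits) == [0, 0, 1, 1]
        assert list(c2.bits) == [1, 1, 0, 0]

    def test_crossover_conserves_genes_per_position(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p1 = Chromosome(rng.integers(0, 2, 6).astype(np.uint8))
            p2 = Chromosome(rng.integers(0, 2, 6).astype(np.uint8))
            c1, c2 = one_point_crossover(p1, p2, rng)
            assert np.array_equal(c1.bits + c2.bits, p1.bits + p2.bits)

    def test_crossover_length_mismatch(self):
        with pytest.raises(GAError):
            one_point_crossover(_chrom("01"), _chrom("011"), np.random.default_rng(0))

    def test_crossover_repins_core(self):
        core = np.array([True, False, False, False])
        c1, c2 = one_point_crossover(_chrom("0000"), _chrom("0111"), _FixedCutRng(1),
                                     core_mask=core)
        assert c1.bits[0] == 1 and c2.bits[0] == 1

    def test_uniform_crossover_conserves_genes(self):
        rng = np.random.default_rng(4)
        p1 = Chromosome(rng.integers(0, 2, 8).astype(np.uint8))
        p2 = Chromosome(rng.integers(0, 2, 8).astype(np.uint8))
        c1, c2 = uniform_crossover(p1, p2, rng)
        assert np.array_equal(c1.bits + c2.bits, p1.bits + p2.bits)

    def test_mutation_prob_zero_is_identity(self):
        c = _chrom([1, 0, 1])
        out = mutate(c, 0.0, np.random.default_rng(0))
        assert np.array_equal(out.bits, c.bits)

    def test_mutation_prob_one_flips_single_noncore_bit(self):
        core = np.array([True, True, False])
        out = mutate(_chrom([1, 1, 0]), 1.0, np.random.default_rng(0), core_mask=core)
        assert list(out.bits) == [1, 1, 1]

    def test_mutation_rate_matches_probability(self):
        rng = np.random.default_rng(5)
        pm = 0.03
        trials = 10_000
        flipped = 0
        base = _chrom([1, 0, 1, 0, 1, 0])
        for _ in range(trials):
            out = mutate(base, pm, rng)
            flipped += int(not np.array_equal(out.bits, base.bits))
        se = np.sqrt(pm * (1 - pm) / trials)
        assert abs(flipped / trials - pm) < 3 * se


class TestRunGA:
    def test_core_reaching_gamma_skips_generations(self, t1):
        res = run_ga(t1, GAConfig(population_size=10, max_generations=5, seed=0))
        assert res.selected == ("a", "b")
        assert res.generations_run == 0
        assert res.gamma_selected == pytest.approx(4 / 6)

    def test_same_seed_identical_result(self):
        t, _ = generate_planted_table(PlantedTableSpec(n_objects=80, seed=1))
        cfg = GAConfig(population_size=40, max_generations=30, seed=9)
        r1, r2 = run_ga(t, cfg), run_ga(t, cfg)
        assert r1 == r2

    def test_planted_recovery_and_invariants(self):
        t, truth = generate_planted_table(
            PlantedTableSpec(n_objects=300, relevant=5, irrelevant=10, seed=21)
        )
        res = run_ga(t, GAConfig(population_size=150, max_generations=80, seed=13))
        assert res.gamma_selected == pytest.approx(res.gamma_full)
        assert set(res.core) <= set(res.selected)
        assert res.gamma_selected <= res.gamma_full + 1e-12
        # non-decreasing best fitness (elitism)
        assert all(b >= a for a, b in zip(res.history, res.history[1:]))

    def test_matches_exhaustive_oracle_on_small_tables(self):
        rng = np.random.default_rng(0)
        hits = 0
        n_tables = 10
        for i in range(n_tables):
            t, _ = generate_planted_table(
                PlantedTableSpec(
                    n_objects=100, relevant=3, irrelevant=4,
                    value_cardinality=2, n_classes=2, seed=100 + i,
                )
            )
            rs = enumerate_reducts(t)
            min_size = min(len(r) for r in rs.reducts)
            res = run_ga(t, GAConfig(population_size=80, max_generations=60,
                                     seed=200 + i))
            assert res.gamma_selected == pytest.approx(rs.reference_gamma)
            assert len(res.selected) <= min_size + 1
            hits += len(res.selected) == min_size
        assert hits >= 0.9 * n_tables

    def test_invalid_config_rejected(self, t1):
        with pytest.raises(GAError):
            run_ga(t1, GAConfig(mutation_prob=1.5))

    def test_gamma_zero_warns_and_proceeds(self):
        frame = pd.DataFrame({"a": ["1", "1"], "d": ["x", "y"]})
        t = DecisionTable(frame, "d")
        with pytest.warns(UserWarning, match="gamma_C = 0"):
            res = run_ga(t, GAConfig(population_size=5, max_generations=3, seed=0))
        assert res.gamma_full == 0.0


class TestSelector:
    def test_sklearn_contract_and_transform(self):
        t, truth = generate_planted_table(
            PlantedTableSpec(n_objects=120, relevant=2, irrelevant=4,
                             value_cardinality=2, n_classes=2, seed=5)
        )
        X = pd.DataFrame(t.X(), columns=t.condition_attributes)
        sel = GARoughSetSelector(population_size=60, max_generations=40,
                                 random_state=0)
        from sklearn.base import clone

        clone(sel)  # param contract
        sel.fit(X, t.y())
        assert sel.support_mask_.sum() == len(sel.selected_attributes_)
        Xt = sel.transform(X)
        assert Xt.shape == (120, len(sel.selected_attributes_))
        gamma = dependency(t, sel.selected_attributes_).gamma
        assert gamma == pytest.approx(sel.result_.gamma_full)

    def test_pipeline_composition(self):
        from sklearn.pipeline import Pipeline

        from adscreen import BayesNetClassifier, CohortSpec, generate_cohort

        t, _ = generate_cohort(CohortSpec(n_subjects=150, n_items=8,
                                          n_discriminative=3, separable=True,
                                          noise=0.0, seed=2))
        pipe = Pipeline(
            [
                ("reduce", GARoughSetSelector(population_size=40,
                                              max_generations=20,
                                              random_state=0)),
                ("bn", BayesNetClassifier()),
            ]
        )
        pipe.fit(t.X(), t.y())
        assert (pipe.predict(t.X()) == t.y()).mean() > 0.9
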