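"""Unit tests for the COVIDOA primitives and the SA stage.

Monte-Carlo frequency checks use 3-sigma binomial bounds at 1e4-1e5 draws;
all generators are seeded.
"""

import math

import numpy as np
import pytest

from covidsa import (
    CovidoaParams,
    Individual,
    SaParams,
    binarize,
    combine_proteins,
    cool_temperature,
    covidoa_run,
    frameshift_replicate,
    hybrid_run,
    mutate,
    repair,
    roulette_select,
    sa_accept,
    sa_neighbor,
    sa_refine,
    sigmoid_transfer,
    stage_rngs,
)


def binom_3sigma(p, n):
    return 3 * math.sqrt(p * (1 - p) / n)


def make_individual(bits, fitness):
    bits = np.asarray(bits, dtype=np.uint8)
    return Individual(bits=bits, fitness=fitness, error_rate=fitness,
                      subset_size=int(bits.sum()))


class TestSigmoidTransfer:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.0, 0.5), (10.0, 1 / (1 + math.exp(-10))), (-10.0, 1 / (1 + math.exp(10)))],
    )
    def test_closed_form(self, x, expected):
        assert sigmoid_transfer(x) == pytest.approx(expected, rel=1e-12)

    def test_symmetry_and_monotonicity(self):
        xs = np.linspace(-20, 20, 401)
        s = sigmoid_transfer(xs)
        assert np.all(np.diff(s) > 0)
        assert s + sigmoid_transfer(-xs) == pytest.approx(np.ones_like(xs))

    @pytest.mark.parametrize("bad", [np.nan, np.inf, -np.inf])
    def test_rejects_non_finite(self, bad):
        with pytest.raises(ValueError):
            sigmoid_transfer(bad)


class TestBinarize:
    def test_extreme_values_are_deterministic(self, rng):
        x = np.array([50.0, -50.0] * 10)
        for _ in range(20):
            bits = binarize(x, rng)
            # S(x)->1 gives bit 0 (rand >= 1 impossible); S(x)->0 gives bit 1
            assert np.array_equal(bits, np.tile([0, 1], 10))

    def test_one_probability_matches_complement_of_transfer(self):
        # S(ln 3) = 0.75 so P(bit=1) = 0.25 under the printed rule
        rng = np.random.default_rng(7)
        n = 100_000
        bits = binarize(np.full(n, math.log(3.0)), rng)
        assert abs(bits.mean() - 0.25) < binom_3sigma(0.25, n)

    def test_invert_flips_probability(self):
        rng = np.random.default_rng(8)
        n = 100_000
        bits = binarize(np.full(n, math.log(3.0)), rng, invert=True)
        assert abs(bits.mean() - 0.75) < binom_3sigma(0.75, n)


class TestRouletteSelect:
    def test_single_individual_always_selected(self, rng):
        ind = make_individual([1, 0], 0.3)
        assert roulette_select([ind], rng) is ind

    def test_equal_fitness_is_uniform(self):
        rng = np.random.default_rng(9)
        pop = [make_individual([1, 0, 0], 0.5) for _ in range(4)]
        n = 100_000
        counts = np.zeros(4)
        for _ in range(n):
            chosen = roulette_select(pop, rng)
            counts[pop.index(chosen)] += 1
        assert np.all(np.abs(counts / n - 0.25) < binom_3sigma(0.25, n))

    def test_weight_formula_dominates(self):
        # weights (0.9-0.1)+delta vs delta: first picked essentially always
        rng = np.random.default_rng(10)
        pop = [make_individual([1], 0.1), make_individual([1], 0.9)]
        picks = sum(roulette_select(pop, rng) is pop[0] for _ in range(10_000))
        assert picks >= 9_990

    def test_empty_population_rejected(self, rng):
        with pytest.raises(ValueError):
            roulette_select([], rng)


class TestFrameshiftReplicate:
    def test_shift_structure(self):
        parent = np.array([1, 0, 1, 1], dtype=np.uint8)
        rng = np.random.default_rng(0)
        for p in frameshift_replicate(parent, 5, rng):
            assert np.array_equal(p[1:], parent[:-1])
            assert p[0] in (0, 1)

    def test_first_bits_are_independent_draws(self):
        # replaying the rng stream reproduces each protein's random head bit
        parent = np.zeros(6, dtype=np.uint8)
        proteins = frameshift_replicate(parent, 4, np.random.default_rng(33))
        expected_heads = [np.random.default_rng(33).integers(0, 2, size=4)[i] for i in range(4)]
        assert [int(p[0]) for p in proteins] == [int(h) for h in expected_heads]

    def test_d1_protein_is_fully_random(self):
        rng = np.random.default_rng(11)
        heads = [int(frameshift_replicate(np.array([1], dtype=np.uint8), 1, rng)[0][0])
                 for _ in range(200)]
        assert set(heads) == {0, 1}

    def test_nop_count(self, rng):
        assert len(frameshift_replicate(np.array([1, 0], dtype=np.uint8), 3, rng)) == 3


class TestCombineProteins:
    def test_single_protein_identity(self, rng):
        p = np.array([1, 1, 0], dtype=np.uint8)
        assert np.array_equal(combine_proteins([p], rng), p)

    def test_identical_proteins_unchanged(self, rng):
        p = np.array([1, 0, 1, 0], dtype=np.uint8)
        assert np.array_equal(combine_proteins([p, p.copy(), p.copy()], rng), p)

    def test_uniform_mixing_rate(self):
        rng = np.random.default_rng(12)
        zeros, ones = np.zeros(4, np.uint8), np.ones(4, np.uint8)
        n = 10_000
        total = sum(combine_proteins([zeros, ones], rng).sum() for _ in range(n))
        frac = total / (4 * n)
        assert abs(frac - 0.5) < binom_3sigma(0.5, 4 * n)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            combine_proteins([np.zeros(3, np.uint8), np.zeros(4, np.uint8)], rng)


class TestMutate:
    def test_mr_zero_is_identity(self, rng):
        bits = (np.arange(50) % 2).astype(np.uint8)
        assert np.array_equal(mutate(bits, 0.0, rng), bits)

    def test_mr_one_flips_half_on_average(self):
        rng = np.random.default_rng(13)
        bits = np.zeros(10_000, dtype=np.uint8)
        flipped = (mutate(bits, 1.0, rng) != bits).mean()
        assert abs(flipped - 0.5) < binom_3sigma(0.5, 10_000)

    def test_change_probability_is_half_mr(self):
        # resampling a bit changes it with probability MR/2
        rng = np.random.default_rng(14)
        bits = np.zeros(1000, dtype=np.uint8)
        trials = 100
        changed = np.mean([(mutate(bits, 0.2, rng) != bits).mean() for _ in range(trials)])
        assert abs(changed - 0.10) < binom_3sigma(0.10, 1000 * trials)


class TestRepair:
    def test_empty_mask_gets_one_bit(self, rng):
        out = repair(np.zeros(7, dtype=np.uint8), rng)
        assert out.sum() == 1

    def test_nonempty_mask_untouched(self, rng):
        bits = np.array([0, 1, 0], dtype=np.uint8)
        assert repair(bits, rng) is bits


class TestCooling:
    def test_direct_product(self):
        assert cool_temperature(100.0, 0.9) == pytest.approx(90.0)

    def test_iterated_schedule_reaches_floor(self):
        t = 1.0
        steps = 0
        while t > 0.0101:
            t = cool_temperature(t, 0.99)
            steps += 1
        assert steps == 458
        assert t == pytest.approx(0.99**458)

    def test_strictly_decreasing(self):
        for t in (1e-6, 0.5, 1e3):
            assert cool_temperature(t, 0.999) < t

    def test_invalid_cooling_rejected(self):
        for bad in (0.0, 1.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                cool_temperature(1.0, bad)

    def test_schedule_length_formula(self):
        p = SaParams(t0=1.0, t_end=1e-4, cooling=0.99)
        assert p.n_steps == math.ceil(math.log(1e-4) / math.log(0.99))
        assert SaParams(t0=0.5, t_end=0.6, cooling=0.9).n_steps == 0


class TestSaAccept:
    def test_improvement_always_accepted(self, rng):
        for t in (1e-9, 1.0, 1e6):
            assert sa_accept(-0.05, t, rng)
            assert sa_accept(0.0, t, rng)

    def test_metropolis_frequency(self):
        rng = np.random.default_rng(15)
        n = 100_000
        p = math.exp(-0.1)
        freq = np.mean([sa_accept(0.1, 1.0, rng) for _ in range(n)])
        assert abs(freq - p) < binom_3sigma(p, n)

    def test_cold_limit_rejects(self):
        rng = np.random.default_rng(16)
        assert not any(sa_accept(0.1, 1e-6, rng) for _ in range(10_000))

    def test_nonpositive_temperature_rejected(self, rng):
        with pytest.raises(ValueError):
            sa_accept(0.1, 0.0, rng)


class TestSaNeighbor:
    def test_single_flip_distance(self):
        rng = np.random.default_rng(17)
        bits = np.array([1, 0, 1, 1, 0], dtype=np.uint8)
        for _ in range(100):
            out = sa_neighbor(bits, rng)
            assert (out != bits).sum() in (1, 2)  # 2 only via repair of [0..0]

    def test_d1_repair_floor(self):
        rng = np.random.default_rng(18)
        out = sa_neighbor(np.array([1], dtype=np.uint8), rng)
        assert out.sum() == 1

    def test_flip_position_uniform(self):
        rng = np.random.default_rng(19)
        bits = np.ones(10, dtype=np.uint8)
        n = 10_000
        counts = np.zeros(10)
        for _ in range(n):
            counts += sa_neighbor(bits, rng) != bits
        assert np.all(np.abs(counts / n - 0.1) < binom_3sigma(0.1, n))


class TestCovidoaRun:
    def test_zero_iterations_returns_initial_best(self, small_fitness):
        params = CovidoaParams(d=8, n_pop=5, max_iter=0)
        best, trace = covidoa_run(params, small_fitness, np.random.default_rng(1))
        assert trace.size == 0
        assert best.subset_size >= 1

    def test_trace_non_increasing_and_valid_masks(self, small_fitness):
        params = CovidoaParams(d=8, n_pop=6, max_iter=15)
        best, trace = covidoa_run(params, small_fitness, np.random.default_rng(2))
        assert np.all(np.diff(trace) <= 1e-15)
        assert trace[-1] == pytest.approx(best.fitness)
        assert best.bits.size == 8 and best.subset_size == best.bits.sum() >= 1

    def test_deterministic_given_seed(self, small_dataset):
        from covidsa import WrapperFitness

        ds, _ = small_dataset
        params = CovidoaParams(d=8, n_pop=5, max_iter=10)
        outs = []
        for _ in range(2):
            best, trace = covidoa_run(params, WrapperFitness(ds), np.random.default_rng(3))
            outs.append((best.bits.copy(), trace.copy()))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])


class TestSaRefine:
    def test_empty_schedule_returns_initial(self, small_fitness, rng):
        initial = Individual.evaluated(np.array([1, 0, 1, 0, 0, 0, 0, 0], np.uint8),
                                       small_fitness)
        best, trace = sa_refine(initial, SaParams(t0=0.1, t_end=0.2), small_fitness, rng)
        assert best is initial and trace.size == 0

    def test_constant_landscape_keeps_fitness(self):
        class Flat:
            fitness, epsilon = 0.5, 0.5

            def __init__(self, mask):
                self.s_size = int(mask.sum())

        flat = Flat
        initial = Individual(np.array([1, 0], np.uint8), 0.5, 0.5, 1)
        best, trace = sa_refine(initial, SaParams(t0=1, t_end=0.5, cooling=0.9),
                                flat, np.random.default_rng(4))
        assert best.fitness == initial.fitness
        assert np.all(trace == 0.5)

    def test_trace_monotone_and_never_worse_than_initial(self, small_fitness):
        rng = np.random.default_rng(5)
        bits = repair((rng.random(8) < 0.5).astype(np.uint8), rng)
        initial = Individual.evaluated(bits, small_fitness)
        best, trace = sa_refine(initial, SaParams(), small_fitness, rng)
        assert np.all(np.diff(trace) <= 1e-15)
        assert best.fitness <= initial.fitness
        assert trace[-1] == pytest.approx(best.fitness)


class TestHybridRun:
    def test_degenerate_sa_equals_covidoa_alone(self, small_dataset):
        from covidsa import WrapperFitness

        ds, _ = small_dataset
        c = CovidoaParams(d=8, n_pop=5, max_iter=8)
        res = hybrid_run(c, SaParams(t0=0.1, t_end=0.2), WrapperFitness(ds), seed=6)
        covid_rng, _ = stage_rngs(6)
        best, trace = covidoa_run(c, WrapperFitness(ds), covid_rng)
        assert np.array_equal(res.best.bits, best.bits)
        assert res.sa_trace.size == 0
        assert res.covidoa_stage_best == pytest.approx(best.fitness)

    def test_bit_identical_across_calls(self, small_dataset):
        from covidsa import WrapperFitness

        ds, _ = small_dataset
        c = CovidoaParams(d=8, n_pop=5, max_iter=8)
        r1 = hybrid_run(c, SaParams(t0=0.05, t_end=1e-3), WrapperFitness(ds), seed=7)
        r2 = hybrid_run(c, SaParams(t0=0.05, t_end=1e-3), WrapperFitness(ds), seed=7)
        assert r1.to_dict() == r2.to_dict()

    def test_hybrid_never_worse_than_covidoa_stage(self, small_dataset):
        from covidsa import WrapperFitness

        ds, _ = small_dataset
        c = CovidoaParams(d=8, n_pop=6, max_iter=10)
        for seed in range(5):
            res = hybrid_run(c, SaParams(t0=0.05, t_end=1e-3), WrapperFitness(ds), seed=seed)
            assert res.best.fitness <= res.covidoa_stage_best
            assert np.all(np.diff(res.full_trace) <= 1e-15)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(d=0), dict(d=4, n_pop=0), dict(d=4, nop=0),
         dict(d=4, mr=0.004), dict(d=4, mr=0.6), dict(d=4, lb=1.0, ub=-1.0)],
    )
    def test_covidoa_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CovidoaParams(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(t0=0.0), dict(t_end=0.0), dict(cooling=0.0), dict(cooling=1.0)],
    )
    def test_sa_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SaParams(**kwargs)
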