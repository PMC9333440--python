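"""Evolutionary operators: fitness, selection, crossover, mutation, loop."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import xpars
from xpars.ga import UndefinedFitnessError, _auroc_from_hists

from conftest import random_valid_chromosome


def auroc_bruteforce(scores, labels):
    """O(n^2) pairwise oracle: concordant + half ties over pos x neg pairs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    diff = pos[:, None] - neg[None, :]
    return ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size


class TestAuroc:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),    # perfect separation
        ([5, 5, 5, 5], [0, 1, 0, 1], 0.5),    # everything tied
        ([1, 2, 2, 3], [0, 1, 0, 1], 0.875),  # one tied pair of four
        ([4, 3, 2, 1], [0, 0, 1, 1], 0.0),
    ])
    def test_known_values(self, scores, labels, expected):
        assert xpars.fitness_auroc(scores, labels) == pytest.approx(expected)
        assert auroc_bruteforce(scores, labels) == pytest.approx(expected)

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedFitnessError):
            xpars.fitness_auroc([1, 2], [1, 1])

    def test_matches_bruteforce_and_sklearn_on_random_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 200))
            scores = rng.integers(1, 7, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            ours = xpars.fitness_auroc(scores, labels)
            assert ours == pytest.approx(auroc_bruteforce(scores, labels),
                                         abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(labels, scores),
                                         abs=1e-12)

    def test_histogram_form_agrees_with_rank_form(self, rng):
        for _ in range(30):
            levels = rng.integers(1, 7, size=500)
            labels = rng.integers(0, 2, size=500)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            hp = np.bincount(levels[labels == 1] - 1, minlength=6).astype(float)
            hn = np.bincount(levels[labels == 0] - 1, minlength=6).astype(float)
            assert _auroc_from_hists(hp, hn) == pytest.approx(
                xpars.fitness_auroc(levels, labels), abs=1e-12)


class TestRouletteSelect:
    def test_single_item(self, rng):
        assert xpars.roulette_select(["a"], [2.0], 1, rng) == ["a"]

    def test_without_replacement_and_deterministic(self):
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        items = list(range(6))
        w = [1, 2, 3, 4, 5, 6]
        pick1 = xpars.roulette_select(items, w, 4, rng1)
        pick2 = xpars.roulette_select(items, w, 4, rng2)
        assert pick1 == pick2
        assert len(set(pick1)) == 4

    def test_first_draw_frequencies_proportional_to_weights(self, rng):
        weights = [0.5, 0.25, 0.25]
        n = 10_000
        draws = np.array([
            xpars.roulette_select([0, 1, 2], weights, 1, rng)[0]
            for _ in range(n)
        ])
        for i, p in enumerate(weights):
            freq = (draws == i).mean()
            assert abs(freq - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_zero_weights_fall_back_to_uniform(self, rng):
        n = 4000
        draws = np.array([
            xpars.roulette_select([0, 1], [0.0, 0.0], 1, rng)[0]
            for _ in range(n)
        ])
        assert abs(draws.mean() - 0.5) < 3 * np.sqrt(0.25 / n)


class TestSpliceChildren:
    def test_identical_parents_collapse_to_one(self):
        p = np.array([[1, 2, 2, 3]]).T
        pool = xpars.enumerate_splice_children(p, p, 6)
        assert len(pool) == 1
        assert np.array_equal(pool[0], p)

    def test_enumeration_example(self):
        a = np.array([[1, 1, 2, 2]]).T
        b = np.array([[1, 2, 2, 3]]).T
        pool = xpars.enumerate_splice_children(a, b, 6)
        got = {tuple(c.ravel()) for c in pool}
        assert got == {(1, 2, 2, 3), (1, 1, 2, 3), (1, 1, 2, 2), (1, 2, 2, 2)}

    def test_pool_bound_and_validity(self, rng):
        for _ in range(50):
            a = random_valid_chromosome(rng, (4, 5), 6)
            b = random_valid_chromosome(rng, (4, 5), 6)
            pool = xpars.enumerate_splice_children(a, b, 6)
            assert 1 <= len(pool) <= 2 * (20 - 1)
            assert all(xpars.is_valid(c, 6) for c in pool)

    def test_dimension_mismatch(self):
        with pytest.raises(xpars.StructuralError):
            xpars.enumerate_splice_children(np.ones((4, 1), int),
                                            np.ones((4, 5), int), 6)

    def test_matches_naive_enumeration(self, rng):
        """Cross-check the vectorized splice against a literal re-derivation."""
        for _ in range(20):
            a = random_valid_chromosome(rng, (2, 3), 4)
            b = random_valid_chromosome(rng, (2, 3), 4)
            fa, fb = a.ravel(), b.ravel()
            naive = {}
            for k in range(1, 6):
                for child in (np.r_[fa[:k], fb[k:]], np.r_[fb[:k], fa[k:]]):
                    child = child.reshape(2, 3)
                    if xpars.is_valid(child, 4):
                        naive.setdefault(child.tobytes(), child)
            got = {c.tobytes() for c in
                   xpars.enumerate_splice_children(a, b, 4)}
            assert got == set(naive)


class TestMutate:
    def test_boundary_clamp_leaves_matrix_unchanged(self):
        g = np.full((4, 5), 6, dtype=np.int64)
        rng = np.random.default_rng(0)
        for _ in range(20):
            out = xpars.mutate(g, rng, 6)
            # only -1 moves are possible; +1 draws clamp to no-op
            assert xpars.is_valid(out, 6)

    def test_mutation_matches_repair_semantics(self):
        g = np.array([[1, 2, 2, 3]]).T
        # find a seed whose draw is (index 1, +1)
        for seed in range(2000):
            rng = np.random.default_rng(seed)
            idx = int(rng.integers(4))
            up = rng.random() < 0.5
            if idx == 1 and up:
                out = xpars.mutate(g, np.random.default_rng(seed), 6)
                assert out.ravel().tolist() == [1, 3, 3, 3]
                return
        pytest.fail("no suitable seed found")

    def test_validity_closure_sweep(self, rng):
        for _ in range(2000):
            shape = (4, 5) if rng.random() < 0.5 else (4, 1)
            g = random_valid_chromosome(rng, shape, 6)
            assert xpars.is_valid(xpars.mutate(g, rng, 6), 6)


def _planted_block_context(n=2000, seed=0):
    """Single-block 1D chart whose true risk increases with BP."""
    spec = xpars.ChartSpec(stratifiers=(),
                           row_axis=xpars.spec_1d_4feature().row_axis)
    model = xpars.make_planted_model(
        spec, xpars.EffectParams(effects={"bp": 1.0}, target_rate=0.2))
    cohort = xpars.simulate_cohort(model, n=n, seed=seed)
    chart = xpars.RiskChart.constant(spec, 3)
    ctx = xpars.FitnessContext(chart, cohort)
    ctx.set_block(())
    return spec, cohort, chart, ctx


class TestFitnessContext:
    def test_incumbent_substitution_is_identity(self, cohort_1d):
        chart = xpars.RiskChart.constant(cohort_1d.spec, 2)
        ctx = xpars.FitnessContext(chart, cohort_1d)
        key = cohort_1d.spec.stratum_keys()[0]
        ctx.set_block(key)
        assert ctx.fitness(chart.blocks[key]) == pytest.approx(
            ctx.chart_auroc(), abs=1e-12)

    def test_fitness_agrees_with_direct_lookup_scoring(self, cohort_1d, rng):
        blocks = {k: random_valid_chromosome(rng, (4, 1), 6)
                  for k in cohort_1d.spec.stratum_keys()}
        chart = xpars.RiskChart(cohort_1d.spec, blocks)
        ctx = xpars.FitnessContext(chart, cohort_1d)
        key = cohort_1d.spec.stratum_keys()[3]
        ctx.set_block(key)
        cand = random_valid_chromosome(rng, (4, 1), 6)
        sub = chart.copy()
        sub.blocks[key] = cand
        direct = xpars.chart_auroc(sub, cohort_1d)
        assert ctx.fitness(cand) == pytest.approx(direct, abs=1e-12)
        many = ctx.fitness_many([cand, chart.blocks[key]])
        assert many[0] == pytest.approx(direct, abs=1e-12)

    def test_unpopulated_block_fitness_is_flat(self, cohort_1d, rng):
        # restrict the cohort to one stratum, then probe another block
        block, _, _, keys = cohort_1d.indexers()
        sub = cohort_1d.subset(np.flatnonzero(block == 0))
        chart = xpars.RiskChart.constant(cohort_1d.spec, 2)
        ctx = xpars.FitnessContext(chart, sub)
        ctx.set_block(keys[5])
        base = ctx.chart_auroc()
        for _ in range(5):
            cand = random_valid_chromosome(rng, (4, 1), 6)
            assert ctx.fitness(cand) == pytest.approx(base, abs=1e-12)

    def test_ordered_candidate_beats_constant_on_planted_block(self):
        _, _, _, ctx = _planted_block_context()
        constant = np.full((4, 1), 3, dtype=np.int64)
        ordered = np.array([[1, 2, 3, 4]]).T
        assert ctx.fitness(ordered) >= ctx.fitness(constant)


class TestCrossover:
    def test_identical_parents_give_identical_children(self):
        _, _, _, ctx = _planted_block_context()
        p = np.array([[1, 2, 2, 3]]).T
        rng = np.random.default_rng(1)
        c1, c2 = xpars.crossover(p, p, ctx, rng)
        assert np.array_equal(c1, p) and np.array_equal(c2, p)

    def test_pool_of_two_returns_both(self):
        _, _, _, ctx = _planted_block_context()
        a = np.array([[1, 1, 1, 1]]).T
        b = np.array([[1, 1, 1, 2]]).T
        pool = xpars.enumerate_splice_children(a, b, 6)
        assert len(pool) == 2
        rng = np.random.default_rng(2)
        c1, c2 = xpars.crossover(a, b, ctx, rng)
        got = {c1.tobytes(), c2.tobytes()}
        assert got == {p.tobytes() for p in pool}

    def test_selected_children_not_worse_than_uniform_pairs(self):
        """Fitness-weighted child selection beats uniform pair sampling on
        average (paired comparison over seeded trials)."""
        _, _, _, ctx = _planted_block_context(n=4000, seed=3)
        rng = np.random.default_rng(42)
        diffs = []
        for _ in range(1000):
            a = random_valid_chromosome(rng, (4, 1), 6)
            b = random_valid_chromosome(rng, (4, 1), 6)
            pool = xpars.enumerate_splice_children(a, b, 6)
            if len(pool) < 3:
                continue
            c1, c2 = xpars.crossover(a, b, ctx, rng)
            sel = (ctx.fitness(c1) + ctx.fitness(c2)) / 2
            u1, u2 = rng.choice(len(pool), size=2, replace=False)
            uni = (ctx.fitness(pool[u1]) + ctx.fitness(pool[u2])) / 2
            diffs.append(sel - uni)
        assert np.mean(diffs) > 0


class TestEvolveBlock:
    def test_trace_is_non_decreasing_any_seed(self):
        _, _, _, ctx = _planted_block_context()
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pop = [random_valid_chromosome(rng, (4, 1), 6) for _ in range(6)]
            params = xpars.GAParams(population_size=6, generations=15,
                                    stall_limit=5)
            _, trace = xpars.evolve_block(ctx, params, pop, rng)
            assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_never_below_incumbent_with_planted_signal(self):
        _, _, chart, ctx = _planted_block_context(n=2000, seed=9)
        incumbent = chart.blocks[()]
        inc_fit = ctx.fitness(incumbent)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pop = [incumbent.copy()] + [
                xpars.mutate(incumbent, rng, 6) for _ in range(7)
            ]
            best, _ = xpars.evolve_block(
                ctx, xpars.GAParams(population_size=8, generations=20), pop,
                rng)
            assert ctx.fitness(best) >= inc_fit
            assert xpars.is_valid(best, 6)

    def test_empty_population_is_error(self):
        _, _, _, ctx = _planted_block_context()
        with pytest.raises(xpars.StructuralError):
            xpars.evolve_block(ctx, xpars.GAParams(), [],
                               np.random.default_rng(0))

    def test_deterministic_given_seed(self):
        _, _, chart, ctx = _planted_block_context()
        incumbent = chart.blocks[()]
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            pop = [incumbent.copy()] + [
                xpars.mutate(incumbent, rng, 6) for _ in range(5)
            ]
            best, trace = xpars.evolve_block(
                ctx, xpars.GAParams(population_size=6, generations=10), pop,
                rng)
            outs.append((best.tobytes(), tuple(trace)))
        assert outs[0] == outs[1]
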