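"""MAP updates, fixed-Q fitting, AIC model selection and responsibilities."""

import itertools
import math

import numpy as np
import pytest

from conftest import make_locus, reads_from_strings
from epiallele import (
    FitConfig,
    aic,
    emission_loglik,
    fit_fixed_q,
    map_assign,
    map_epialleles,
    map_epsilon,
    responsibilities,
    select_model,
    simulate_locus,
    SimulationScenario,
)


def conditional_loglik(model, n):
    """Undo the uniform-attribution prior term: log p(Y | X, w, eps, Q)."""
    return model.loglik + n * math.log(model.Q)


def brute_force_conditional_loglik(values, mask, Q):
    """Global optimum of log p(Y | X, w, eps_hat(X, w)) by enumerating X.

    For any fixed X the optimal w minimises per-read mismatches, and the
    profile likelihood is monotone in total matches, so enumerating all
    2^(Qd) pattern matrices with greedy per-read assignment is exhaustive
    over (X, w).
    """
    n, d = values.shape
    total = int(mask.sum())
    best = -np.inf
    for bits in itertools.product([0, 1], repeat=Q * d):
        X = np.asarray(bits, dtype=np.uint8).reshape(Q, d)
        mm_matrix = np.array(
            [[int(np.sum(mask[i] & (values[i] != X[q]))) for q in range(Q)]
             for i in range(n)]
        )
        mm = int(mm_matrix.min(axis=1).sum())
        eps = min(max(mm / total, 1e-6), 0.5)
        ll = (total - mm) * math.log1p(-eps) + mm * math.log(eps)
        best = max(best, ll)
    return best


class TestEmission:
    def test_all_matches(self):
        v = np.ones(6, dtype=np.uint8)
        assert emission_loglik(v, np.ones(6, bool), v, 0.05) == pytest.approx(
            6 * math.log(0.95)
        )

    def test_one_mismatch(self):
        v = np.array([1, 1, 1, 1, 1, 0], dtype=np.uint8)
        p = np.ones(6, dtype=np.uint8)
        assert emission_loglik(v, np.ones(6, bool), p, 0.05) == pytest.approx(
            math.log(0.05) + 5 * math.log(0.95)
        )

    def test_fully_masked_read_scores_zero(self):
        v = np.zeros(4, dtype=np.uint8)
        assert emission_loglik(v, np.zeros(4, bool), 1 - v, 0.05) == 0.0

    def test_zero_epsilon_with_mismatch_rejected(self):
        v = np.zeros(3, dtype=np.uint8)
        with pytest.raises(ValueError, match="floor"):
            emission_loglik(v, np.ones(3, bool), 1 - v, 0.0)


class TestMapUpdates:
    def test_assign_to_identical_pattern(self):
        values = reads_from_strings(["111111"], [1])
        mask = np.ones_like(values, bool)
        X = reads_from_strings(["000000", "111111"], [1, 1])
        assert map_assign(values, mask, X).tolist() == [1]

    def test_assign_tie_breaks_low(self):
        values = reads_from_strings(["1100"], [1])
        mask = np.ones_like(values, bool)
        X = reads_from_strings(["1000", "1110"], [1, 1])  # one mismatch each
        assert map_assign(values, mask, X).tolist() == [0]

    def test_assign_prefers_fewer_mismatches(self):
        values = reads_from_strings(["111100"], [1])
        mask = np.ones_like(values, bool)
        X = reads_from_strings(["111110", "100001"], [1, 1])  # 1 vs 4 mismatches
        assert map_assign(values, mask, X).tolist() == [0]

    def test_majority_vote(self):
        values = reads_from_strings(["111"], [3])
        mask = np.ones_like(values, bool)
        X, empty = map_epialleles(values, mask, np.zeros(3, dtype=int), 1)
        assert X.tolist() == [[1, 1, 1]] and empty.size == 0

    def test_majority_tie_gives_zero(self):
        values = reads_from_strings(["1", "1", "0", "0"], [1, 1, 1, 1])
        mask = np.ones_like(values, bool)
        X, _ = map_epialleles(values, mask, np.zeros(4, dtype=int), 1)
        assert X.tolist() == [[0]]

    def test_majority_three_to_one(self):
        values = reads_from_strings(["1", "1", "1", "0"], [1, 1, 1, 1])
        mask = np.ones_like(values, bool)
        X, _ = map_epialleles(values, mask, np.zeros(4, dtype=int), 1)
        assert X.tolist() == [[1]]

    def test_epsilon_is_mismatch_fraction(self):
        # 10 reads x 6 sites = 60 observed calls, 3 mismatches
        values = reads_from_strings(["111111"], [10])
        values[0, :3] = 0
        mask = np.ones_like(values, bool)
        X = reads_from_strings(["111111"], [1])
        w = np.zeros(10, dtype=int)
        assert map_epsilon(values, mask, X, w) == pytest.approx(3 / 60)

    def test_epsilon_zero_and_half(self):
        values = reads_from_strings(["10"], [2])
        mask = np.ones_like(values, bool)
        X = reads_from_strings(["10"], [1])
        w = np.zeros(2, dtype=int)
        assert map_epsilon(values, mask, X, w) == 0.0
        assert map_epsilon(values, mask, 1 - X, w) == 1.0
        half = reads_from_strings(["10", "01"], [1, 1])
        assert map_epsilon(half, mask, X, w) == 0.5

    def test_epsilon_requires_observed_entries(self):
        values = np.zeros((2, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="observed"):
            map_epsilon(values, np.zeros_like(values, bool),
                        np.zeros((1, 3), np.uint8), np.zeros(2, int))


class TestFixedQ:
    def test_two_clean_clusters_reach_brute_force_optimum(self):
        values = reads_from_strings(["000000", "111111"], [50, 50])
        locus = make_locus(values)
        model = fit_fixed_q(locus, 2)
        assert sorted(model.pattern_strings()) == ["000000", "111111"]
        assert model.epsilon == 0.0
        assert (model.w[:50] != model.w[50:]).all() or (
            len(set(model.w[:50])) == 1 and len(set(model.w[50:])) == 1
        )
        # brute force over two-pattern models on a reduced instance
        small = values[[0, 1, 2, 50, 51, 52]][:, :3]
        mask = np.ones_like(small, bool)
        oracle = brute_force_conditional_loglik(small, mask, 2)
        m = fit_fixed_q(make_locus(small), 2)
        assert conditional_loglik(m, 6) == pytest.approx(oracle, abs=1e-9)

    def test_identical_reads_q1(self):
        values = reads_from_strings(["101010"], [20])
        model = fit_fixed_q(make_locus(values), 1)
        assert model.pattern_strings() == ["101010"]
        assert model.epsilon == 0.0

    def test_four_patterns_recovered_as_cluster_majorities(self):
        # four well-separated generators with light noise: the fitted
        # patterns must equal the majority votes of the true clusters
        patterns = ["000000", "111111", "000111", "111000"]
        rng = np.random.default_rng(11)
        values = reads_from_strings(patterns, [40, 40, 40, 40])
        truth = np.repeat(np.arange(4), 40)
        flips = rng.random(values.shape) < 0.02
        noisy = np.where(flips, 1 - values, values).astype(np.uint8)
        model = fit_fixed_q(make_locus(noisy), 4)
        expected = set()
        for g in range(4):
            sub = noisy[truth == g]
            expected.add("".join(str(int(b)) for b in (sub.sum(0) * 2 > len(sub))))
        assert set(model.pattern_strings()) == expected

    def test_q_exceeding_reads_rejected(self):
        values = reads_from_strings(["10"], [3])
        with pytest.raises(ValueError, match="exceeds"):
            fit_fixed_q(make_locus(values), 4)

    def test_loglik_nondecreasing_over_iterations(self):
        for seed in range(50):
            scenario = SimulationScenario(
                q_true=3, d=6, n_reads=40, epsilon=0.1, seed=seed
            )
            locus, _ = simulate_locus(scenario)
            for Q in (2, 3, 4):
                model = fit_fixed_q(locus, Q)
                diffs = np.diff(model.loglik_path)
                assert (diffs >= -1e-9).all(), (seed, Q, model.loglik_path)

    def test_epsilon_at_most_half_after_majority_update(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            values = rng.integers(0, 2, (15, 5)).astype(np.uint8)
            mask = rng.random((15, 5)) < 0.8
            mask[:, 0] = True  # keep every column observed somewhere
            w = rng.integers(0, 3, 15)
            X, _ = map_epialleles(values, mask, w, 3)
            if mask.sum() == 0:
                continue
            assert map_epsilon(values, mask, X, w) <= 0.5


class TestBruteForceParity:
    def test_heuristic_rarely_beaten_on_tiny_instances(self):
        """On N<=8, d<=4, Q<=2 instances the coordinate ascent should reach
        the exhaustive optimum in >95% of random cases."""
        rng = np.random.default_rng(123)
        shortfalls = 0
        trials = 200
        for _ in range(trials):
            n = int(rng.integers(2, 9))
            d = int(rng.integers(2, 5))
            Q = int(rng.integers(1, 3))
            values = rng.integers(0, 2, (n, d)).astype(np.uint8)
            mask = rng.random((n, d)) < 0.9
            if mask.sum() == 0 or Q > n:
                continue
            locus = make_locus(values, mask)
            model = fit_fixed_q(locus, Q)
            oracle = brute_force_conditional_loglik(values, mask, Q)
            if conditional_loglik(model, n) < oracle - 1e-9:
                shortfalls += 1
        assert shortfalls / trials < 0.05


class TestAic:
    def test_closed_form_perfect_fit(self):
        # 10 identical fully observed reads, Q=1: epsilon floored at 1e-6
        values = reads_from_strings(["111111"], [10])
        model = fit_fixed_q(make_locus(values), 1)
        expected = -2 * 60 * math.log1p(-1e-6) + 12
        assert model.aic == pytest.approx(expected, abs=1e-9)
        assert model.aic == pytest.approx(12.00012, abs=1e-4)

    def test_arithmetic(self):
        assert aic(-100.0, 2, 6) == 224.0

    def test_extra_pattern_costs_two_d(self):
        d = 7
        assert aic(-50.0, 3, d) - aic(-50.0, 2, d) == 2 * d


class TestSelectModel:
    def test_identical_reads_select_one_epiallele(self):
        values = reads_from_strings(["110011"], [30])
        model = select_model(make_locus(values))
        assert model.Q == 1

    def test_two_separated_clusters_select_two(self):
        values = reads_from_strings(["000000", "111111"], [50, 50])
        locus = make_locus(values)
        model = select_model(locus)
        assert model.Q == 2
        # oracle: enumerate AIC over Q=1..4; optimal patterns for this
        # dataset are majority votes of subsets, hence in {000000,111111}
        n, d = 100, 6
        total = n * d
        candidates = [np.zeros(d, np.uint8), np.ones(d, np.uint8)]
        best_aic = {}
        for Q in range(1, 5):
            best = -np.inf
            for rows in itertools.product(candidates, repeat=Q):
                X = np.stack(rows)
                mm = sum(
                    min(int(np.sum(v != X[q])) for q in range(Q)) for v in values
                )
                eps = min(max(mm / total, 1e-6), 0.5)
                ll = (total - mm) * math.log1p(-eps) + mm * math.log(eps)
                best = max(best, ll - n * math.log(Q))
            best_aic[Q] = -2 * best + 2 * Q * d
        assert min(best_aic, key=best_aic.get) == 2
        assert model.aic == pytest.approx(best_aic[2], abs=1e-9)

    def test_noise_only_locus_selects_one(self):
        hits = 0
        for seed in range(20):
            scenario = SimulationScenario(q_true=1, d=6, n_reads=100,
                                          epsilon=0.05, seed=seed)
            locus, _ = simulate_locus(scenario)
            hits += select_model(locus).Q == 1
        assert hits >= 18

    def test_aic_curve_reported_for_all_q(self):
        values = reads_from_strings(["000000", "111111"], [20, 20])
        model = select_model(make_locus(values), FitConfig(q_max=5))
        assert sorted(model.aic_by_q) == [1, 2, 3, 4, 5]


class TestResponsibilities:
    def test_single_pattern_rows_are_one(self):
        values = reads_from_strings(["1010"], [5])
        locus = make_locus(values)
        model = fit_fixed_q(locus, 1)
        resp = responsibilities(locus, model)
        assert np.allclose(resp.values, 1.0)

    def test_equidistant_read_splits_evenly(self):
        values = reads_from_strings(["1100", "0011", "1001"], [4, 4, 1])
        locus = make_locus(values)
        model = fit_fixed_q(locus, 2)
        resp = responsibilities(locus, model)
        assert resp.values[-1] == pytest.approx([0.5, 0.5])

    def test_six_site_match_ratio(self):
        values = reads_from_strings(["111111", "000000"], [10, 10])
        values = np.vstack([values, values[:1]])
        locus = make_locus(values)
        model = fit_fixed_q(locus, 2)
        model.epsilon = 0.05  # evaluate the marginal at a fixed noise level
        resp = responsibilities(locus, model)
        q_match = int(np.argmax(model.X[:, 0] == 1))
        expected = 0.95 ** 6 / (0.95 ** 6 + 0.05 ** 6)
        assert resp.values[-1, q_match] == pytest.approx(expected, rel=1e-9)
        assert resp.values[-1, 1 - q_match] == pytest.approx(
            0.05 ** 6 / (0.95 ** 6 + 0.05 ** 6), rel=1e-9
        )

    def test_rows_sum_to_one(self):
        scenario = SimulationScenario(seed=4, missing_fraction=0.2)
        locus, _ = simulate_locus(scenario)
        model = select_model(locus)
        resp = responsibilities(locus, model)
        assert np.allclose(resp.values.sum(axis=1), 1.0, atol=1e-9)
        assert (resp.values >= 0).all() and (resp.values <= 1).all()
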