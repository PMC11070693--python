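"""Information estimators: plug-in MI, complexity penalties, optimal
discretization and 3-point information."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from causalmi.info import (
    InfoEngine,
    complexity_term,
    conditional_mi_reg,
    discrete_mi,
    optimal_discretization_mi,
    rectify,
    three_point_info,
)

from conftest import binary_motif, cat_table, gaussian_motif


def _from_counts(counts):
    """Expand a contingency table into label samples."""
    xs, ys = [], []
    for i, row in enumerate(counts):
        for j, c in enumerate(row):
            xs += [f"x{i}"] * c
            ys += [f"y{j}"] * c
    return np.array(xs), np.array(ys)


def _plugin_mi(counts):
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p = counts / n
    px = p.sum(1, keepdims=True)
    py = p.sum(0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / (px * py)), 0.0)
    return terms.sum()


class TestDiscreteMI:
    @pytest.mark.parametrize("counts,expected", [
        ([[2, 0], [0, 2]], math.log(2)),
        ([[1, 1], [1, 1]], 0.0),
    ])
    def test_known_values(self, counts, expected):
        assert discrete_mi(*_from_counts(counts)) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_cell_sum(self):
        counts = [[3, 1], [1, 3]]
        assert discrete_mi(*_from_counts(counts)) == pytest.approx(
            _plugin_mi(counts), abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_small_tables(self, seed):
        """Plug-in formula equivalence on random <=3-level samples, n<=50."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        x = rng.integers(0, 3, n)
        y = rng.integers(0, 3, n)
        counts = np.zeros((3, 3), dtype=int)
        np.add.at(counts, (x, y), 1)
        assert discrete_mi(x, y) == pytest.approx(_plugin_mi(counts), abs=1e-12)

    def test_zero_rows_error(self):
        with pytest.raises(ValueError):
            discrete_mi(np.array([]), np.array([]))


def _brute_force_parametric_complexity(r: int, n: int) -> float:
    """Sum of maximized multinomial likelihoods over all count vectors."""
    total = 0.0
    for counts in itertools.product(range(n + 1), repeat=r):
        if sum(counts) != n:
            continue
        w = math.factorial(n)
        for c in counts:
            w //= math.factorial(c)
        lik = 1.0
        for c in counts:
            if c:
                lik *= (c / n) ** c
        total += w * lik
    return math.log(total)


class TestComplexityTerm:
    def test_bic_closed_form(self):
        assert complexity_term(2, 2, 1, 100, "bic") == pytest.approx(
            0.5 * math.log(100))

    @pytest.mark.parametrize("mode", ["bic", "nml"])
    def test_single_bin_is_free(self, mode):
        assert complexity_term(1, 4, 2, 50, mode) == 0.0
        assert complexity_term(4, 1, 2, 50, mode) == 0.0

    def test_nml_matches_brute_force_2x2_n4(self):
        # k = log C_4(4) - 2 log C_2(4): enumerate all 4-sample tables
        expected = (_brute_force_parametric_complexity(4, 4)
                    - 2 * _brute_force_parametric_complexity(2, 4))
        assert complexity_term(2, 2, 1, 4, "nml") == pytest.approx(expected,
                                                                   rel=1e-9)

    @pytest.mark.parametrize("mode", ["bic", "nml"])
    def test_monotone_in_cardinality_and_n(self, mode):
        grid = [(2, 2), (2, 3), (3, 3), (3, 4)]
        for (a1, b1), (a2, b2) in zip(grid, grid[1:]):
            assert complexity_term(a2, b2, 1, 200, mode) >= complexity_term(
                a1, b1, 1, 200, mode)
        for n1, n2 in [(50, 100), (100, 400), (400, 1000)]:
            assert complexity_term(3, 3, 2, n2, mode) >= complexity_term(
                3, 3, 2, n1, mode)


class TestRectify:
    @pytest.mark.parametrize("v,expected", [(-0.3, 0.0), (0.2, 0.2), (0.0, 0.0)])
    def test_values(self, v, expected):
        assert rectify(v) == expected

    @given(st.floats(allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, derandomize=True)
    def test_never_negative(self, v):
        assert rectify(v) >= 0.0


class TestOptimalDiscretization:
    def test_independent_pairs_vanish_exactly(self):
        """Independent continuous draws give I' = 0 with single-bin
        partitions in at least 95/100 seeds (n=1000)."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res = optimal_discretization_mi(rng.normal(size=1000),
                                            rng.normal(size=1000))
            if res.reg_info_rect == 0.0 and all(
                p.n_bins == 1 for p in res.partitions.values()
            ):
                hits += 1
        assert hits >= 95

    def test_max_bins_cap_binds_for_identity(self):
        # at n=150000 the unconstrained optimum exceeds 50 bins, so the cap
        # must bind for y = x exactly
        x = np.random.default_rng(7).normal(size=150_000)
        res = optimal_discretization_mi(x, x.copy(), max_bins=50)
        assert all(p.n_bins == 50 for p in res.partitions.values())

    def test_bins_never_exceed_cap(self):
        x = np.random.default_rng(3).normal(size=2000)
        res = optimal_discretization_mi(x, x + 0.1 * np.random.default_rng(4).normal(size=2000),
                                        max_bins=8)
        assert all(p.n_bins <= 8 for p in res.partitions.values())

    def test_tracks_knn_oracle_at_moderate_dependence(self):
        """The MI estimate at the optimal partition (plug-in value) agrees
        with an independent kNN estimator within 0.05 nats on 10-seed
        means (y = x + noise, n=500)."""
        from sklearn.feature_selection import mutual_info_regression

        ours, knn = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=500)
            y = x + 1.0 * rng.normal(size=500)
            res = optimal_discretization_mi(x, y)
            ours.append(res.raw_info)
            knn.append(mutual_info_regression(x.reshape(-1, 1), y,
                                              random_state=0, n_neighbors=3)[0])
        assert abs(np.mean(ours) - np.mean(knn)) < 0.05

    def test_too_few_rows_error(self):
        with pytest.raises(ValueError):
            optimal_discretization_mi(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestConditionalMI:
    def test_empty_cond_reduces_to_unconditional(self):
        data = binary_motif("chain", n=800, seed=1)
        eng = InfoEngine(data)
        a = eng.info("X", "Y", (), quality="full")
        b = eng.info("X", "Y", quality="full")
        assert a.reg_info_rect == b.reg_info_rect

    @pytest.mark.parametrize("seed", range(10))
    def test_conditional_independence_is_exact_zero(self, seed):
        data = binary_motif("fork", n=2000, seed=seed, strength=2.5)
        res = conditional_mi_reg("X", "Y", ["Z"], data)
        assert res.reg_info_rect == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_all_categorical(self, seed):
        data = binary_motif("chain", n=1000, seed=seed)
        eng = InfoEngine(data)
        a = eng.info("X", "Y", ("Z",))
        eng2 = InfoEngine(data)
        b = eng2.info("Y", "X", ("Z",))
        assert a.reg_info_rect == pytest.approx(b.reg_info_rect, abs=1e-9)

    def test_zero_usable_rows_error(self):
        data = cat_table({"X": np.array([0, 1, 0, 1]),
                          "Y": np.array([0, 1, 1, 0])})
        data.columns["X"][:] = -1  # all missing
        eng = InfoEngine(data)
        with pytest.raises(ValueError):
            eng.info("X", "Y")


class TestThreePointInfo:
    def test_double_independence_gives_exact_zero(self):
        data = binary_motif("independent", n=1500, seed=2)
        assert three_point_info("X", "Y", "Z", [], data) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_collider_negative(self, seed):
        data = binary_motif("collider", n=2000, seed=seed)
        assert three_point_info("X", "Y", "Z", [], data) < 0

    @pytest.mark.parametrize("seed", range(5))
    def test_chain_positive(self, seed):
        data = binary_motif("chain", n=2000, seed=seed)
        assert three_point_info("X", "Y", "Z", [], data) > 0

    @pytest.mark.parametrize("seed", range(3))
    def test_gaussian_collider_negative(self, seed):
        data = gaussian_motif("collider", n=2000, seed=seed)
        assert three_point_info("X", "Y", "Z", [], data) < 0


class TestNonNegativityFuzz:
    @given(st.integers(0, 10_000), st.integers(2, 4), st.integers(0, 2))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_rectified_info_never_negative(self, seed, levels, n_cond):
        """Every rectified estimate the engine returns is >= 0, for random
        categorical tables and conditioning sets."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 300))
        names = ["A", "B", "C", "D"]
        cols = {k: rng.integers(0, levels, n) for k in names}
        data = cat_table(cols, n_levels=levels)
        eng = InfoEngine(data)
        cond = tuple(names[2:2 + n_cond])
        res = eng.info("A", "B", cond)
        assert res.reg_info_rect >= 0.0
        assert res.raw_info >= res.reg_info


class TestScaling:
    def test_runtime_subquadratic_once_cap_binds(self):
        """log-log runtime slope below 1.3 over n in {1e3, 1e4, 1e5}."""
        import time

        ns = [1_000, 10_000, 100_000]
        times = []
        for n in ns:
            rng = np.random.default_rng(0)
            x = rng.normal(size=n)
            y = x + 0.5 * rng.normal(size=n)
            best = math.inf
            for _ in range(2):
                t0 = time.perf_counter()
                optimal_discretization_mi(x, y)
                best = min(best, time.perf_counter() - t0)
            times.append(best)
        slope = np.polyfit(np.log(ns), np.log(times), 1)[0]
        assert slope < 1.3
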