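"""PFI, Shapley attribution, ALE curves, kappa-ALE, normalisation, ranking."""

import itertools
import math

import numpy as np
import pytest

from envrank.importance import (
    ImportanceEstimate,
    PfiConfig,
    ale_curve,
    kappa_ale,
    normalize_importance,
    pfi,
    rank_features,
    shapley_importance,
)
from .conftest import StubModel, make_table


class TestPfi:
    def test_ignored_feature_scores_exactly_zero(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(size=20), rng.normal(size=20)
        table = make_table({"x1": x1, "x2": x2}, targets={"y": np.ones(20, int)})
        model = StubModel(["x1", "x2"], lambda X: X[:, 0])
        est = pfi(model, table, PfiConfig(n_repeats=10, seed=1))
        assert est.raw["x2"] == 0.0
        assert est.metadata["raw_preclip"]["x2"] == 0.0

    def test_two_row_exhaustive_average(self):
        """x1 = (0, 1), f = x1, y = x1: identity gives 0, swap gives 1 -> 0.5."""
        table = make_table({"x1": [0.0, 1.0]}, targets={"y": [0, 1]})
        model = StubModel(["x1"], lambda X: X[:, 0])
        est = pfi(model, table, PfiConfig(exhaustive=True))
        assert est.raw["x1"] == pytest.approx(0.5, abs=1e-12)
        assert est.metadata["n_repeats"] == 2

    def test_duplicated_column_unused_by_stub_scores_zero(self):
        x = np.random.default_rng(1).uniform(1.0, 2.0, 15)
        y = np.round(2 * x).astype(int)
        table = make_table({"x1": x, "x2": x.copy()}, targets={"y": y})
        model = StubModel(["x1", "x2"], lambda X: 2 * X[:, 0])
        est = pfi(model, table, PfiConfig(n_repeats=8, seed=2))
        assert est.raw["x2"] == 0.0
        assert est.raw["x1"] > 0.0

    def test_exhaustive_matches_independent_enumeration(self):
        """n = 4: compare against a from-scratch loop over all 24 permutations."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(4, 2))
        y = X[:, 0] ** 2 + X[:, 1]
        table = make_table(
            {"a": X[:, 0], "b": X[:, 1]},
            targets={"y": np.zeros(4, int)},
        )
        fn = lambda M: M[:, 0] ** 2 + M[:, 1]
        model = StubModel(["a", "b"], fn)
        est = pfi(model, table, PfiConfig(exhaustive=True), target="y")

        yv = np.zeros(4)
        base = np.mean((yv - fn(X)) ** 2)
        for j, name in enumerate(["a", "b"]):
            diffs = []
            for perm in itertools.permutations(range(4)):
                Xp = X.copy()
                Xp[:, j] = X[list(perm), j]
                diffs.append(np.mean((yv - fn(Xp)) ** 2) - base)
            assert abs(est.metadata["raw_preclip"][name] - np.mean(diffs)) < 1e-12

    def test_absolute_error_loss_supported(self):
        table = make_table({"x1": [0.0, 1.0]}, targets={"y": [0, 1]})
        model = StubModel(["x1"], lambda X: X[:, 0])
        est = pfi(model, table, PfiConfig(loss="absolute_error", exhaustive=True))
        assert est.raw["x1"] == pytest.approx(0.5)  # swap loss 1, identity 0

    def test_too_few_rows_rejected(self):
        table = make_table({"x1": [1.0]}, targets={"y": [1]})
        model = StubModel(["x1"], lambda X: X[:, 0])
        with pytest.raises(ValueError):
            pfi(model, table, PfiConfig())


def _brute_force_shapley(fn, x, bg, d):
    """Coalition-enumeration oracle, written independently of the package."""
    phi = np.zeros(d)
    def v(coal):
        rows = np.array(bg, dtype=float, copy=True)
        for j in coal:
            rows[:, j] = x[j]
        return float(np.mean(fn(rows)))
    for j in range(d):
        others = [k for k in range(d) if k != j]
        for r in range(len(others) + 1):
            for coal in itertools.combinations(others, r):
                w = (
                    math.factorial(len(coal))
                    * math.factorial(d - len(coal) - 1)
                    / math.factorial(d)
                )
                phi[j] += w * (v(coal + (j,)) - v(coal))
    return phi


class TestShapley:
    def test_single_feature_is_deviation_from_background_mean(self):
        x = np.array([1.0, 3.0, -2.0])
        table = make_table({"a": x}, targets={"y": np.ones(3, int)})
        bg = np.array([[0.0], [2.0]])
        model = StubModel(["a"], lambda X: 5 * X[:, 0])
        est = shapley_importance(model, table, background=bg, mode="exact")
        phi = est.metadata["phi"][:, 0]
        expected = 5 * x - np.mean(5 * bg[:, 0])
        assert np.allclose(phi, expected, atol=1e-12)

    def test_additive_model_matches_coalition_enumeration(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 2))
        bg = rng.normal(size=(8, 2))
        fn = lambda M: np.sin(M[:, 0]) + M[:, 1] ** 2
        table = make_table(
            {"a": X[:, 0], "b": X[:, 1]}, targets={"y": np.ones(6, int)}
        )
        model = StubModel(["a", "b"], fn)
        est = shapley_importance(model, table, background=bg, mode="exact")
        for i in range(6):
            oracle = _brute_force_shapley(fn, X[i], bg, 2)
            assert np.allclose(est.metadata["phi"][i], oracle, atol=1e-10)
        # additivity: phi_a = g_a(x_a) - mean_bg g_a for interventional values
        expected_a = np.sin(X[:, 0]) - np.mean(np.sin(bg[:, 0]))
        assert np.allclose(est.metadata["phi"][:, 0], expected_a, atol=1e-10)

    def test_efficiency_dummy_and_symmetry(self):
        rng = np.random.default_rng(5)
        n, d = 15, 4
        X = rng.normal(size=(n, d))
        X[:, 1] = X[:, 0]  # duplicate pair entering symmetrically
        bg = rng.normal(size=(30, d))
        bg[:, 1] = bg[:, 0]
        fn = lambda M: M[:, 0] + M[:, 1] + np.cos(M[:, 2])  # ignores column 3
        table = make_table(
            {"a": X[:, 0], "b": X[:, 1], "c": X[:, 2], "dummy": X[:, 3]},
            targets={"y": np.ones(n, int)},
        )
        model = StubModel(["a", "b", "c", "dummy"], fn)
        est = shapley_importance(model, table, background=bg, mode="exact")
        phi = est.metadata["phi"]
        total = phi.sum(axis=1)
        assert np.abs(total - (est.metadata["fx"] - est.metadata["v_empty"])).max() < 1e-8
        assert np.all(phi[:, 3] == 0.0)
        assert np.allclose(phi[:, 0], phi[:, 1], atol=1e-10)
        assert est.raw["a"] == pytest.approx(est.raw["b"], abs=1e-10)

    def test_sampled_mode_approaches_exact(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 3))
        bg = rng.normal(size=(10, 3))
        fn = lambda M: M[:, 0] * M[:, 1] + M[:, 2]
        table = make_table(
            {f"f{j}": X[:, j] for j in range(3)}, targets={"y": np.ones(10, int)}
        )
        model = StubModel([f"f{j}" for j in range(3)], fn)
        exact = shapley_importance(model, table, background=bg, mode="exact")
        sampled = shapley_importance(
            model, table, background=bg, mode="sampled", n_samples=150, seed=0
        )
        for f in exact.raw:
            assert sampled.raw[f] == pytest.approx(exact.raw[f], abs=0.15)

    def test_exact_mode_refuses_high_dimension(self):
        d = 16
        table = make_table(
            {f"f{j}": np.arange(3.0) for j in range(d)},
            targets={"y": np.ones(3, int)},
        )
        model = StubModel([f"f{j}" for j in range(d)], lambda M: M[:, 0])
        with pytest.raises(ValueError, match="sampled"):
            shapley_importance(model, table, mode="exact")


# frozen hand computation for the 4-row, K=2 fixture:
#   x = (0, 1, 2, 3), w = (10, 20, 30, 40), f = x^2 + 0.1 w, y = (1, 2, 3, 6)
#   breakpoints (0, 1.5, 3); intervals {0, 1} and {2, 3}
#   local effects: f(1.5,.) - f(0,.) = 2.25 ; f(3,.) - f(1.5,.) = 6.75
#   ALE effects: (0, 2.25, 9.0)
#   Newton ratios: 1.5 and 4.5 -> mean square 11.25
#   var(x) = 5/3, var(y) = 14/3  ->  kappa = 11.25 * 5/14 = 225/56
HAND_X = np.array([0.0, 1.0, 2.0, 3.0])
HAND_W = np.array([10.0, 20.0, 30.0, 40.0])
HAND_Y = np.array([1, 2, 3, 6])
HAND_EFFECTS = np.array([0.0, 2.25, 9.0])
HAND_KAPPA = 225.0 / 56.0


def _hand_table():
    return make_table({"x": HAND_X, "w": HAND_W}, targets={"y": HAND_Y})


def _hand_model():
    return StubModel(["x", "w"], lambda M: M[:, 0] ** 2 + 0.1 * M[:, 1])


class TestAle:
    def test_linear_model_gives_linear_accumulated_effect(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=200)
        table = make_table(
            {"x": x, "w": rng.normal(size=200)}, targets={"y": np.ones(200, int)}
        )
        model = StubModel(["x", "w"], lambda M: 3.0 * M[:, 0])
        grid = ale_curve(model, table, "x", K=10)
        expected = 3.0 * (grid.breakpoints - grid.breakpoints[0])
        assert np.allclose(grid.effects, expected, atol=1e-10)

    def test_inert_feature_has_flat_curve(self):
        rng = np.random.default_rng(8)
        table = make_table(
            {"x": rng.normal(size=100), "w": rng.normal(size=100)},
            targets={"y": np.ones(100, int)},
        )
        model = StubModel(["x", "w"], lambda M: M[:, 0] ** 2)
        grid = ale_curve(model, table, "w", K=8)
        assert np.allclose(grid.effects, 0.0, atol=1e-12)

    def test_hand_computed_fixture(self):
        grid = ale_curve(_hand_model(), _hand_table(), "x", K=2)
        assert np.allclose(grid.breakpoints, [0.0, 1.5, 3.0])
        assert np.array_equal(grid.counts, [2, 2])
        assert np.allclose(grid.effects, HAND_EFFECTS, atol=1e-12)

    def test_counts_partition_the_sample(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=137)
        table = make_table(
            {"x": x, "w": rng.normal(size=137)}, targets={"y": np.ones(137, int)}
        )
        model = StubModel(["x", "w"], lambda M: M.sum(axis=1))
        grid = ale_curve(model, table, "x", K=12)
        assert grid.counts.sum() == 137
        assert np.all(grid.counts > 0)
        assert np.all(np.diff(grid.breakpoints) > 0)

    def test_constant_feature_rejected(self):
        table = make_table(
            {"x": np.full(20, 1.0), "w": np.arange(20.0)},
            targets={"y": np.ones(20, int)},
        )
        model = StubModel(["x", "w"], lambda M: M[:, 1])
        with pytest.raises(ValueError, match="constant"):
            ale_curve(model, table, "x", K=5)


class TestKappaAle:
    def test_linear_closed_form(self):
        rng = np.random.default_rng(10)
        n = 500
        x, w = rng.normal(size=n), rng.normal(size=n)
        y = np.maximum(0, np.round(5 + 2 * x)).astype(int)
        table = make_table({"x": x, "w": w}, targets={"y": y})
        beta = 2.0
        model = StubModel(["x", "w"], lambda M: beta * M[:, 0])
        est = kappa_ale(model, table, K=20, target="y")
        closed = beta**2 * np.var(x, ddof=1) / np.var(y.astype(float), ddof=1)
        assert est.raw["x"] == pytest.approx(closed, rel=0.05)
        assert est.raw["w"] == 0.0

    def test_hand_computed_fixture(self):
        est = kappa_ale(_hand_model(), _hand_table(), K=2, target="y")
        assert est.raw["x"] == pytest.approx(HAND_KAPPA, abs=1e-12)

    def test_zero_target_variance_rejected(self):
        table = make_table(
            {"x": np.arange(10.0), "w": np.arange(10.0)[::-1]},
            targets={"y": np.full(10, 3, dtype=int)},
        )
        model = StubModel(["x", "w"], lambda M: M[:, 0])
        with pytest.raises(ValueError, match="variance"):
            kappa_ale(model, table, K=3, target="y")


class TestNormalizeAndRank:
    def _est(self, raw):
        order = sorted(raw, key=lambda f: (-raw[f], f))
        return ImportanceEstimate("PFI", dict(raw), None, order, {})

    def test_sum_to_one(self):
        out = normalize_importance(self._est({"a": 2.0, "b": 2.0}), "sum_to_one")
        assert out.normalized == {"a": 0.5, "b": 0.5}
        assert sum(out.normalized.values()) == pytest.approx(1.0)

    def test_max_to_one_and_single_feature(self):
        out = normalize_importance(self._est({"a": 3.0, "b": 1.0}), "max_to_one")
        assert out.normalized == {"a": 1.0, "b": pytest.approx(1 / 3)}
        single = normalize_importance(self._est({"only": 0.7}), "sum_to_one")
        assert single.normalized == {"only": 1.0}

    def test_all_zero_rejected_and_ranking_preserved(self):
        with pytest.raises(ValueError):
            normalize_importance(self._est({"a": 0.0, "b": 0.0}))
        out = normalize_importance(self._est({"a": 1.0, "b": 3.0}))
        assert out.ranking == ["b", "a"]

    def test_rank_descending_with_named_example(self):
        est = self._est({"P_atm": 0.5, "Tmin": 0.3, "CO": 0.2})
        assert rank_features(est) == ["P_atm", "Tmin", "CO"]

    def test_rank_ties_lexicographic_and_flagged(self):
        est = self._est({"b": 1.0, "a": 1.0, "c": 1.0})
        assert rank_features(est) == ["a", "b", "c"]
        assert set(est.metadata["ties"]) == {"a", "b", "c"}

    def test_rank_matches_independent_sort_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            raw = {f"f{j}": float(rng.normal()) for j in range(6)}
            est = self._est(raw)
            oracle = [f for _, f in sorted(((-v, k) for k, v in raw.items()))]
            assert rank_features(est) == oracle
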