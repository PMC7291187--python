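"""Univariate kernel tests: regression draws, PMM, classifiers, CART, baselines."""

import numpy as np
import pytest

from sice import (
    DataTable,
    ImputationTask,
    MISSING,
    VariableSpec,
    apply_method,
    draw_blr,
    impute_baseline,
    impute_cart,
    impute_lda,
    impute_logreg,
    impute_pmm,
    impute_polyreg,
)
from sice.imputers import fit_cart


def make_task(schema, columns, target, rng=None, mask=None):
    t = DataTable.from_columns(schema, columns)
    if mask is None:
        mask = t.missing_mask(target)
    predictors = [s.name for s in schema if s.name != target]
    return ImputationTask(
        table=t, target=target, predictors=predictors, mask=np.asarray(mask),
        rng=rng or np.random.default_rng(0),
    )


def numeric_xy_task(x, y, rng=None):
    """Numeric target y on numeric predictor x; None marks missing y."""
    return make_task(
        [VariableSpec("x", "numeric"), VariableSpec("y", "numeric")],
        {"x": x, "y": [MISSING if v is None else v for v in y]},
        "y",
        rng=rng,
    )


class TestDrawBlr:
    def test_exact_fit_gives_degenerate_posterior(self, rng):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([2.0, 4.0, 6.0, 8.0])
        draw = draw_blr(X, y, rng=rng)
        assert draw.b == pytest.approx([2.0])
        assert draw.b_star == pytest.approx([2.0])
        assert draw.sigma2_star == 0.0

    def test_posterior_mean_matches_least_squares(self, rng):
        n, n_draws = 50, 10_000
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = 1.0 + 2.0 * X[:, 1] + rng.standard_normal(n)
        b = draw_blr(X, y, rng=rng).b
        draws = np.array([draw_blr(X, y, rng=rng).b_star for _ in range(n_draws)])
        se = draws.std(axis=0) / np.sqrt(n_draws)
        assert np.all(np.abs(draws.mean(axis=0) - b) < 3 * se)

    def test_all_zero_design_falls_back_to_ridge(self, rng, caplog):
        X = np.zeros((5, 2))
        y = np.arange(5.0)
        with caplog.at_level("WARNING"):
            draw = draw_blr(X, y, ridge=0.0, rng=rng)
        assert np.all(np.isfinite(draw.b))
        assert "ridge" in caplog.text

    def test_fewer_than_two_rows_is_an_error(self, rng):
        with pytest.raises(ValueError, match="2 rows"):
            draw_blr(np.ones((1, 1)), np.ones(1), rng=rng)

    def test_sigma2_positive_with_nonzero_residuals(self, rng):
        X = np.ones((4, 1))
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert draw_blr(X, y, rng=rng).sigma2_star > 0


class TestPmm:
    def test_constant_column_imputes_the_constant(self):
        task = numeric_xy_task([1, 2, 3, 4, 5, 6], [7, 7, 7, 7, None, 7])
        assert impute_pmm(task, donors=3) == [7.0]

    def test_single_donor_on_exact_line_returns_nearest_observed(self):
        # y = 10x exactly: zero residuals force b_star = b, so the donor with
        # predicted value nearest to 10*2.05 = 20.5 is the (2, 20) row.
        task = numeric_xy_task([1.0, 2.0, 3.0, 2.05], [10.0, 20.0, 30.0, None])
        assert impute_pmm(task, donors=1) == [20.0]

    def test_donor_pool_larger_than_observed_rows_errors(self):
        task = numeric_xy_task([1, 2, 3], [1.0, 2.0, None])
        with pytest.raises(ValueError, match="donor pool"):
            impute_pmm(task, donors=5)

    @pytest.mark.parametrize("seed", range(25))
    def test_confinement_to_observed_values(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        x = rng.standard_normal(n)
        y = list(2 * x + rng.standard_normal(n))
        miss = rng.choice(n, size=6, replace=False)
        observed = {v for i, v in enumerate(y) if i not in miss}
        for i in miss:
            y[i] = None
        task = numeric_xy_task(list(x), y, rng=rng)
        assert set(impute_pmm(task)) <= observed

    def test_binary_target_returns_levels(self):
        rng = np.random.default_rng(4)
        task = make_task(
            [VariableSpec("x", "numeric"), VariableSpec("g", "binary", ("A", "B"))],
            {"x": [-2, -1.5, -1, 1, 1.5, 2, -1.8],
             "g": ["A", "A", "A", "B", "B", "B", MISSING]},
            "g", rng=rng,
        )
        assert set(impute_pmm(task)) <= {"A", "B"}


class TestLogreg:
    def test_single_observed_class_fallback(self, caplog):
        task = make_task(
            [VariableSpec("x", "numeric"), VariableSpec("g", "binary", ("Male", "Female"))],
            {"x": [1, 2, 3, 4], "g": ["Male", "Male", "Male", MISSING]},
            "g",
        )
        with caplog.at_level("WARNING"):
            assert impute_logreg(task) == ["Male"]
        assert "one class" in caplog.text

    def test_separated_classes_recover_the_correct_side(self):
        # x < 0 -> A, x > 0 -> B; 20 training points, 200 missing at x = -5.
        rng = np.random.default_rng(1)
        x = list(np.linspace(-2, -0.1, 10)) + list(np.linspace(0.1, 2, 10)) + [-5.0] * 200
        g = ["A"] * 10 + ["B"] * 10 + [MISSING] * 200
        task = make_task(
            [VariableSpec("x", "numeric"), VariableSpec("g", "binary", ("A", "B"))],
            {"x": x, "g": g}, "g", rng=rng,
        )
        values = impute_logreg(task)
        assert np.mean([v == "A" for v in values]) >= 0.99

    def test_non_binary_target_rejected(self):
        task = make_task(
            [VariableSpec("x", "numeric"),
             VariableSpec("g", "nominal", ("a", "b", "c"))],
            {"x": [1, 2, 3, 4], "g": ["a", "b", "c", MISSING]}, "g",
        )
        with pytest.raises(ValueError, match="binary"):
            impute_logreg(task)


class TestPolyreg:
    def test_separated_clusters(self):
        rng = np.random.default_rng(2)
        centers = {"a": -10.0, "b": 0.0, "c": 10.0}
        x, g = [], []
        for label, c in centers.items():
            x += list(c + 0.1 * rng.standard_normal(15))
            g += [label] * 15
        x += [0.0] * 300
        g += [MISSING] * 300
        task = make_task(
            [VariableSpec("x", "numeric"), VariableSpec("g", "nominal", ("a", "b", "c"))],
            {"x": x, "g": g}, "g", rng=rng,
        )
        values = impute_polyreg(task)
        assert np.mean([v == "b" for v in values]) >= 0.99

    def test_uninformative_predictor_reproduces_observed_frequencies(self):
        # constant predictor: the multinomial fit reduces to the marginal
        # class frequencies, so draws are a plain multinomial sample
        rng = np.random.default_rng(3)
        freqs = {"a": 0.7, "b": 0.2, "c": 0.1}
        n_obs, n_mis = 100, 10_000
        g = (["a"] * 70 + ["b"] * 20 + ["c"] * 10) + [MISSING] * n_mis
        x = [1.0] * (n_obs + n_mis)
        task = make_task(
            [VariableSpec("x", "numeric"), VariableSpec("g", "nominal", ("a", "b", "c"))],
            {"x": x, "g": g}, "g", rng=rng,
        )
        values = impute_polyreg(task)
        for label, p in freqs.items():
            observed = np.mean([v == label for v in values])
            assert abs(observed - p) < 3 * np.sqrt(p * (1 - p) / n_mis) + 1e-3

    def test_single_class_degenerate(self):
        task = make_task(
            [VariableSpec("x", "numeric"), VariableSpec("g", "nominal", ("a", "b"))],
            {"x": [1, 2, 3], "g": ["a", "a", MISSING]}, "g",
        )
        assert impute_polyreg(task) == ["a"]


class TestLda:
    def test_well_separated_gaussians(self):
        rng = np.random.default_rng(5)
        x = list(-5 + rng.standard_normal(30)) + list(5 + rng.standard_normal(30))
        g = ["neg"] * 30 + ["pos"] * 30
        x += [-5.0] * 300
        g += [MISSING] * 300
        task = make_task(
            [VariableSpec("x", "numeric"), VariableSpec("g", "binary", ("neg", "pos"))],
            {"x": x, "g": g}, "g", rng=rng,
        )
        values = impute_lda(task)
        assert np.mean([v == "neg" for v in values]) >= 0.99

    def test_identical_class_distributions_draw_near_priors(self):
        # x carries no class signal, so posteriors hover at the 0.7/0.3 priors
        rng = np.random.default_rng(6)
        n_a, n_b, n_mis = 350, 150, 4000
        x = list(rng.standard_normal(n_a + n_b)) + list(rng.standard_normal(n_mis))
        g = ["a"] * n_a + ["b"] * n_b + [MISSING] * n_mis
        task = make_task(
            [VariableSpec("x", "numeric"), VariableSpec("g", "binary", ("a", "b"))],
            {"x": x, "g": g}, "g", rng=rng,
        )
        values = impute_lda(task)
        assert np.mean([v == "a" for v in values]) == pytest.approx(0.7, abs=0.06)

    def test_singleton_class_dropped(self, caplog):
        task = make_task(
            [VariableSpec("x", "numeric"), VariableSpec("g", "nominal", ("a", "b", "c"))],
            {"x": [-1, -2, 1, 2, 5, 0], "g": ["a", "a", "b", "b", "c", MISSING]},
            "g",
        )
        with caplog.at_level("WARNING"):
            values = impute_lda(task)
        assert "dropped" in caplog.text
        assert set(values) <= {"a", "b"}


# -- CART --------------------------------------------------------------------

def brute_force_best_split(X, y, min_leaf, kind):
    """Exhaustive first-split search: best weighted impurity decrease over
    every (feature, threshold-between-consecutive-values) candidate."""

    def impurity(vals):
        if kind == "numeric":
            return float(np.var(vals)) if len(vals) else 0.0
        _, counts = np.unique(vals, return_counts=True)
        p = counts / counts.sum()
        return float(1.0 - (p ** 2).sum())

    n = len(y)
    best = (-np.inf, None)
    for j in range(X.shape[1]):
        for thr in np.unique(X[:, j])[:-1]:
            left = X[:, j] <= thr
            nl, nr = int(left.sum()), int(n - left.sum())
            if nl < min_leaf or nr < min_leaf:
                continue
            decrease = impurity(y) - (nl / n) * impurity(y[left]) - (nr / n) * impurity(
                y[~left])
            if decrease > best[0] + 1e-12:
                best = (decrease, frozenset(np.flatnonzero(left)))
    return best


class TestCart:
    def test_pure_leaf_toy(self):
        rng = np.random.default_rng(7)
        x = [-4, -3, -2, -1, -0.5, 0.5, 1, 2, 3, 4, -5]
        g = ["A"] * 5 + ["B"] * 5 + [MISSING]
        task = make_task(
            [VariableSpec("x", "numeric"), VariableSpec("g", "binary", ("A", "B"))],
            {"x": x, "g": g}, "g", rng=rng,
        )
        for _ in range(20):
            assert impute_cart(task, min_leaf=2) == ["A"]

    def test_constant_target_single_leaf(self):
        task = numeric_xy_task([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11],
                               [42.0] * 10 + [None])
        assert impute_cart(task) == [42.0]

    def test_imputed_values_come_from_the_routed_leaf(self):
        rng = np.random.default_rng(8)
        x = list(np.arange(20.0)) + [2.0, 17.0]
        y = [float(v < 10) * 100 + v for v in range(20)] + [None, None]
        task = numeric_xy_task(x, y, rng=rng)
        model = fit_cart(task, min_leaf=5)
        X_mis = np.array([[2.0], [17.0]])
        leaves = model.tree.apply(X_mis)
        for _ in range(10):
            values = model.sample(X_mis, rng)
            for v, leaf in zip(values, leaves):
                assert v in model.leaf_values[int(leaf)]

    @pytest.mark.parametrize("kind", ["numeric", "categorical"])
    @pytest.mark.parametrize("seed", range(6))
    def test_first_split_matches_exhaustive_search(self, kind, seed):
        """On tiny inputs the greedy root split attains the exhaustively
        optimal impurity decrease (deviance for numeric, Gini for labels)."""
        rng = np.random.default_rng(seed)
        n, min_leaf = 12, 2
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        if kind == "numeric":
            y_obs = list(3 * x1 + rng.standard_normal(n))
            schema = [VariableSpec("x1", "numeric"), VariableSpec("x2", "numeric"),
                      VariableSpec("y", "numeric")]
            cols = {"x1": list(x1) + [0.0], "x2": list(x2) + [0.0],
                    "y": y_obs + [MISSING]}
        else:
            y_obs = ["p" if v > 0 else "q" for v in x1 + 0.3 * rng.standard_normal(n)]
            schema = [VariableSpec("x1", "numeric"), VariableSpec("x2", "numeric"),
                      VariableSpec("y", "nominal", ("p", "q"))]
            cols = {"x1": list(x1) + [0.0], "x2": list(x2) + [0.0],
                    "y": y_obs + [MISSING]}
        t = DataTable.from_columns(schema, cols)
        task = ImputationTask(t, "y", ["x1", "x2"], np.asarray(t.missing_mask("y")),
                              np.random.default_rng(seed))
        model = fit_cart(task, min_leaf=min_leaf)
        X = np.column_stack([x1, x2])
        y_arr = np.asarray(y_obs)
        best_decrease, _ = brute_force_best_split(X, y_arr, min_leaf, kind)
        root_feature = model.tree.tree_.feature[0]
        if root_feature < 0:  # no split improved: oracle must agree
            assert best_decrease == -np.inf or best_decrease <= 1e-12
            return
        thr = model.tree.tree_.threshold[0]
        left = X[:, root_feature] <= thr

        def impurity(vals):
            if kind == "numeric":
                return float(np.var(vals)) if len(vals) else 0.0
            _, counts = np.unique(vals, return_counts=True)
            p = counts / counts.sum()
            return float(1.0 - (p ** 2).sum())

        nl = int(left.sum())
        decrease = impurity(y_arr) - (nl / n) * impurity(y_arr[left]) \
            - ((n - nl) / n) * impurity(y_arr[~left])
        assert decrease == pytest.approx(best_decrease, abs=1e-9)


class TestBaselines:
    def test_mean_imputation_of_income_column(self, income_table):
        """(100+100+300+200+200)/5 = 180 fills both missing cells."""
        task = ImputationTask(
            income_table, "Income", ["Gender"],
            np.asarray(income_table.missing_mask("Income")),
            np.random.default_rng(0),
        )
        assert impute_baseline(task, "mean") == [180.0, 180.0]

    def test_mode_imputation_of_death_reason(self, death_table):
        task = ImputationTask(
            death_table, "DeathReason", ["Age"],
            np.asarray(death_table.missing_mask("DeathReason")),
            np.random.default_rng(0),
        )
        assert impute_baseline(task, "mode") == ["Cancer", "Cancer", "Cancer"]

    def test_single_observed_value_any_kind(self):
        for kind in ("mean", "median"):
            task = numeric_xy_task([1, 2, 3], [5.0, None, None])
            assert impute_baseline(task, kind) == [5.0, 5.0]
        task = make_task(
            [VariableSpec("x", "numeric"), VariableSpec("g", "binary", ("v", "w"))],
            {"x": [1, 2], "g": ["v", MISSING]}, "g",
        )
        assert impute_baseline(task, "mode") == ["v"]
        assert impute_baseline(task, "random") == ["v"]

    def test_type_mismatches_rejected(self, death_table, income_table):
        cat_task = ImputationTask(
            death_table, "DeathReason", ["Age"],
            np.asarray(death_table.missing_mask("DeathReason")),
            np.random.default_rng(0),
        )
        num_task = ImputationTask(
            income_table, "Income", ["Gender"],
            np.asarray(income_table.missing_mask("Income")),
            np.random.default_rng(0),
        )
        with pytest.raises(ValueError, match="numeric"):
            impute_baseline(cat_task, "mean")
        with pytest.raises(ValueError, match="categorical"):
            impute_baseline(num_task, "mode")


@pytest.mark.parametrize("method", ["pmm", "blr", "cart", "mean", "median", "random"])
def test_numeric_methods_are_deterministic_given_seed(method):
    rng_data = np.random.default_rng(9)
    x = list(rng_data.standard_normal(40))
    y = list(3 * np.asarray(x) + rng_data.standard_normal(40))
    for i in range(5):
        y[i] = None

    def run():
        return apply_method(method, numeric_xy_task(x, y, rng=np.random.default_rng(42)))

    assert run() == run()


@pytest.mark.parametrize("method", ["pmm", "logreg", "polyreg", "lda", "cart", "mode",
                                    "random"])
def test_categorical_methods_are_deterministic_and_level_confined(method):
    rng_data = np.random.default_rng(10)
    x = list(rng_data.standard_normal(40))
    g = ["A" if v + 0.5 * rng_data.standard_normal() > 0 else "B" for v in x]
    for i in range(5):
        g[i] = MISSING

    def run():
        return apply_method(
            method,
            make_task(
                [VariableSpec("x", "numeric"), VariableSpec("g", "binary", ("A", "B"))],
                {"x": x, "g": g}, "g", rng=np.random.default_rng(42),
            ),
        )

    first = run()
    assert first == run()
    assert set(first) <= {"A", "B"}
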