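"""Response-surface fitting, ANOVA lack-of-fit, prediction and desirability
optimization, checked against independent normal-equations / brute-force
oracles and closed forms."""

import numpy as np
import pytest

from doepk import (
    DesirabilityGoal,
    FactorDefinition,
    fit_quadratic,
    generate_fccd,
    optimize_desirability,
)
from doepk.rsm import (
    PureErrorUnavailable,
    QuadraticSurface,
    SingularFitError,
    anova_lack_of_fit,
    individual_desirability,
    overall_desirability,
    surface_grid,
)

from conftest import normal_equations_fit, quadratic_design_matrix_2f


class TestFitQuadratic:
    def test_reported_retention_time_coefficients(self, ccd_design, ccd_table):
        model = fit_quadratic(ccd_design, ccd_table["Y1"], "Y1")
        coefs = model.coefficients()
        assert coefs["b0"] == pytest.approx(4.931, abs=0.03 / 100 * 4.931)
        assert coefs["b1"] == pytest.approx(1.203, abs=5e-4)
        assert coefs["b2"] == pytest.approx(0.231, abs=1e-3)

    def test_reported_resolution_coefficients(self, ccd_design, ccd_table):
        coefs = fit_quadratic(ccd_design, ccd_table["Y2"], "Y2").coefficients()
        assert coefs["b0"] == pytest.approx(8.082, abs=0.03 / 100 * 8.082)
        assert coefs["b1"] == pytest.approx(0.268, abs=5e-4)
        assert coefs["b2"] == pytest.approx(0.700, abs=5e-4)

    @pytest.mark.parametrize("response", ["Y1", "Y2", "Y3"])
    def test_full_vector_matches_normal_equations_oracle(
        self, ccd_design, ccd_table, response
    ):
        model = fit_quadratic(ccd_design, ccd_table[response], response)
        M = quadratic_design_matrix_2f(ccd_table["A"], ccd_table["B"])
        oracle = normal_equations_fit(M, ccd_table[response])
        assert np.allclose(model.coef_, oracle, atol=1e-10)

    def test_noise_free_recovery_is_exact(self, two_unit_factors):
        design = generate_fccd(two_unit_factors, n_centre=5, seed=0)
        X = design[["A", "B"]].to_numpy()
        truth = np.array([4.931, 1.203, 0.231, 0.852, 3.539, 0.674])
        y = quadratic_design_matrix_2f(X[:, 0], X[:, 1]) @ truth
        model = QuadraticSurface("y").fit(X, y)
        assert np.allclose(model.coef_, truth, atol=1e-10)
        assert model.r_squared_ == pytest.approx(1.0)

    def test_linear_coefs_orthogonal_to_quadratic_terms(self, ccd_design, ccd_table):
        """On an FCCD the linear columns are orthogonal to everything else,
        so dropping the quadratic/interaction terms leaves b1, b2 unchanged
        and equal to sum(xi*y)/sum(xi^2)."""
        A = ccd_table["A"].to_numpy()
        B = ccd_table["B"].to_numpy()
        y = ccd_table["Y1"].to_numpy()
        full = fit_quadratic(ccd_design, y, "Y1").coef_
        linear_only = normal_equations_fit(
            np.column_stack([np.ones_like(A), A, B]), y
        )
        assert full[1] == pytest.approx(linear_only[1], abs=1e-10)
        assert full[2] == pytest.approx(linear_only[2], abs=1e-10)
        assert full[1] == pytest.approx(np.dot(A, y) / np.dot(A, A))

    def test_r_squared_non_decreasing_with_added_term(self, ccd_table):
        A = ccd_table["A"].to_numpy()
        B = ccd_table["B"].to_numpy()
        y = ccd_table["Y2"].to_numpy()

        def r2(M):
            beta = normal_equations_fit(M, y)
            resid = y - M @ beta
            return 1 - resid @ resid / np.sum((y - y.mean()) ** 2)

        M_small = np.column_stack([np.ones_like(A), A, B, A * B, A**2])
        M_full = np.column_stack([M_small, B**2])
        assert r2(M_full) >= r2(M_small) - 1e-12

    def test_unbiased_over_noisy_replicates(self, two_unit_factors):
        """Mean OLS estimate over 500 noisy surfaces sits within 3 Monte
        Carlo standard errors of the generating coefficients."""
        design = generate_fccd(two_unit_factors, n_centre=5, seed=1)
        X = design[["A", "B"]].to_numpy()
        M = quadratic_design_matrix_2f(X[:, 0], X[:, 1])
        truth = np.array([4.931, 1.203, 0.231, 0.852, 3.539, 0.674])
        rng = np.random.default_rng(2024)
        n_rep, sigma = 500, 0.3
        Y = (M @ truth)[:, None] + rng.normal(0, sigma, size=(len(M), n_rep))
        betas = np.linalg.lstsq(M, Y, rcond=None)[0]  # one solve, many RHS
        mean_est = betas.mean(axis=1)
        mc_se = betas.std(axis=1, ddof=1) / np.sqrt(n_rep)
        assert np.all(np.abs(mean_est - truth) <= 3 * mc_se + 1e-12)

    def test_rank_deficient_design_names_aliased_terms(self):
        X = np.array([[1.0, 1.0], [1, 1], [-1, -1], [-1, -1], [0, 0], [0, 0], [0.5, 0.5]])
        with pytest.raises(SingularFitError, match="aliased"):
            QuadraticSurface().fit(X, np.arange(7.0))

    def test_too_few_runs_rejected(self):
        X = np.array([[-1.0, -1], [1, -1], [-1, 1], [1, 1], [0, 0]])
        with pytest.raises(SingularFitError):
            QuadraticSurface().fit(X, np.arange(5.0))


class TestAnova:
    def test_table2_degrees_of_freedom(self, ccd_design, ccd_table):
        model = fit_quadratic(ccd_design, ccd_table["Y1"], "Y1")
        table = anova_lack_of_fit(model)
        assert table.loc["pure_error", "df"] == 4  # 5 centre replicates
        assert table.loc["lack_of_fit", "df"] == 13 - 6 - 4
        assert table.loc["total", "df"] == 12

    @pytest.mark.parametrize("response", ["Y1", "Y2", "Y3"])
    def test_sum_of_squares_identities(self, ccd_design, ccd_table, response):
        model = fit_quadratic(ccd_design, ccd_table[response], response)
        t = anova_lack_of_fit(model)
        assert t.loc["model", "ss"] + t.loc["residual", "ss"] == pytest.approx(
            t.loc["total", "ss"]
        )
        assert t.loc["lack_of_fit", "ss"] + t.loc["pure_error", "ss"] == pytest.approx(
            t.loc["residual", "ss"]
        )
        # pure error from a direct group-by-replicate oracle (centre points)
        centre = ccd_table.loc[ccd_table["point_type"] == "centre", response]
        ss_pe = np.sum((centre - centre.mean()) ** 2)
        assert t.loc["pure_error", "ss"] == pytest.approx(ss_pe)
        f_lof = (t.loc["lack_of_fit", "ss"] / t.loc["lack_of_fit", "df"]) / (
            t.loc["pure_error", "ss"] / t.loc["pure_error", "df"]
        )
        assert t.loc["lack_of_fit", "F"] == pytest.approx(f_lof)

    def test_perfect_fit_has_zero_residual(self, two_unit_factors):
        design = generate_fccd(two_unit_factors, n_centre=5, seed=0)
        X = design[["A", "B"]].to_numpy()
        y = quadratic_design_matrix_2f(X[:, 0], X[:, 1]) @ np.array(
            [1.0, 2, 3, 4, 5, 6]
        )
        model = QuadraticSurface().fit(X, y)
        table = anova_lack_of_fit(model)
        assert table.loc["residual", "ss"] == pytest.approx(0.0, abs=1e-18)
        assert model.r_squared_ == pytest.approx(1.0)

    def test_no_replicates_raises(self):
        X = np.array([
            [-1.0, -1], [1, -1], [-1, 1], [1, 1],
            [-1, 0], [1, 0], [0, -1], [0, 1], [0, 0],
        ])
        model = QuadraticSurface().fit(X, np.arange(9.0) ** 1.5)
        with pytest.raises(PureErrorUnavailable):
            anova_lack_of_fit(model)


class TestPredict:
    def test_origin_returns_intercept(self, ccd_design, ccd_table):
        model = fit_quadratic(ccd_design, ccd_table["Y1"], "Y1")
        assert model.predict([[0.0, 0.0]])[0] == pytest.approx(model.coef_[0])

    def test_pure_linear_model(self):
        model = QuadraticSurface()
        model.n_factors_ = 2
        model.coef_names_ = ["b0", "b1", "b2", "b12", "b11", "b22"]
        model.coef_ = np.array([0.0, 2.0, 0, 0, 0, 0])
        assert model.predict([[1.0, 0.0]])[0] == pytest.approx(2.0)

    def test_intercept_vs_centre_mean(self, ccd_design, ccd_table):
        """The quadratic-fit intercept sits within 0.2 of the centre-point
        mean retention time (4.782 min)."""
        model = fit_quadratic(ccd_design, ccd_table["Y1"], "Y1")
        centre_mean = ccd_table.loc[
            ccd_table["point_type"] == "centre", "Y1"
        ].mean()
        assert centre_mean == pytest.approx(4.782)
        assert abs(model.predict([[0.0, 0.0]])[0] - centre_mean) < 0.2

    def test_dimension_mismatch(self, ccd_design, ccd_table):
        model = fit_quadratic(ccd_design, ccd_table["Y1"], "Y1")
        with pytest.raises(ValueError):
            model.predict([[0.0, 0.0, 0.0]])


class TestSurfaceGrid:
    def test_constant_model_constant_grid(self):
        model = QuadraticSurface()
        model.n_factors_ = 2
        model.coef_names_ = ["b0", "b1", "b2", "b12", "b11", "b22"]
        model.coef_ = np.array([3.5, 0, 0, 0, 0, 0.0])
        grid = surface_grid(model, resolution=5)
        assert np.allclose(grid["prediction"], 3.5)
        assert len(grid) == 25

    def test_grid_matches_pointwise_predictions_at_corners(self, ccd_design, ccd_table):
        model = fit_quadratic(ccd_design, ccd_table["Y2"], "Y2")
        grid = surface_grid(model, resolution=2)
        corners = np.array([[-1.0, -1], [-1, 1], [1, -1], [1, 1]])
        expected = model.predict(corners)
        got = {
            (r.x1, r.x2): r.prediction for r in grid.itertuples()
        }
        for pt, val in zip(corners, expected):
            assert got[tuple(pt)] == pytest.approx(val)

    def test_fine_grid_max_approaches_analytic_stationary_point(self):
        # concave paraboloid with interior maximum at (0.25, -0.5)
        model = QuadraticSurface()
        model.n_factors_ = 2
        model.coef_names_ = ["b0", "b1", "b2", "b12", "b11", "b22"]
        b1, b2, b11, b22 = 1.0, -2.0, -2.0, -2.0
        model.coef_ = np.array([5.0, b1, b2, 0.0, b11, b22])
        x_star = np.array([-b1 / (2 * b11), -b2 / (2 * b22)])
        grid = surface_grid(model, resolution=401)
        best = grid.iloc[grid["prediction"].idxmax()]
        assert best["x1"] == pytest.approx(x_star[0], abs=2 / 400)
        assert best["x2"] == pytest.approx(x_star[1], abs=2 / 400)


def _model_from_coefs(coefs):
    m = QuadraticSurface(response_name=coefs.pop("name", "y"))
    m.n_factors_ = 2
    m.coef_names_ = ["b0", "b1", "b2", "b12", "b11", "b22"]
    m.coef_ = np.array([coefs.get(k, 0.0) for k in m.coef_names_])
    return m


class TestDesirability:
    def test_single_minimize_goal_finds_stationary_point(self):
        # convex paraboloid, interior minimum at (-0.25, 0.5)
        m = _model_from_coefs({"b0": 4.0, "b1": 1.0, "b2": -2.0, "b11": 2.0, "b22": 2.0})
        m.response_name = "Y1"
        x_star = np.array([-1.0 / 4.0, 2.0 / 4.0])
        goal = DesirabilityGoal("Y1", "minimize", low=3.0, high=10.0)
        res = optimize_desirability([m], [goal], resolution=201)
        assert res.coded[0] == pytest.approx(x_star[0], abs=2 / 200)
        assert res.coded[1] == pytest.approx(x_star[1], abs=2 / 200)

    def test_d_is_one_when_every_response_at_target(self):
        m1 = _model_from_coefs({"b0": 5.0})
        m1.response_name = "Y1"
        m2 = _model_from_coefs({"b0": 8.0})
        m2.response_name = "Y2"
        goals = [
            DesirabilityGoal("Y1", "target", low=4.0, high=6.0, target=5.0),
            DesirabilityGoal("Y2", "target", low=7.0, high=9.0, target=8.0),
        ]
        res = optimize_desirability([m1, m2], goals, resolution=11)
        assert res.desirability == pytest.approx(1.0)

    def test_grid_search_equals_brute_force_oracle(self, ccd_design, ccd_table):
        models = [
            (n, __import__("doepk").fit_quadratic(ccd_design, ccd_table[n], n))
            for n in ("Y1", "Y2", "Y3")
        ]
        fitted = [m for _, m in models]
        goals = [
            DesirabilityGoal("Y1", "minimize", low=4.0, high=12.0),
            DesirabilityGoal("Y2", "maximize", low=2.0, high=9.0),
            DesirabilityGoal("Y3", "target", low=0.8, high=1.8, target=1.0),
        ]
        resolution = 41
        res = optimize_desirability(fitted, goals, resolution=resolution)

        # exhaustive double loop, scalar desirability arithmetic
        axis = np.linspace(-1, 1, resolution)
        best_d, best_pt = -1.0, None
        by_name = dict(models)
        for x1 in axis:
            for x2 in axis:
                ds = []
                for g in goals:
                    v = by_name[g.response_name].predict([[x1, x2]])[0]
                    if g.direction == "minimize":
                        d = (g.high - v) / (g.high - g.low)
                    elif g.direction == "maximize":
                        d = (v - g.low) / (g.high - g.low)
                    elif v <= g.target:
                        d = (v - g.low) / (g.target - g.low)
                    else:
                        d = (g.high - v) / (g.high - g.target)
                    ds.append(min(max(d, 0.0), 1.0))
                D = 0.0 if 0.0 in ds else float(np.prod(ds)) ** (1 / len(ds))
                if D > best_d + 1e-15:
                    best_d, best_pt = D, (x1, x2)
        assert res.desirability == pytest.approx(best_d, abs=1e-12)
        assert res.coded[0] == pytest.approx(best_pt[0])
        assert res.coded[1] == pytest.approx(best_pt[1])

    def test_goal_order_and_uniform_weight_scaling_invariance(self, ccd_design, ccd_table):
        from doepk import fit_quadratic as fq

        fitted = [fq(ccd_design, ccd_table[n], n) for n in ("Y1", "Y2")]
        goals = [
            DesirabilityGoal("Y1", "minimize", low=4.0, high=12.0, weight=1.0),
            DesirabilityGoal("Y2", "maximize", low=2.0, high=9.0, weight=2.0),
        ]
        base = optimize_desirability(fitted, goals, resolution=51)
        flipped = optimize_desirability(fitted, goals[::-1], resolution=51)
        scaled = optimize_desirability(
            fitted,
            [DesirabilityGoal(g.response_name, g.direction, g.low, g.high,
                              g.target, g.weight * 7.0) for g in goals],
            resolution=51,
        )
        assert flipped.desirability == pytest.approx(base.desirability)
        assert scaled.desirability == pytest.approx(base.desirability)
        assert np.allclose(flipped.coded, base.coded)
        assert np.allclose(scaled.coded, base.coded)

    def test_all_zero_desirability_reported_not_raised(self):
        m = _model_from_coefs({"b0": 100.0})
        m.response_name = "Y1"
        goal = DesirabilityGoal("Y1", "minimize", low=0.0, high=1.0)
        res = optimize_desirability([m], [goal], resolution=11)
        assert res.all_zero
        assert res.desirability == 0.0

    def test_empty_goal_list_rejected(self):
        with pytest.raises(ValueError):
            optimize_desirability([], [], resolution=11)

    def test_individual_desirability_bounds(self):
        g = DesirabilityGoal("y", "maximize", low=0.0, high=1.0)
        v = np.linspace(-1, 2, 31)
        d = individual_desirability(v, g)
        assert np.all((d >= 0) & (d <= 1))

    def test_overall_zero_iff_some_d_zero(self):
        d = np.array([[0.5], [0.0]])
        assert overall_desirability(d)[0] == 0.0
        d = np.array([[0.5], [0.5]])
        assert overall_desirability(d)[0] == pytest.approx(0.5)
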