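import numpy as np
import pytest

from floatdoe.doe import (
    ResponseModel,
    ValidationSet,
    build_ccf_design,
    build_ffd_design,
    fit_response_model,
    predict_dissolution,
    predict_f2,
    rmsep,
    solve_hpmc_threshold,
)
from floatdoe.errors import ValidationError
from floatdoe.synthetic import evaluate_actual_equation, generate_doe_dataset

FFD_RANGES = (50.0, 250.0, 5.0, 25.0)


def fit_three(design, df, model_type="linear"):
    return [
        fit_response_model(design, df[r].to_numpy(), model_type, response_id=r)
        for r in ("R1", "R2", "R3")
    ]


class TestDesignConstruction:
    def test_ffd_two_replicates_two_centers_is_10_runs(self):
        d = build_ffd_design(FFD_RANGES, replicates=2, center_points=2, seed=0)
        assert d.n_runs == 10
        corners = d.points[~d.points["is_center"]]
        assert len(corners.drop_duplicates(["A_mg", "B_pct"])) == 4

    def test_ffd_minimal_is_4_corners(self):
        d = build_ffd_design(FFD_RANGES, replicates=1, center_points=0, seed=0)
        assert d.n_runs == 4
        assert set(map(tuple, d.points[["a_coded", "b_coded"]].values)) == {
            (-1, -1), (-1, 1), (1, -1), (1, 1)
        }

    def test_ccf_two_centers_is_10_points(self, ccf_design):
        assert ccf_design.n_runs == 10
        axial = ccf_design.points[
            (~ccf_design.points["is_center"])
            & ((ccf_design.points["a_coded"] == 0) | (ccf_design.points["b_coded"] == 0))
        ]
        assert len(axial) == 4
        # every axial point has exactly one coded coordinate at zero
        for _, row in axial.iterrows():
            assert (row["a_coded"] == 0) != (row["b_coded"] == 0)

    def test_ccf_axial_point_actual_units(self):
        d = build_ccf_design((150, 250, 15, 25), center_points=2, seed=3)
        pt = d.points[(d.points["a_coded"] == 0) & (d.points["b_coded"] == -1)]
        assert pt[["A_mg", "B_pct"]].values.tolist() == [[200.0, 15.0]]

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValidationError):
            build_ffd_design((150, 150, 5, 25))

    def test_run_order_randomized_but_content_stable(self):
        d1 = build_ccf_design(FFD_RANGES, seed=1)
        d2 = build_ccf_design(FFD_RANGES, seed=2)
        assert not (d1.points["run"] == d2.points["run"]).all()
        assert sorted(d1.points["run"]) == sorted(d2.points["run"])


class TestModelFitting:
    def test_noiseless_recovery_of_actual_equations(
        self, ccf_design, noiseless_responses, actual_equations
    ):
        for model in fit_three(ccf_design, noiseless_responses):
            truth = actual_equations[model.response_id]
            for term, value in truth.items():
                assert model.actual_coeffs[term] == pytest.approx(value, abs=1e-9)
            assert model.r_squared == pytest.approx(100.0, abs=1e-6)

    def test_coded_and_actual_forms_agree_at_design_points(
        self, ccf_design, noiseless_responses
    ):
        pts = ccf_design.points
        for model in fit_three(ccf_design, noiseless_responses, "quadratic"):
            actual = model.predict(pts["A_mg"], pts["B_pct"])
            coded = model.predict_coded(pts["a_coded"], pts["b_coded"])
            np.testing.assert_allclose(actual, coded, atol=1e-9)

    def test_ols_matches_normal_equations_oracle(self, ccf_design, rng):
        y = rng.normal(50, 5, ccf_design.n_runs)
        model = fit_response_model(ccf_design, y, "quadratic", "R1")
        a = ccf_design.points["a_coded"].to_numpy()
        b = ccf_design.points["b_coded"].to_numpy()
        X = np.column_stack([np.ones_like(a), a, b, a * b, a**2, b**2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        got = [model.coded_coeffs[t] for t in ("intercept", "A", "B", "AB", "A2", "B2")]
        np.testing.assert_allclose(got, beta, atol=1e-9)

    def test_quadratic_generator_needs_quadratic_model(self, ccf_design):
        coeffs = {"R1": {"intercept": 40.0, "A": -0.03, "B": -0.5, "A2": 0.001}}
        df = generate_doe_dataset(coeffs, ccf_design, noise_sd=0.0)
        quad = fit_response_model(ccf_design, df["R1"].to_numpy(), "quadratic")
        lin = fit_response_model(ccf_design, df["R1"].to_numpy(), "linear")
        assert quad.actual_coeffs["A2"] == pytest.approx(0.001, abs=1e-9)
        assert quad.r_squared == pytest.approx(100.0, abs=1e-6)
        assert lin.r_squared < quad.r_squared

    def test_constant_response_flagged(self, ccf_design):
        model = fit_response_model(ccf_design, np.full(10, 42.0), "linear")
        assert model.degenerate
        assert model.coded_coeffs["A"] == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(model.p_values["model"])

    def test_rank_deficiency_names_the_term(self):
        # FFD corners only: a*a == 1 everywhere, collinear with the intercept
        d = build_ffd_design(FFD_RANGES, replicates=2, center_points=0, seed=0)
        with pytest.raises(ValidationError, match="A2"):
            fit_response_model(d, np.arange(8.0), "quadratic")

    def test_model_p_value_significant_for_real_signal(
        self, ccf_design, actual_equations
    ):
        df = generate_doe_dataset(actual_equations, ccf_design, noise_sd=0.3, seed=9)
        model = fit_response_model(ccf_design, df["R1"].to_numpy(), "linear", "R1")
        assert model.p_values["model"] < 0.05
        assert model.adj_r_squared <= model.r_squared

    def test_coefficients_within_3_se_under_noise(self, ccf_design, actual_equations):
        rng = np.random.default_rng(11)
        hits = 0
        total = 0
        truth = actual_equations["R1"]
        for _ in range(200):
            df = generate_doe_dataset(
                {"R1": truth}, ccf_design, noise_sd=1.0,
                seed=int(rng.integers(2**31)),
            )
            y = df["R1"].to_numpy()
            model = fit_response_model(ccf_design, y, "linear", "R1")
            a = ccf_design.points["a_coded"].to_numpy()
            b = ccf_design.points["b_coded"].to_numpy()
            X = np.column_stack([np.ones_like(a), a, b])
            resid = y - X @ np.array(
                [model.coded_coeffs[t] for t in ("intercept", "A", "B")]
            )
            sigma2 = resid @ resid / (len(y) - 3)
            se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
            # compare in coded units where the truth is exactly known
            dA = (ccf_design.factor_ranges[1] - ccf_design.factor_ranges[0]) / 2
            dB = (ccf_design.factor_ranges[3] - ccf_design.factor_ranges[2]) / 2
            true_coded_A = truth["A"] * dA
            true_coded_B = truth["B"] * dB
            for est, tr, s in [
                (model.coded_coeffs["A"], true_coded_A, se[1]),
                (model.coded_coeffs["B"], true_coded_B, se[2]),
            ]:
                total += 1
                hits += abs(est - tr) <= 3 * s
        assert hits / total >= 0.95


class TestPrediction:
    def test_predicted_profile_matches_direct_evaluation(
        self, ccf_design, noiseless_responses, actual_equations
    ):
        models = fit_three(ccf_design, noiseless_responses)
        pred = predict_dissolution(models, 150, 17)
        expected = [
            evaluate_actual_equation(actual_equations[r], 150, 17)
            for r in ("R1", "R2", "R3")
        ]
        np.testing.assert_allclose(pred.values, expected, atol=1e-9)
        assert not pred.clipped

    def test_clipping_flagged(self, ccf_design, noiseless_responses):
        models = fit_three(ccf_design, noiseless_responses)
        pred = predict_dissolution(models, 0.0, 0.0)  # intercepts > 100 for R3
        assert pred.extrapolated and pred.clipped
        assert pred.r3 == 100.0

    def test_predicted_f2_identity_and_value(
        self, ccf_design, noiseless_responses
    ):
        models = fit_three(ccf_design, noiseless_responses)
        pred = predict_dissolution(models, 150, 17)
        assert predict_f2(models, 150, 17, pred.values) == pytest.approx(100.0)
        # independent hand evaluation of the similarity transform
        d = pred.values - np.array([30, 60, 80])
        expected = 100 - 25 * np.log10(1 + np.mean(d**2))
        assert predict_f2(models, 150, 17, [30, 60, 80]) == pytest.approx(
            expected, abs=1e-9
        )

    def test_f2_increases_with_hpmc_at_150mg_cetyl(
        self, ccf_design, noiseless_responses
    ):
        models = fit_three(ccf_design, noiseless_responses)
        low = predict_f2(models, 150, 15, [30, 60, 80])
        high = predict_f2(models, 150, 25, [30, 60, 80])
        assert high > low


class TestThreshold:
    def test_bisection_matches_closed_form_root(
        self, ccf_design, noiseless_responses, actual_equations
    ):
        models = fit_three(ccf_design, noiseless_responses)
        got = solve_hpmc_threshold(models, 150, [30, 60, 80], 50)
        # oracle: f2 = 50 iff sum of squared differences = 3 * 99; the three
        # differences are linear in B, so solve the quadratic exactly
        ref = np.array([30.0, 60.0, 80.0])
        c0 = np.array(
            [
                evaluate_actual_equation(actual_equations[r], 150, 0)
                for r in ("R1", "R2", "R3")
            ]
        ) - ref
        c1 = np.array([actual_equations[r]["B"] for r in ("R1", "R2", "R3")])
        # sum (c0_i + c1_i B)^2 = 297
        coeffs = [np.sum(c1**2), 2 * np.sum(c0 * c1), np.sum(c0**2) - 297.0]
        roots = np.roots(coeffs)
        root = min(r for r in roots.real if 15 <= r <= 25)
        assert got == pytest.approx(root, abs=1e-3)
        assert got == pytest.approx(16.92, abs=0.01)

    def test_no_crossing_raises_with_bracket_values(
        self, ccf_design, noiseless_responses
    ):
        models = fit_three(ccf_design, noiseless_responses)
        with pytest.raises(ValidationError, match="does not cross"):
            solve_hpmc_threshold(models, 150, [30, 60, 80], cutoff=100)

    def test_bracket_choice_does_not_move_the_root(
        self, ccf_design, noiseless_responses
    ):
        models = fit_three(ccf_design, noiseless_responses)
        a = solve_hpmc_threshold(models, 150, [30, 60, 80], 50, b_range=(15, 25))
        b = solve_hpmc_threshold(models, 150, [30, 60, 80], 50, b_range=(16, 20))
        assert a == pytest.approx(b, abs=2e-4)


class TestRmsep:
    def test_perfect_prediction_gives_zero(self):
        assert rmsep(ValidationSet([1, 2, 3], [1, 2, 3])) == 0.0

    def test_hand_computed_value(self):
        assert rmsep(ValidationSet([1, 2, 3], [2, 2, 2])) == pytest.approx(
            np.sqrt(2 / 3), abs=1e-12
        )

    def test_pairing_order_invariance(self, rng):
        y = rng.normal(size=10)
        yhat = y + rng.normal(size=10)
        perm = rng.permutation(10)
        assert rmsep(ValidationSet(y, yhat)) == pytest.approx(
            rmsep(ValidationSet(y[perm], yhat[perm])), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            ValidationSet([1, 2], [1])

    def test_linear_truth_favors_linear_model_on_holdout(
        self, ccf_design, actual_equations
    ):
        # generating R3 from the linear equation plus noise, the linear fit
        # predicts the six external-validation compositions (cetyl 150/200/250
        # mg at the low HPMC levels 5/10 %) better than the quadratic fit in
        # the vast majority of repeats
        rng = np.random.default_rng(5)
        truth = {"R3": actual_equations["R3"]}
        A_ext = np.array([150, 150, 200, 200, 250, 250], float)
        B_ext = np.array([5, 10, 5, 10, 5, 10], float)
        y_true = evaluate_actual_equation(actual_equations["R3"], A_ext, B_ext)
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            df = generate_doe_dataset(
                truth, ccf_design, noise_sd=1.0, seed=int(rng.integers(2**31))
            )
            y = df["R3"].to_numpy()
            lin = fit_response_model(ccf_design, y, "linear", "R3")
            quad = fit_response_model(ccf_design, y, "quadratic", "R3")
            e_lin = rmsep(ValidationSet(y_true, lin.predict(A_ext, B_ext)))
            e_quad = rmsep(ValidationSet(y_true, quad.predict(A_ext, B_ext)))
            wins += e_lin < e_quad
        assert wins / n_rep >= 0.90
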