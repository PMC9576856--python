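"""Factorial design, effects, correlations, convergence arithmetic."""

import numpy as np
import pandas as pd
import pytest

from tonosim import doe
from tonosim.errors import ConfigError
from tonosim.fixtures import FixtureSpec, doe_response_table, generate_fixture


class TestFullFactorial:
    def test_five_factors_give_32_runs(self):
        design = doe.full_factorial(doe.FactorSpec.defaults())
        assert len(design) == 32
        assert len(design.drop_duplicates()) == 32

    def test_single_factor(self):
        design = doe.full_factorial([doe.FactorSpec("IOP", 8, 22)])
        assert len(design) == 2
        assert sorted(design["IOP"]) == [8, 22]

    def test_balance(self):
        design = doe.full_factorial(doe.FactorSpec.defaults())
        for f in doe.FACTOR_NAMES:
            counts = design[f"{f}_coded"].value_counts()
            assert counts[1] == 16 and counts[-1] == 16

    def test_duplicate_names_rejected(self):
        with pytest.raises(ConfigError):
            doe.full_factorial([doe.FactorSpec("IOP", 8, 22),
                                doe.FactorSpec("IOP", 9, 21)])


class TestMainEffects:
    def test_pure_linear_model(self):
        """y = 2 x_IOP (coded) -> IOP effect 4, all others 0."""
        design, responses = doe_response_table(
            coefficients=(0, 0, 0, 0, 2.0), intercept=0.0)
        eff = doe.main_effects(design, responses,
                               response_cols=["response"])
        main = eff[eff["kind"] == "main"].set_index("source")["effect"]
        assert main["IOP"] == pytest.approx(4.0)
        for f in ("C10_c", "k1", "k2", "C10_s"):
            assert main[f] == pytest.approx(0.0, abs=1e-12)

    def test_constant_response(self):
        design, responses = doe_response_table(
            coefficients=(0, 0, 0, 0, 0), intercept=5.0)
        eff = doe.main_effects(design, responses,
                               response_cols=["response"])
        assert np.allclose(eff["effect"], 0.0)

    def test_pure_interaction(self):
        design, responses = doe_response_table(
            coefficients=(0, 0, 0, 0, 0), intercept=0.0,
            interactions={("C10_c", "IOP"): 1.5})
        eff = doe.main_effects(design, responses,
                               response_cols=["response"])
        main = eff[eff["kind"] == "main"]["effect"]
        assert np.allclose(main, 0.0, atol=1e-12)
        inter = eff[eff["source"] == "C10_c*IOP"]["effect"].iloc[0]
        assert inter == pytest.approx(3.0)

    def test_generative_coefficients_recovered(self):
        coef = (-2.0, 0.0, 0.0, -0.5, -4.0)
        design, responses = doe_response_table(coefficients=coef)
        eff = doe.main_effects(design, responses,
                               response_cols=["response"])
        main = eff[eff["kind"] == "main"].set_index("source")["effect"]
        for name, c in zip(doe.FACTOR_NAMES, coef):
            assert main[name] == pytest.approx(2 * c, abs=1e-12)

    def test_contrasts_equal_regression_coefficients(self):
        """Independent oracle: effects = 2 x coded-OLS coefficients."""
        rng = np.random.default_rng(0)
        design, responses = doe_response_table(
            coefficients=(-1.0, 0.3, 0.7, -0.2, -3.0), noise=0.2, seed=4)
        eff = doe.main_effects(design, responses,
                               response_cols=["response"])
        main = eff[eff["kind"] == "main"].set_index("source")["effect"]
        X = design[[f"{f}_coded" for f in doe.FACTOR_NAMES]].to_numpy(float)
        X1 = np.column_stack([np.ones(len(X)), X])
        beta, *_ = np.linalg.lstsq(X1, responses["response"].to_numpy(),
                                   rcond=None)
        for j, name in enumerate(doe.FACTOR_NAMES):
            assert main[name] == pytest.approx(2 * beta[j + 1], rel=1e-10)


class TestPearson:
    def test_self_correlation_and_exact_negative(self):
        design, responses = doe_response_table(
            coefficients=(0, 0, 0, 0, -1.0), intercept=0.0)
        corr = doe.pearson_matrix(design, responses,
                                  response_cols=["response"])
        assert corr.loc["IOP", "IOP"] == pytest.approx(1.0)
        assert corr.loc["IOP", "response"] == pytest.approx(-1.0)
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T,
                           equal_nan=True)
        vals = corr.to_numpy()
        assert np.nanmax(np.abs(vals)) <= 1.0 + 1e-12

    def test_zero_variance_flagged_nan(self):
        design, responses = doe_response_table(
            coefficients=(0, 0, 0, 0, 0), intercept=1.0)
        corr = doe.pearson_matrix(design, responses,
                                  response_cols=["response"])
        assert np.isnan(corr.loc["IOP", "response"])


class TestMeshConvergenceError:
    def test_arithmetic(self):
        assert doe.mesh_convergence_error(1.01, 1.00) \
            == pytest.approx(1.0)
        assert doe.mesh_convergence_error(1.00, 1.00) == 0.0
        assert doe.mesh_convergence_error(0.99, 1.00) \
            == pytest.approx(1.0)
        with pytest.raises(ZeroDivisionError):
            doe.mesh_convergence_error(1.0, 0.0)

    def test_report_builds_pairwise_errors(self):
        rep = doe.MeshConvergenceReport(n_thickness=[3, 4, 5],
                                        apex_displacement=[1.10, 1.08, 1.081])
        assert rep.errors_percent[0] == pytest.approx(100 * 0.02 / 1.10)
        assert rep.errors_percent[1] == pytest.approx(100 * 0.001 / 1.08)


class TestAblationReport:
    def test_identical_models_zero_differences(self):
        same = {"max_iop": 21.0, "deflection_amplitude": 1.1,
                "peak_distance": 5.7}
        rep = doe.ablation_compare(lambda flag: dict(same))
        assert rep.max_difference_percent == 0.0

    def test_run_batch_keeps_failures(self):
        design = doe.full_factorial([doe.FactorSpec("IOP", 8, 22)])

        def runner(row):
            if row["IOP"] > 10:
                from tonosim.errors import ConvergenceError
                raise ConvergenceError("boom")
            return {"deflection_amplitude": 1.0}

        responses = doe.run_batch(design, runner)
        assert len(responses) == 2
        assert responses["failed"].sum() == 1
        assert "boom" in responses.loc[responses["failed"],
                                       "failure"].iloc[0]


class TestReducedRange:
    def test_same_machinery_and_synthetic_recovery(self):
        """The physiological-IOP study reuses the factorial machinery
        (32 rows, IOP narrowed to 12-15 mmHg) and recovers the
        coefficients of a constructed generative model."""
        coef = dict(zip(doe.FACTOR_NAMES, (-1.0, -0.1, -0.3, -1.0, -0.8)))

        def design_runner(design):
            coded = design[[f"{f}_coded" for f in doe.FACTOR_NAMES]]
            y = sum(coef[f] * coded[f"{f}_coded"] for f in doe.FACTOR_NAMES)
            return pd.DataFrame({"deflection_amplitude": y + 1.1,
                                 "peak_distance": 2 * y + 5.5,
                                 "failed": False}, index=design.index)

        design, responses, effects = doe.reduced_range_study(design_runner)
        assert len(design) == 32
        assert sorted(design["IOP"].unique()) == [12.0, 15.0]
        main = effects[(effects["kind"] == "main")
                       & (effects["response"] == "deflection_amplitude")]
        main = main.set_index("source")["effect"]
        for f in doe.FACTOR_NAMES:
            assert main[f] == pytest.approx(2 * coef[f], abs=1e-12)
        assert (main < 0).all()     # inverse influence of every factor


class TestFixtures:
    def test_same_seed_bit_identical(self):
        a = doe_response_table(noise=0.3, seed=9)[1]["response"].to_numpy()
        b = doe_response_table(noise=0.3, seed=9)[1]["response"].to_numpy()
        assert np.array_equal(a, b)
        c = doe_response_table(noise=0.3, seed=10)[1]["response"].to_numpy()
        assert not np.array_equal(a, c)

    def test_generate_fixture_dispatch(self):
        df = generate_fixture(FixtureSpec(kind="stress_strain_curves",
                                          seed=1))
        assert set(df.columns) == {"stretch", "stress_MPa",
                                   "orientation_deg"}
        with pytest.raises(ValueError):
            FixtureSpec(kind="nope")
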