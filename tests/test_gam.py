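"""Tests for the penalized-spline GAM engine."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from patsep.gam import GAM, compare_models, fit_model, parse_formula, power_from_n, power_sample_size
from patsep.gam.basis import SplineBasis, difference_penalty, row_kron

from conftest import make_linear_data


class TestFormulaGrammar:
    def test_term_kinds(self):
        spec = parse_formula(
            "ldi ~ s(age) + te(v, age) + ti(w, age) + s(age, by=x) + sex + a:b"
        )
        kinds = [t.kind for t in spec.terms]
        assert kinds == ["smooth", "tensor", "ti", "varying", "linear", "product"]
        assert spec.outcome == "ldi"
        assert spec.terms[3].by == "x"

    def test_basis_dimension_options(self):
        spec = parse_formula("y ~ s(x, k=20) + te(a, b, k=7)")
        assert spec.terms[0].k == (20,)
        assert spec.terms[1].k == (7, 7)

    @pytest.mark.parametrize(
        "bad",
        [
            "y ~ s(x) + s(x)",  # duplicate
            "y ~ x + s(x)",  # linear and smooth main effect
            "y ~ s(x, span=2)",  # unknown option
            "y ~ 2x",  # unparseable token
            "y + x",  # no tilde
        ],
    )
    def test_malformed_formulas_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)


class TestBasis:
    def test_partition_of_unity(self):
        x = np.linspace(0, 1, 57)
        B = SplineBasis.from_data(x, 10).design(x)
        assert B.shape == (57, 10)
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_difference_penalty_annihilates_linear(self):
        S = difference_penalty(8)
        lin = np.arange(8, dtype=float)
        assert np.allclose(S @ lin, 0.0)
        assert np.allclose(S @ np.ones(8), 0.0)

    def test_row_kron_shape_and_values(self):
        a = np.array([[1.0, 2.0]])
        b = np.array([[3.0, 4.0, 5.0]])
        assert np.allclose(row_kron(a, b), [[3, 4, 5, 6, 8, 10]])


class TestFitting:
    def test_linear_limit_matches_ols(self):
        """Infinite smoothing collapses a smooth to the least-squares line."""
        d = make_linear_data(n=200, slope=2.0, noise=0.3, seed=1)
        res = GAM(d, "y ~ s(x)").fit(lambdas=[1e8])
        X = np.column_stack([np.ones(len(d)), d.x])
        beta = np.linalg.lstsq(X, d.y, rcond=None)[0]
        ols_fit = X @ beta
        assert np.max(np.abs(res.fittedvalues - ols_fit)) < 1e-6 * np.abs(ols_fit).max()
        assert res.edf_by_term["s(x)"] == pytest.approx(1.0, abs=1e-4)

    def test_noise_free_linear_reml_collapses(self):
        d = make_linear_data(n=200, slope=2.0, noise=0.0)
        res = GAM(d, "y ~ s(x)").fit()
        assert res.edf_by_term["s(x)"] == pytest.approx(1.0, abs=0.05)
        pred = res.predict(pd.DataFrame({"x": [0.25, 0.75]}))
        assert np.allclose(pred, [1.5, 2.5], atol=1e-5)

    def test_sine_recovery(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 2 * np.pi, 500)
        d = pd.DataFrame({"x": x, "y": np.sin(x)})
        res = GAM(d, "y ~ s(x, k=20)").fit()
        assert np.sqrt(np.mean((res.fittedvalues - np.sin(x)) ** 2)) < 1e-2

    def test_refit_is_deterministic(self):
        d = make_linear_data(n=150, noise=0.5, seed=3)
        r1 = fit_model(d, "y ~ s(x)")
        r2 = fit_model(d, "y ~ s(x)")
        assert r1.aic == r2.aic
        assert np.array_equal(r1.params, r2.params)

    def test_edf_bounds_and_cov_psd(self, cohort500):
        res = GAM(cohort500, "ldi ~ s(age) + sex + education").fit()
        edf = res.edf_by_term["s(age)"]
        assert 1.0 - 1e-6 <= edf <= 9.0  # basis_dim - 1
        ev = np.linalg.eigvalsh(res.cov_params())
        assert ev.min() > -1e-12 * max(ev.max(), 1.0)
        assert np.isfinite(res.aic)

    def test_gcv_option_fits(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 300)
        d = pd.DataFrame({"x": x, "y": np.sin(6 * x) + rng.normal(0, 0.2, 300)})
        res = GAM(d, "y ~ s(x)").fit(method="gcv")
        assert 2.0 < res.edf_by_term["s(x)"] < 9.0

    def test_varying_coefficient_recovery(self):
        """s(age, by=x) recovers a known linear-in-age coupling."""
        rng = np.random.default_rng(5)
        age = rng.uniform(20, 70, 800)
        x = rng.normal(0, 1, 800)
        y = 0.1 + (0.5 - 0.01 * age) * x + rng.normal(0, 0.3, 800)
        d = pd.DataFrame({"age": age, "x": x, "y": y})
        res = GAM(d, "y ~ s(age) + s(age, by=x)").fit()
        grid = np.linspace(25, 65, 9)
        hi = res.predict(pd.DataFrame({"age": grid, "x": 1.0}))
        lo = res.predict(pd.DataFrame({"age": grid, "x": 0.0}))
        assert np.max(np.abs((hi - lo) - (0.5 - 0.01 * grid))) < 0.08

    def test_tensor_bilinear_closed_form(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(20, 70, 400)
        m = rng.uniform(-2, 2, 400)
        d = pd.DataFrame({"a": a, "m": m, "y": 0.01 * a * m})
        res = GAM(d, "y ~ te(m, a)").fit(lambdas=[0.0])
        assert np.max(np.abs(res.resid)) < 1e-8
        # REML leaves only a negligible smoothing bias on noise-free data
        res_reml = GAM(d, "y ~ te(m, a)").fit()
        assert np.max(np.abs(res_reml.resid)) < 1e-3 * d.y.std()


def test_recovers_generating_age_function(cfg):
    """The fitted LDI-on-age smooth tracks the generator's mean function
    g(age) across the observed age support on a large cohort."""
    from patsep.cohort import simulate_cohort

    df = simulate_cohort(cfg, seed=55, n=5000)
    res = GAM(df, "ldi ~ s(age)").fit()
    g = np.asarray(cfg.ldi_model.g(df.age))
    assert np.max(np.abs(res.fittedvalues - g)) < 0.02


class TestErrors:
    def test_non_finite_data_rejected(self):
        d = make_linear_data(50)
        d.loc[3, "y"] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            GAM(d, "y ~ s(x)")

    def test_rank_deficient_design_names_term(self):
        d = make_linear_data(100)
        d["x2"] = 2 * d.x
        with pytest.raises(ValueError, match="rank-deficient"):
            GAM(d, "y ~ x + x2")

    def test_too_small_sample_rejected(self):
        d = make_linear_data(8)
        with pytest.raises(ValueError, match="basis dimension"):
            GAM(d, "y ~ s(x)")

    def test_missing_variable_rejected(self):
        d = make_linear_data(50)
        with pytest.raises(ValueError, match="not in data"):
            GAM(d, "y ~ s(z)")

    def test_unknown_categorical_level_in_predict(self, cohort500):
        res = GAM(cohort500, "ldi ~ age + sex").fit()
        bad = pd.DataFrame({"age": [40.0], "sex": ["other"]})
        with pytest.raises(ValueError, match="unknown level"):
            res.predict(bad)


class TestPrediction:
    def test_exact_at_training_points_when_noise_free(self):
        d = make_linear_data(n=100, slope=3.0)
        res = GAM(d, "y ~ x").fit()
        assert np.allclose(res.predict(d), d.y, atol=1e-8)

    def test_se_smaller_at_center_than_edge(self):
        d = make_linear_data(n=200, noise=1.0, seed=7)
        res = GAM(d, "y ~ s(x)").fit()
        out = res.predict(pd.DataFrame({"x": [0.5, 0.999]}), se=True)
        assert out["se"][0] < out["se"][1]

    def test_extrapolation_flagged_not_rejected(self):
        d = make_linear_data(n=100)
        res = GAM(d, "y ~ s(x)").fit()
        out = res.predict(pd.DataFrame({"x": [0.5, 1.7]}), se=True)
        assert not out["extrapolated"][0] and out["extrapolated"][1]
        assert np.isfinite(out["mean"]).all()

    def test_pointwise_interval_coverage(self):
        """95% intervals cover the true curve at about the nominal rate."""
        rng = np.random.default_rng(8)
        grid = pd.DataFrame({"x": np.linspace(0.05, 0.95, 40)})
        truth = np.sin(3 * grid.x.to_numpy())
        hits = []
        for _ in range(120):
            x = rng.uniform(0, 1, 250)
            y = np.sin(3 * x) + rng.normal(0, 0.3, 250)
            res = GAM(pd.DataFrame({"x": x, "y": y}), "y ~ s(x)").fit()
            out = res.predict(grid, se=True)
            lo = out["mean"] - 1.96 * out["se"]
            hi = out["mean"] + 1.96 * out["se"]
            hits.append(np.mean((lo <= truth) & (truth <= hi)))
        assert np.mean(hits) == pytest.approx(0.95, abs=0.04)


class TestModelSelection:
    def test_identical_fits_are_degenerate(self):
        d = make_linear_data(n=150, noise=0.5, seed=9)
        r1 = GAM(d, "y ~ x").fit()
        r2 = GAM(d, "y ~ x").fit()
        c = compare_models(r1, r2)
        assert c.degenerate and c.selected == "linear"
        assert c.delta_aic == pytest.approx(0.0, abs=1e-10)

    def test_strong_quadratic_selects_smooth(self):
        rng = np.random.default_rng(10)
        picks = []
        for _ in range(30):
            x = rng.uniform(-1, 1, 300)
            y = x**2 * 3 + rng.normal(0, 0.5, 300)
            d = pd.DataFrame({"x": x, "y": y})
            c = compare_models(GAM(d, "y ~ x").fit(), GAM(d, "y ~ s(x)").fit())
            picks.append(c.selected == "smooth")
        assert sum(picks) >= 28

    def test_mismatched_fits_rejected(self, cohort500):
        a = GAM(cohort500, "ldi ~ age").fit()
        b = GAM(cohort500, "crs ~ s(age)").fit()
        with pytest.raises(ValueError, match="different outcomes"):
            compare_models(a, b)


class TestAgainstMgcv:
    def test_penalized_fit_matches_mgcv(self, tmp_path):
        """Independent oracle: R mgcv P-spline fit on the same data."""
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 1, 200)
        y = np.sin(2 * np.pi * x) + rng.normal(0, 0.3, 200)
        csv = tmp_path / "d.csv"
        pd.DataFrame({"x": x, "y": y}).to_csv(csv, index=False)
        out = tmp_path / "fit.csv"
        script = (
            f'd <- read.csv("{csv}"); '
            'm <- mgcv::gam(y ~ s(x, k=10, bs="ps", m=c(2,2)), data=d, method="REML"); '
            f'write.csv(data.frame(fit=fitted(m), edf=sum(m$edf)), "{out}", row.names=FALSE)'
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out)
        res = GAM(pd.DataFrame({"x": x, "y": y}), "y ~ s(x)").fit()
        rmse = np.sqrt(np.mean((res.fittedvalues - ref.fit.to_numpy()) ** 2))
        assert rmse < 0.01 * np.std(y)
        assert res.total_edf == pytest.approx(ref.edf[0], abs=0.5)


class TestPower:
    def test_matches_study_scale_sample_size(self):
        assert power_sample_size(0.221, 0.05, 0.80, 3) == 38
        assert power_sample_size(0.221, 0.05, 0.80, 3, convention="regression") == 38

    def test_monotone_in_effect_size(self):
        sizes = [power_sample_size(r2, 0.05, 0.8, 3) for r2 in (0.1, 0.2, 0.4, 0.999)]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] == 4  # minimal admissible design

    def test_power_increases_with_n(self):
        p = [power_from_n(n, 0.2, 0.05, 2, n - 3) for n in (10, 20, 40, 80)]
        assert p == sorted(p)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"r_squared": 1.2},
            {"r_squared": 0.2, "alpha": 0.0},
            {"r_squared": 0.2, "power": 1.0},
            {"r_squared": 0.2, "n_groups": 1},
            {"r_squared": 0.2, "convention": "bayes"},
        ],
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            power_sample_size(**kwargs)
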