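"""OLS with standardized betas, diagnostics, and FDR screening."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from qvburden.regression import (
    Covariate,
    ModelSpec,
    breusch_pagan,
    durbin_watson,
    fit_mlr,
    model_screen,
    vif,
)


def frame(**cols):
    n = len(next(iter(cols.values())))
    return pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])


def spec(dep="y", covs=(("x1", "continuous"), ("x2", "continuous")),
         family="f"):
    return ModelSpec(dependent=dep,
                     covariates=tuple(Covariate(n, k) for n, k in covs),
                     family_id=family)


class TestFitMLR:
    def test_exact_linear_relation(self, rng):
        x1 = rng.normal(size=50)
        x2 = rng.normal(size=50)
        data = frame(y=2 * x1, x1=x1, x2=x2)
        res = fit_mlr(spec(), data)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        beta = res.coef.set_index("covariate")["beta"]
        assert beta["x1"] == pytest.approx(1.0, abs=1e-8)
        assert beta["x2"] == pytest.approx(0.0, abs=1e-8)

    def test_r2_equals_squared_correlation_of_fitted(self, rng):
        x1, x2 = rng.normal(size=120), rng.normal(size=120)
        y = 0.5 * x1 - 0.2 * x2 + rng.normal(size=120)
        data = frame(y=y, x1=x1, x2=x2)
        res = fit_mlr(spec(), data)
        yz = (y - y.mean()) / y.std(ddof=1)
        X = sm.add_constant(np.column_stack([
            (x1 - x1.mean()) / x1.std(ddof=1), (x2 - x2.mean()) / x2.std(ddof=1)]))
        fitted = X @ np.linalg.lstsq(X, yz, rcond=None)[0]
        assert res.r_squared == pytest.approx(np.corrcoef(fitted, yz)[0, 1] ** 2,
                                              abs=1e-10)

    def test_standardized_beta_equals_raw_times_sd_ratio(self, rng):
        x1, x2 = rng.normal(2, 3, 150), rng.normal(size=150)
        y = 10 + 1.7 * x1 + rng.normal(size=150)
        data = frame(y=y, x1=x1, x2=x2)
        res = fit_mlr(spec(), data)
        raw = sm.OLS(y, sm.add_constant(np.column_stack([x1, x2]))).fit()
        expected = raw.params[1] * x1.std(ddof=1) / y.std(ddof=1)
        beta = res.coef.set_index("covariate")["beta"]
        assert beta["x1"] == pytest.approx(expected, abs=1e-10)

    def test_adding_covariate_never_decreases_r2(self, rng):
        x1, x2 = rng.normal(size=80), rng.normal(size=80)
        y = 0.4 * x1 + rng.normal(size=80)
        data = frame(y=y, x1=x1, x2=x2, x3=rng.normal(size=80))
        r2_small = fit_mlr(spec(), data).r_squared
        r2_big = fit_mlr(spec(covs=(("x1", "continuous"), ("x2", "continuous"),
                                    ("x3", "continuous"))), data).r_squared
        assert r2_big >= r2_small - 1e-12

    def test_null_model_f_p_roughly_uniform(self):
        ps = []
        for rep in range(200):
            rng = np.random.default_rng(3000 + rep)
            data = frame(y=rng.normal(size=60), x1=rng.normal(size=60),
                         x2=rng.normal(size=60))
            ps.append(fit_mlr(spec(), data).f_pvalue)
        assert abs(np.mean(ps) - 0.5) < 0.08
        assert (np.array(ps) < 0.05).mean() < 0.12

    def test_rank_deficiency_names_columns(self, rng):
        x1 = rng.normal(size=40)
        data = frame(y=rng.normal(size=40), x1=x1, x2=2 * x1)
        with pytest.raises(ValueError, match="x"):
            fit_mlr(spec(), data)

    def test_dummy_entered_as_coded(self, rng):
        sex = np.array([1, 2] * 30)
        y = 5.0 - 1.0 * sex + rng.normal(0, 0.1, 60)
        data = frame(y=y, sex=sex.astype(float), x=rng.normal(size=60))
        res = fit_mlr(spec(covs=(("sex", "dummy"), ("x", "continuous"))), data)
        beta = res.coef.set_index("covariate")["beta"]
        # coefficient of the raw dummy on z-scored y: -1 / sd(y)
        assert beta["sex"] == pytest.approx(-1.0 / y.std(ddof=1), rel=0.05)


class TestDiagnostics:
    def test_dw_constant_residuals(self):
        assert durbin_watson([1.0, 1.0, 1.0]) == 0.0

    def test_dw_alternating(self):
        assert durbin_watson([1.0, -1.0, 1.0, -1.0]) == pytest.approx(3.0)

    def test_dw_white_noise_near_two(self):
        rng = np.random.default_rng(8)
        assert durbin_watson(rng.normal(size=1000)) == pytest.approx(2.0, abs=0.15)

    def test_dw_zero_residuals_undefined(self):
        with pytest.raises(ValueError):
            durbin_watson([0.0, 0.0, 0.0])

    def test_bp_hand_computed_lm(self, rng):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([0.1, -0.2, 0.3, -0.1, 0.2, -0.3])
        X = sm.add_constant(x)
        aux = sm.OLS(e ** 2, X).fit()
        res = breusch_pagan(e, X)
        assert res.statistic == pytest.approx(len(e) * aux.rsquared, rel=1e-9)

    def test_bp_perfect_aux_fit(self, rng):
        x = rng.normal(size=30)
        e = np.sqrt(np.abs(x - x.min() + 0.1))  # e^2 exactly linear in x
        res = breusch_pagan(e, sm.add_constant(x))
        assert res.statistic == pytest.approx(len(e), rel=1e-6)

    def test_bp_homoscedastic_calibration(self):
        ps = []
        for rep in range(200):
            rng = np.random.default_rng(500 + rep)
            x = rng.normal(size=100)
            X = sm.add_constant(x)
            e = rng.normal(size=100)
            ps.append(breusch_pagan(e, X).p_value)
        assert abs(np.mean(ps) - 0.5) < 0.08

    def test_vif_orthogonal_columns(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        design = pd.DataFrame({"const": 1.0, "x1": x1, "x2": x2})
        v = vif(design)
        assert np.allclose(v, 1.0)

    def test_vif_closed_form_at_correlation_08(self):
        # build two exactly 0.8-correlated unit vectors
        n = 100
        rng = np.random.default_rng(11)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)  # orthogonalize
        b /= b.std()
        x2 = 0.8 * a + np.sqrt(1 - 0.64) * b
        design = pd.DataFrame({"const": 1.0, "x1": a, "x2": x2})
        v = vif(design)
        assert v["x1"] == pytest.approx(1 / (1 - 0.64), rel=1e-6)

    def test_vif_duplicated_covariate_infinite(self):
        x = np.arange(10.0)
        design = pd.DataFrame({"const": 1.0, "x1": x, "x2": x})
        v = vif(design)
        assert np.isinf(v).any() or (v > 1e10).any()


class TestScreen:
    def _results(self, p_r2, p_cov, family="f"):
        out = []
        for i, (pr, pc) in enumerate(zip(p_r2, p_cov)):
            coef = pd.DataFrame({"covariate": ["qv_count"], "beta": [0.1],
                                 "ci_low": [0.0], "ci_high": [0.2], "p": [pc]})
            out.append(type("R", (), {
                "family_id": family, "dependent": f"y{i}", "n": 100,
                "r_squared": 0.1, "f_pvalue": pr, "coef": coef,
                "durbin_watson": 2.0, "dw_in_range": True,
                "breusch_pagan_p": 0.5, "max_vif": 1.0, "shapiro_p": 0.5})())
        return out

    def test_all_ones_nothing_flagged(self):
        table = model_screen(self._results([1.0] * 4, [1.0] * 4))
        assert not table["significant"].any()
        assert not table["r2_significant"].any()

    def test_planted_strong_effects_all_flagged(self):
        p_r2 = [1e-4] * 10 + [0.8] * 95
        p_cov = [1e-4] * 10 + [0.8] * 95
        table = model_screen(self._results(p_r2, p_cov))
        strong = table[table["p"] <= 1e-4]
        assert strong["significant"].all()
        assert strong["r2_significant"].all()

    def test_screen_equals_bh_per_family(self):
        from qvburden.stats_core import bh_fdr

        p_cov = [0.01, 0.2, 0.04, 0.9]
        results = (self._results([0.5] * 2, p_cov[:2], family="A")
                   + self._results([0.5] * 2, p_cov[2:], family="B"))
        table = model_screen(results)
        for fam, ps in (("A", p_cov[:2]), ("B", p_cov[2:])):
            q, _ = bh_fdr(ps, threshold=0.1)
            got = table[table["family_id"] == fam]["q"].to_numpy()
            assert np.allclose(np.sort(got), np.sort(q))


class TestRecoverySimulation:
    def test_known_beta_recovered_and_covered(self):
        # standardized genetic beta -0.4, n=300: CI coverage near 95%
        cover = 0
        reps = 60
        for rep in range(reps):
            rng = np.random.default_rng(7000 + rep)
            x = rng.poisson(1.2, 300).astype(float)
            sex = rng.integers(1, 3, 300).astype(float)
            age = rng.normal(50, 15, 300)
            xz = (x - x.mean()) / x.std(ddof=1)
            y = -0.4 * xz + np.sqrt(1 - 0.16) * rng.normal(size=300)
            data = frame(y=y, qv=x, sex=sex, age=age)
            res = fit_mlr(spec(covs=(("sex", "dummy"), ("age", "continuous"),
                                     ("qv", "continuous"))), data)
            row = res.coef.set_index("covariate").loc["qv"]
            cover += row["ci_low"] <= -0.4 <= row["ci_high"]
        assert cover / reps >= 0.85
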