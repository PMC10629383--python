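import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import gammaln

from skystrip.count_models import (
    backward_select,
    build_design,
    effect_ratio,
    fit_tweedie,
    fit_ztp,
    profile_power,
    rtweedie,
    tweedie_unit_deviance,
    wald_table,
    ztp_loglik,
)


def make_tweedie_data(rng, n=2000, power=1.6, phi=1.0,
                      beta=(0.3, 0.29, -0.4), heterogeneity=0.0):
    platform = rng.integers(0, 2, n)
    vis = rng.integers(1, 3, n)
    area = rng.uniform(0.5, 2.0, n)
    flight = rng.integers(0, 4, n)
    transect = rng.integers(0, 3, n)
    eta = (
        beta[0]
        + beta[1] * platform
        + beta[2] * (vis == 2)
        + np.log(area)
        + heterogeneity * rng.standard_normal(4)[flight]
    )
    y = rtweedie(rng, np.exp(eta), power, phi)
    return pd.DataFrame(
        dict(
            count=y,
            platform=np.where(platform == 1, "imagery", "observer"),
            visibility=vis,
            area=area,
            flight_id=flight,
            transect_id=transect,
        )
    )


class TestTweedieFit:
    def test_intercept_mean_matching(self, rng):
        y = rng.poisson(3.0, 500).astype(float)
        df = pd.DataFrame(dict(count=y, area=np.ones(500)))
        fit = fit_tweedie(df, "count", [], power=1.5)
        assert math.exp(fit.beta[0]) == pytest.approx(y.mean(), rel=1e-6)

    def test_offset_identity(self, rng):
        df = make_tweedie_data(rng, n=800)
        fit1 = fit_tweedie(df, "count", ["platform"], power=1.6)
        df2 = df.assign(area=df.area * 2)
        fit2 = fit_tweedie(df2, "count", ["platform"], power=1.6)
        assert fit2.beta[0] == pytest.approx(fit1.beta[0] - math.log(2), abs=1e-6)
        assert fit2.beta[1] == pytest.approx(fit1.beta[1], abs=1e-8)

    def test_matches_statsmodels(self, rng):
        df = make_tweedie_data(rng, n=1000)
        fit = fit_tweedie(df, "count", ["platform", "visibility"], power=1.6)
        X, _, _ = build_design(df, ["platform", "visibility"])
        ref = sm.GLM(
            df["count"].to_numpy(),
            X,
            family=sm.families.Tweedie(var_power=1.6, link=sm.families.links.Log()),
            offset=np.log(df.area.to_numpy()),
        ).fit()
        assert fit.beta == pytest.approx(ref.params, abs=1e-6)
        assert fit.se == pytest.approx(ref.bse, rel=1e-3)

    def test_poisson_limit_agreement(self, rng):
        # Tweedie with power -> 1 on Poisson data ~ Poisson GLM coefficients
        n = 1500
        x = rng.integers(0, 2, n)
        area = np.ones(n)
        y = rng.poisson(np.exp(0.5 + 0.3 * x)).astype(float)
        df = pd.DataFrame(dict(count=y, x=x, area=area))
        fit = fit_tweedie(df, "count", ["x"], power=1.001)
        ref = sm.GLM(y, sm.add_constant(x.astype(float)),
                     family=sm.families.Poisson()).fit()
        assert fit.beta == pytest.approx(ref.params, abs=1e-3)

    def test_coefficient_recovery(self):
        """beta-hat within 3 SE of truth in >=95% of seeds (2000 segments)."""
        hits = 0
        n_seeds = 60
        truth = (0.3, 0.29, -0.4)
        for s in range(n_seeds):
            rng = np.random.default_rng(9000 + s)
            df = make_tweedie_data(rng, n=2000, beta=truth)
            fit = fit_tweedie(df, "count", ["platform", "visibility"], power=1.6)
            idx = {nm: i for i, nm in enumerate(fit.names)}
            ok = (
                abs(fit.beta[idx["platform[observer]"]] + truth[1])
                < 3 * fit.se[idx["platform[observer]"]]
            ) and (
                abs(fit.beta[idx["visibility[2]"]] - truth[2])
                < 3 * fit.se[idx["visibility[2]"]]
            )
            hits += ok
        assert hits / n_seeds >= 0.90

    def test_negative_response_errors(self):
        df = pd.DataFrame(dict(count=[-1.0, 2.0], area=[1.0, 1.0]))
        with pytest.raises(ValueError):
            fit_tweedie(df, "count", [], power=1.5)

    def test_all_zero_flagged(self):
        df = pd.DataFrame(dict(count=np.zeros(50), area=np.ones(50)))
        with pytest.warns(UserWarning):
            fit = fit_tweedie(df, "count", [], power=1.5)
        assert fit.beta[0] < -5

    def test_bad_power_errors(self, rng):
        df = make_tweedie_data(rng, n=50)
        for p in (1.0, 2.0, 2.5):
            with pytest.raises(ValueError):
                fit_tweedie(df, "count", [], power=p)


class TestRandomEffects:
    def test_null_heterogeneity_variance_near_zero(self):
        meds = []
        for s in range(10):
            rng = np.random.default_rng(400 + s)
            df = make_tweedie_data(rng, n=600, heterogeneity=0.0)
            fit = fit_tweedie(df, "count", ["platform"], power=1.6,
                              random_effects=True)
            meds.append(fit.var_flight)
        assert np.median(meds) < 0.1 * 1.0  # well below residual scale

    def test_heterogeneity_detected(self):
        rng = np.random.default_rng(41)
        df = make_tweedie_data(rng, n=1500, heterogeneity=0.8)
        fit = fit_tweedie(df, "count", ["platform"], power=1.6, random_effects=True)
        assert fit.var_flight > 0.05

    def test_fixed_effects_close_to_glm(self, rng):
        df = make_tweedie_data(rng, n=800, heterogeneity=0.0)
        fe = fit_tweedie(df, "count", ["platform"], power=1.6)
        re = fit_tweedie(df, "count", ["platform"], power=1.6, random_effects=True)
        assert re.beta[1] == pytest.approx(fe.beta[1], abs=0.02)


class TestProfilePower:
    def test_recovers_power(self):
        rng = np.random.default_rng(11)
        df = make_tweedie_data(rng, n=3000, power=1.5)
        best, prof = profile_power(df, "count", ["platform"],
                                   grid=np.round(np.arange(1.2, 1.85, 0.05), 3))
        assert abs(best - 1.5) <= 0.1

    def test_poisson_data_lower_edge(self, rng):
        n = 2000
        y = rng.poisson(3.0, n).astype(float)
        df = pd.DataFrame(dict(count=y, area=np.ones(n)))
        grid = np.round(np.arange(1.2, 1.85, 0.1), 2)
        with pytest.warns(UserWarning):
            best, _ = profile_power(df, "count", [], grid=grid)
        assert best == grid[0]

    def test_gamma_data_upper_edge(self, rng):
        n = 2000
        y = rng.gamma(2.0, 1.5, n)
        df = pd.DataFrame(dict(count=y, area=np.ones(n)))
        grid = np.round(np.arange(1.2, 1.85, 0.1), 2)
        with pytest.warns(UserWarning):
            best, _ = profile_power(df, "count", [], grid=grid)
        assert best == grid[-1]

    def test_bad_grid_errors(self, rng):
        df = make_tweedie_data(rng, n=100)
        with pytest.raises(ValueError):
            profile_power(df, "count", [], grid=np.array([0.9, 1.5]))


class TestZTP:
    @staticmethod
    def brute_loglik(y, lam):
        """Independent oracle: truncated pmf summed term by term."""
        total = 0.0
        for yi, li in zip(y, lam):
            log_pmf = yi * math.log(li) - li - gammaln(yi + 1)
            total += log_pmf - math.log(1 - math.exp(-li))
        return total

    def test_loglik_matches_brute_force(self, rng):
        y = rng.integers(1, 8, 30).astype(float)
        lam = rng.uniform(0.5, 4.0, 30)
        assert ztp_loglik(y, lam) == pytest.approx(
            self.brute_loglik(y, lam), abs=1e-10
        )

    def test_intercept_recovery(self, rng):
        from skystrip.synthetic_data import zt_poisson_sizes

        sizes = zt_poisson_sizes(rng, 2.0, 5000)
        df = pd.DataFrame(dict(size=sizes))
        fit = fit_ztp(df, "size", [])
        lam_hat = math.exp(fit.beta[0])
        assert abs(lam_hat - 2.0) < 3 * fit.se[0] * lam_hat

    def test_fitted_mean_equals_sample_mean(self, rng):
        from skystrip.synthetic_data import zt_poisson_sizes

        sizes = zt_poisson_sizes(rng, 1.3, 2000)
        fit = fit_ztp(pd.DataFrame(dict(size=sizes)), "size", [])
        lam = math.exp(fit.beta[0])
        assert lam / (1 - math.exp(-lam)) == pytest.approx(sizes.mean(), rel=1e-8)

    def test_covariate_effect_recovery(self, rng):
        from skystrip.synthetic_data import zt_poisson_sizes

        n = 3000
        x = rng.integers(0, 2, n)
        sizes = np.where(
            x == 1, zt_poisson_sizes(rng, 2.5, n), zt_poisson_sizes(rng, 1.5, n)
        )
        df = pd.DataFrame(dict(size=sizes, x=x))
        fit = fit_ztp(df, "size", ["x"])
        assert abs(fit.beta[1] - math.log(2.5 / 1.5)) < 3 * fit.se[1]

    def test_all_ones_boundary(self):
        with pytest.warns(UserWarning):
            fit = fit_ztp(pd.DataFrame(dict(size=np.ones(30))), "size", [])
        assert fit.extras["boundary"]

    def test_below_one_errors(self):
        with pytest.raises(ValueError):
            fit_ztp(pd.DataFrame(dict(size=[0, 2])), "size", [])


class TestBackwardSelection:
    def test_strong_term_retained(self, rng):
        df = make_tweedie_data(rng, n=1500, beta=(0.3, 1.0, -0.4))
        fit, path = backward_select(
            df, "count", ["platform", "visibility"], fit_tweedie, power=1.6
        )
        kept = [t.name for t in fit.terms]
        assert "platform" in kept

    def test_noise_removed_at_type_one_rate(self):
        removed = 0
        n_reps = 100
        for s in range(n_reps):
            rng = np.random.default_rng(7000 + s)
            df = make_tweedie_data(rng, n=400, beta=(0.5, 0.0, 0.0))
            df["noise"] = rng.standard_normal(len(df))
            fit, path = backward_select(df, "count", ["noise"], fit_tweedie, power=1.6)
            removed += "noise" in path
        assert removed / n_reps >= 0.90  # ~95% expected at alpha=0.05

    def test_marginality_interaction_first(self, rng):
        df = make_tweedie_data(rng, n=1000, beta=(0.5, 0.0, 0.0))
        fit, path = backward_select(
            df, "count", ["platform", "visibility", "platform:visibility"],
            fit_tweedie, power=1.6,
        )
        if "platform:visibility" in path and (
            "platform" in path or "visibility" in path
        ):
            assert path.index("platform:visibility") < min(
                path.index(t) for t in ("platform", "visibility") if t in path
            )


class TestEffectRatio:
    def _fit(self, rng):
        df = make_tweedie_data(rng, n=500)
        return fit_tweedie(df, "count", ["platform"], power=1.6)

    def test_zero_beta_is_100(self, rng):
        fit = self._fit(rng)
        fit.beta[1] = 0.0
        assert effect_ratio(fit, fit.names[1])["ratio_pct"] == pytest.approx(100.0)

    def test_reference_arithmetic(self, rng):
        fit = self._fit(rng)
        fit.beta[1] = 0.2927
        fit.vcov[1, 1] = 0.16**2
        out = effect_ratio(fit, fit.names[1])
        assert out["ratio_pct"] == pytest.approx(134.0, abs=0.1)
        assert out["lo_pct"] == pytest.approx(98.0, abs=0.5)
        assert out["hi_pct"] == pytest.approx(183.5, abs=0.5)

    def test_log_two_halving(self, rng):
        fit = self._fit(rng)
        fit.beta[1] = -math.log(2)
        assert effect_ratio(fit, fit.names[1])["ratio_pct"] == pytest.approx(50.0)

    def test_absent_term_errors(self, rng):
        with pytest.raises(KeyError):
            effect_ratio(self._fit(rng), "nope")


class TestDeviance:
    def test_zero_response_term(self):
        d = tweedie_unit_deviance(np.array([0.0]), np.array([2.0]), 1.5)
        assert d[0] == pytest.approx(2 * 2.0**0.5 / 0.5, rel=1e-12)

    def test_zero_at_saturation(self):
        y = np.array([1.0, 3.0, 0.5])
        assert tweedie_unit_deviance(y, y, 1.5) == pytest.approx([0, 0, 0], abs=1e-12)

    def test_rtweedie_moments(self, rng):
        mu, p, phi = 3.0, 1.5, 1.2
        y = rtweedie(rng, np.full(40000, mu), p, phi)
        assert y.mean() == pytest.approx(mu, rel=0.02)
        assert y.var() == pytest.approx(phi * mu**p, rel=0.05)
        assert (y == 0).mean() == pytest.approx(
            math.exp(-(mu ** (2 - p)) / (phi * (2 - p))), abs=0.01
        )
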