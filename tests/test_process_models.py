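"""Fitters, AIC comparison, and parameter derivation.

The WLS solutions are checked against an independently coded
normal-equations solver, and the coefficient conventions against
noise-free synthetic designs where recovery must be exact.
"""

import numpy as np
import pytest

from taxadyn.process_models import (
    FitError,
    compare_models,
    derive_neutral_params,
    extract_competition_params,
    fit_combined,
    fit_consumer_resource,
    fit_neutral,
)

from conftest import brute_force_wls, make_dataset, synthetic_design


class TestNoiseFreeRecovery:
    def test_consumer_resource_exact(self):
        rng = np.random.default_rng(1)
        inv_x, inv_xr, R, dt = synthetic_design(rng, 50)
        y = 0.5 + 2.0 * R[:, 0]
        ds = make_dataset(response=y, inv_x=inv_x, inv_xr=inv_xr, resources=R, dt=dt)
        fit = fit_consumer_resource(ds)
        assert fit.k0 == pytest.approx(0.5, abs=1e-8)
        assert fit.k1[0] == pytest.approx(2.0, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_neutral_exact(self):
        rng = np.random.default_rng(2)
        inv_x, inv_xr, R, dt = synthetic_design(rng, 50)
        y = -0.1 + 0.3 * inv_x - 0.2 * inv_xr
        ds = make_dataset(response=y, inv_x=inv_x, inv_xr=inv_xr, resources=R, dt=dt)
        fit = fit_neutral(ds)
        assert fit.k0 == pytest.approx(-0.1, abs=1e-8)
        assert fit.k2 == pytest.approx(0.3, abs=1e-8)
        assert fit.k3 == pytest.approx(-0.2, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_combined_exact(self):
        rng = np.random.default_rng(3)
        inv_x, inv_xr, R, dt = synthetic_design(rng, 50)
        y = 0.0 + 1.0 * R[:, 0] + 0.5 * inv_x - 0.5 * inv_xr
        ds = make_dataset(response=y, inv_x=inv_x, inv_xr=inv_xr, resources=R, dt=dt)
        fit = fit_combined(ds)
        assert fit.k0 == pytest.approx(0.0, abs=1e-8)
        assert fit.k1[0] == pytest.approx(1.0, abs=1e-8)
        assert fit.k2 == pytest.approx(0.5, abs=1e-8)
        assert fit.k3 == pytest.approx(-0.5, abs=1e-8)


class TestOracleEquivalence:
    def test_wls_matches_brute_force_normal_equations(self):
        """Fitted coefficients equal the hand-rolled WLS solve to 1e-10."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(8, 21))
            J = int(rng.integers(1, 3))
            inv_x, inv_xr, R, dt = synthetic_design(rng, n, J)
            y = rng.normal(size=n)
            ds = make_dataset(
                response=y, inv_x=inv_x, inv_xr=inv_xr, resources=R, dt=dt
            )
            design = np.column_stack([np.ones(n), R, inv_x, inv_xr])
            expected = brute_force_wls(design, y, ds.weights)
            fit = fit_combined(ds)
            got = np.concatenate([[fit.k0], fit.k1, [fit.k2], [fit.k3]])
            np.testing.assert_allclose(got, expected, atol=1e-10, rtol=1e-8)
            # and the OLS fitter against unit weights
            expected_ols = brute_force_wls(
                design[:, : J + 1], y, np.ones(n)
            )
            cr = fit_consumer_resource(ds)
            np.testing.assert_allclose(
                np.concatenate([[cr.k0], cr.k1]), expected_ols, atol=1e-10, rtol=1e-8
            )

    def test_equal_weights_reduce_wls_to_ols(self):
        """dt proportional to 2/X_i + 2/X_r makes all weights equal, so the
        weighted fit must coincide with the unweighted solve."""
        rng = np.random.default_rng(7)
        n = 30
        inv_x, inv_xr, R, _ = synthetic_design(rng, n)
        dt = 0.5 * (2 * inv_x + 2 * inv_xr)
        y = rng.normal(size=n)
        ds = make_dataset(response=y, inv_x=inv_x, inv_xr=inv_xr, resources=R, dt=dt)
        assert np.ptp(ds.weights) < 1e-12
        fit = fit_neutral(ds)
        design = np.column_stack([np.ones(n), inv_x, inv_xr])
        expected = brute_force_wls(design, y, np.ones(n))
        np.testing.assert_allclose([fit.k0, fit.k2, fit.k3], expected, atol=1e-10)


class TestContracts:
    def test_constant_resource_rank_deficiency_named(self):
        rng = np.random.default_rng(5)
        inv_x, inv_xr, _, dt = synthetic_design(rng, 20)
        R = np.full((20, 1), 2.0)
        ds = make_dataset(
            response=rng.normal(size=20), inv_x=inv_x, inv_xr=inv_xr, resources=R, dt=dt
        )
        with pytest.raises(FitError, match="R\\[res0\\]"):
            fit_consumer_resource(ds)

    def test_too_few_observations(self):
        rng = np.random.default_rng(6)
        inv_x, inv_xr, R, dt = synthetic_design(rng, 3)
        ds = make_dataset(
            response=rng.normal(size=3), inv_x=inv_x, inv_xr=inv_xr, resources=R, dt=dt
        )
        with pytest.raises(FitError, match=">="):
            fit_neutral(ds)

    def test_aic_identity(self):
        rng = np.random.default_rng(8)
        inv_x, inv_xr, R, dt = synthetic_design(rng, 40)
        ds = make_dataset(
            response=rng.normal(size=40), inv_x=inv_x, inv_xr=inv_xr, resources=R, dt=dt
        )
        for fit in (fit_neutral(ds), fit_consumer_resource(ds), fit_combined(ds)):
            assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)


class TestNesting:
    def test_combined_r2_at_least_neutral_r2(self):
        """The neutral model is the k1 = 0 restriction of the combined model
        under identical weights, so weighted r2 cannot decrease."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(12, 60))
            inv_x, inv_xr, R, dt = synthetic_design(rng, n)
            y = rng.normal(size=n) + 0.1 * inv_x
            ds = make_dataset(
                response=y, inv_x=inv_x, inv_xr=inv_xr, resources=R, dt=dt
            )
            assert fit_combined(ds).r2 >= fit_neutral(ds).r2 - 1e-12


class TestCompareModels:
    def _fits(self, aics, n_params=(4, 3, 5), n_obs=30):
        from taxadyn.process_models import ModelFit

        kinds = ("neutral", "consumer_resource", "combined")
        return [
            ModelFit(
                model_kind=k,
                taxon_id="t",
                k0=0.0,
                k1=np.zeros(1),
                k2=0.0,
                k3=0.0,
                n_obs=n_obs,
                n_params=p,
                r2=0.0,
                loglik=0.0,
                aic=a,
            )
            for k, a, p in zip(kinds, aics, n_params)
        ]

    def test_lowest_aic_wins(self):
        assert compare_models(self._fits((100, 95, 97))) == "consumer_resource"

    def test_tie_broken_toward_fewer_parameters(self):
        fits = self._fits((90, 95, 90), n_params=(4, 3, 5))
        assert compare_models(fits) == "neutral"

    def test_different_n_obs_rejected(self):
        fits = self._fits((1, 2, 3))
        fits[1].n_obs = 10
        with pytest.raises(ValueError, match="observation"):
            compare_models(fits)


class TestDeriveNeutralParams:
    def _neutral_fit(self, k2, a_hat):
        from taxadyn.process_models import ModelFit

        return ModelFit(
            model_kind="neutral",
            taxon_id="t",
            k0=0.0,
            k1=np.empty(0),
            k2=k2,
            k3=0.0,
            n_obs=30,
            n_params=4,
            r2=0.5,
            loglik=0.0,
            aic=0.0,
            a_hat=a_hat,
        )

    def test_inversion(self):
        p = derive_neutral_params(self._neutral_fit(-0.8, 1.0), 0.1)
        assert p.lambda_p_product == pytest.approx(0.2)
        assert p.lambda_i == pytest.approx(2.0)
        assert p.neutral_compatible

    def test_k2_zero(self):
        p = derive_neutral_params(self._neutral_fit(0.0, 2.0), 0.5)
        assert p.lambda_p_product == pytest.approx(1.0)
        assert p.lambda_i == pytest.approx(2.0)

    def test_negative_product_flagged(self):
        p = derive_neutral_params(self._neutral_fit(-1.2, 1.0), 0.1)
        assert p.lambda_p_product == pytest.approx(-0.2)
        assert p.lambda_i == 0.0
        assert not p.neutral_compatible

    def test_invalid_abundance_rejected(self):
        with pytest.raises(ValueError):
            derive_neutral_params(self._neutral_fit(-0.5, 1.0), 1.5)


class TestCompetitionParams:
    def test_one_record_per_resource(self):
        rng = np.random.default_rng(12)
        inv_x, inv_xr, R, dt = synthetic_design(rng, 40, J=2)
        y = rng.normal(size=40)
        ds = make_dataset(response=y, inv_x=inv_x, inv_xr=inv_xr, resources=R, dt=dt)
        fit = fit_combined(ds)
        records = extract_competition_params(fit)
        assert [r.resource_name for r in records] == ["res0", "res1"]
        np.testing.assert_allclose([r.k1_j for r in records], fit.k1)

    def test_neutral_fit_rejected(self):
        rng = np.random.default_rng(13)
        inv_x, inv_xr, R, dt = synthetic_design(rng, 20)
        ds = make_dataset(
            response=rng.normal(size=20), inv_x=inv_x, inv_xr=inv_xr, resources=R, dt=dt
        )
        with pytest.raises(ValueError, match="consumer-resource or combined"):
            extract_competition_params(fit_neutral(ds))


class TestStochasticRecovery:
    def test_cr_estimates_within_three_se(self):
        """n = 200 noisy CR data: estimates near truth, oracle agreement."""
        rng = np.random.default_rng(99)
        n = 200
        inv_x, inv_xr, R, dt = synthetic_design(rng, n)
        y = 0.1 + 1.5 * R[:, 0] + rng.normal(0, 0.2, n)
        ds = make_dataset(response=y, inv_x=inv_x, inv_xr=inv_xr, resources=R, dt=dt)
        fit = fit_consumer_resource(ds)
        assert abs(fit.k0 - 0.1) < 3 * fit.coef_se[0]
        assert abs(fit.k1[0] - 1.5) < 3 * fit.coef_se[1]
        design = np.column_stack([np.ones(n), R])
        expected = brute_force_wls(design, y, np.ones(n))
        np.testing.assert_allclose([fit.k0, fit.k1[0]], expected, atol=1e-10)

    def test_combined_k1_consistent_with_zero_under_neutrality(self):
        """Data with no resource effect: k1 within 2 SE of 0 in >= 28/30 runs."""
        rng = np.random.default_rng(123)
        n = 120
        hits = 0
        for _ in range(30):
            inv_x, inv_xr, R, dt = synthetic_design(rng, n)
            w = dt / (2 * inv_x + 2 * inv_xr)
            y = -0.05 + 0.2 * inv_x - 0.1 * inv_xr + rng.normal(size=n) / np.sqrt(w)
            ds = make_dataset(
                response=y, inv_x=inv_x, inv_xr=inv_xr, resources=R, dt=dt
            )
            fit = fit_combined(ds)
            if abs(fit.k1[0]) < 2 * fit.coef_se[1]:
                hits += 1
        assert hits >= 28
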