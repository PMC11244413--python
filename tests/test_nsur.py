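"""NSUR additive system: structural additivity, the identity-covariance
OLS limit, FGLS behaviour, and efficiency relative to equation-wise NLS."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import least_squares

from sbamix import (
    CovariateSet,
    efficiency_gain,
    fit_nls,
    fit_nsur,
    predict,
    predict_nsur,
    reference,
)
from sbamix.forms import predict_unchecked
from sbamix.simulate import default_config, generate_plots

from conftest import random_covariates

M1M1_TRUTH = {
    "P": np.array([0.013, 0.289, 4.454, 1.029]),
    "B": np.array([0.0080, 0.4216, 1.4756, 1.0338]),
}


def _m1m1_config(n, seed, **kw):
    cfg = default_config(n_plots=n, mode="component")
    species = dict(cfg.species)
    from sbamix.simulate import GeneratingEquation

    species["P"] = GeneratingEquation("M1", tuple(M1M1_TRUTH["P"]))
    species["B"] = GeneratingEquation("M1", tuple(M1M1_TRUTH["B"]))
    return replace(cfg, seed=seed, species=species, **kw)


class TestPredictNsur:
    def test_total_is_exact_component_sum(self):
        rng = np.random.default_rng(8)
        cfg = _m1m1_config(80, 17)
        t = generate_plots(cfg).table
        fit = fit_nsur({"P": "M1", "B": "M1"}, t, seed=0, n_starts=2)
        p, b, tot = predict_nsur(fit, t.covariates("P"), t.covariates("B"))
        assert np.all(p + b == tot)  # structural, to machine identity

    def test_matches_single_equation_predictor(self, mean_covariates):
        cfg = _m1m1_config(100, 18)
        t = generate_plots(cfg).table
        fit = fit_nsur({"P": "M1", "B": "M1"}, t, seed=0, n_starts=2)
        _, b, _ = predict_nsur(fit, mean_covariates["P"], mean_covariates["B"])
        direct = predict("M1", fit.species_params["B"], mean_covariates["B"])
        assert b[0] == pytest.approx(direct, rel=1e-12)

    def test_zero_scales_give_zero_triple(self, mean_covariates):
        p = np.atleast_1d(predict_unchecked("M1", [0.0, 0.3, 2.0, 1.0], mean_covariates["P"]))
        b = np.atleast_1d(predict_unchecked("M1", [0.0, 0.3, 2.0, 1.0], mean_covariates["B"]))
        assert p[0] == 0.0 and b[0] == 0.0 and (p + b)[0] == 0.0


class TestFitNsur:
    def test_identity_sigma_single_iteration_is_stacked_ols(self):
        """GLS with identity weight is ordinary least squares: compare to a
        directly minimised stacked objective."""
        cfg = _m1m1_config(120, 19, rho=0.6)
        t = generate_plots(cfg).table
        fit = fit_nsur(
            {"P": "M1", "B": "M1"}, t, fixed_sigma=np.eye(2), max_fgls_iter=1,
            seed=0, n_starts=2,
        )
        y_p, y_b = t.sba("P"), t.sba("B")
        cov_p, cov_b = t.covariates("P"), t.covariates("B")

        def resid(th):
            bp = np.r_[np.exp(th[0]), th[1:4]]
            bb = np.r_[np.exp(th[4]), th[5:8]]
            rp = y_p - predict_unchecked("M1", bp, cov_p)
            rb = y_b - predict_unchecked("M1", bb, cov_b)
            return np.nan_to_num(np.r_[rp, rb], nan=1e6)

        nls_p = fit_nls("M1", y_p, cov_p, n_starts=2, seed=0)
        nls_b = fit_nls("M1", y_b, cov_b, n_starts=2, seed=1)
        th0 = np.r_[np.log(nls_p.params[0]), nls_p.params[1:],
                    np.log(nls_b.params[0]), nls_b.params[1:]]
        res = least_squares(resid, th0, method="trf", ftol=1e-12, xtol=1e-14, gtol=1e-12)
        oracle = np.r_[np.exp(res.x[0]), res.x[1:4], np.exp(res.x[4]), res.x[5:8]]
        got = np.r_[fit.species_params["P"], fit.species_params["B"]]
        np.testing.assert_allclose(got, oracle, atol=1e-8, rtol=1e-6)
        assert fit.n_fgls_iter == 1

    def test_independent_errors_close_to_equation_wise_nls(self):
        cfg = _m1m1_config(400, 23, rho=0.0)
        t = generate_plots(cfg).table
        fit = fit_nsur({"P": "M1", "B": "M1"}, t, seed=0, n_starts=2)
        corr = fit.sigma[0, 1] / np.sqrt(fit.sigma[0, 0] * fit.sigma[1, 1])
        assert abs(corr) < 2 / np.sqrt(400)
        for sp, nls_seed in (("P", 0), ("B", 1)):
            nls = fit_nls("M1", t.sba(sp), t.covariates(sp), n_starts=2, seed=nls_seed)
            z = np.abs(fit.species_params[sp] - nls.params) / np.maximum(nls.se, 1e-12)
            assert np.all(z < 2)

    def test_sigma_spd_and_iterations_recorded(self):
        cfg = _m1m1_config(150, 29, rho=0.5)
        t = generate_plots(cfg).table
        fit = fit_nsur({"P": "M1", "B": "M1"}, t, seed=0, n_starts=2)
        assert fit.n_fgls_iter >= 1
        eig = np.linalg.eigvalsh(fit.sigma)
        assert np.all(eig > 0)
        np.testing.assert_allclose(fit.sigma, fit.sigma.T)

    def test_inner_minimisation_never_increases_objective(self):
        cfg = _m1m1_config(150, 31, rho=0.5)
        t = generate_plots(cfg).table
        fit = fit_nsur({"P": "M1", "B": "M1"}, t, seed=0, n_starts=2)
        for step in fit.objective_trace:
            assert step["objective_end"] <= step["objective_start"] + 1e-9

    def test_correlated_errors_recover_m1_coefficients(self):
        """One replicate of the recovery design restricted to the
        well-identified Korf-type species equation."""
        cfg = replace(default_config(n_plots=400), seed=77,
                      sigma_p=0.6, sigma_b=0.4, rho=0.5)
        t = generate_plots(cfg).table
        fit = fit_nsur({"P": "M6", "B": "M1"}, t, seed=3)
        truth_b = reference.NSUR_COEFFICIENTS["B"].values
        z = np.abs(fit.species_params["B"] - truth_b) / fit.species_se["B"]
        assert np.all(z < 3)


class TestEfficiencyGain:
    def test_self_comparison_is_unity(self):
        cfg = _m1m1_config(120, 37, rho=0.5)
        t = generate_plots(cfg).table
        fit = fit_nsur({"P": "M1", "B": "M1"}, t, seed=0, n_starts=2)
        fake_nls = {
            sp: fit_nls("M1", t.sba(sp), t.covariates(sp), init=fit.species_params[sp], n_starts=1)
            for sp in ("P", "B")
        }
        for sp in ("P", "B"):
            fake_nls[sp].se[:] = fit.species_se[sp]
        ratios = efficiency_gain(fit, fake_nls)["ratio"]
        np.testing.assert_allclose(ratios, 1.0)

    def test_independent_errors_ratio_near_one(self):
        cfg = _m1m1_config(400, 41, rho=0.0)
        t = generate_plots(cfg).table
        fit = fit_nsur({"P": "M1", "B": "M1"}, t, seed=0, n_starts=2)
        nls = {
            sp: fit_nls("M1", t.sba(sp), t.covariates(sp), n_starts=2, seed=i)
            for i, sp in enumerate(("P", "B"))
        }
        ratios = efficiency_gain(fit, nls)["ratio"].to_numpy()
        assert np.all(np.abs(ratios - 1.0) < 0.10)

    def test_strong_correlation_gains_efficiency(self):
        cfg = _m1m1_config(400, 43, rho=0.8)
        t = generate_plots(cfg).table
        fit = fit_nsur({"P": "M1", "B": "M1"}, t, seed=0, n_starts=2)
        nls = {
            sp: fit_nls("M1", t.sba(sp), t.covariates(sp), n_starts=2, seed=i)
            for i, sp in enumerate(("P", "B"))
        }
        ratios = efficiency_gain(fit, nls)["ratio"].to_numpy()
        assert np.median(ratios) < 1.0

    def test_form_mismatch_rejected(self):
        cfg = _m1m1_config(120, 47)
        t = generate_plots(cfg).table
        fit = fit_nsur({"P": "M1", "B": "M1"}, t, seed=0, n_starts=2)
        nls = {sp: fit_nls("M1", t.sba(sp), t.covariates(sp), n_starts=1) for sp in ("P", "B")}
        nls["P"] = fit_nls("M2", t.sba("P"), t.covariates("P"), n_starts=2)
        from sbamix.exceptions import DomainError

        with pytest.raises(DomainError):
            efficiency_gain(fit, nls)
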