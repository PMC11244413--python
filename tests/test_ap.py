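"""Proportional-adjustment system: exact additivity, share-weight
structure, identifiability, and estimation on share-generated data."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from sbamix import CovariateSet, PlotTable, fit_ap, predict, predict_ap, reference
from sbamix.ap import ap_weight_invariance, predict_ap_params
from sbamix.exceptions import EvaluationError
from sbamix.simulate import default_config, generate_plots

from conftest import random_covariates


def _exact_share_table(n=50, seed=0) -> tuple[PlotTable, dict]:
    """Noise-free table whose species SBAs are exact model-based shares of
    an exact total-model surface."""
    rng = np.random.default_rng(seed)
    cov = {s: random_covariates(rng, n) for s in ("P", "B", "total")}
    truth = {
        "total": np.array([0.016, 0.264, 3.155, 1.001]),
        "P": np.array(reference.AP_COEFFICIENTS["P"].b),
        "B": np.array(reference.AP_COEFFICIENTS["B"].b),
    }
    t_hat = predict("M1", truth["total"], cov["total"])
    f_p = predict("M6", truth["P"], cov["P"])
    f_b = predict("M1", truth["B"], cov["B"])
    w = f_p / (f_p + f_b)
    frame = {"plot_id": [f"s{i}" for i in range(n)]}
    for s, suffix in (("P", "p"), ("B", "b"), ("total", "t")):
        si, adbh, sdi = cov[s].arrays()
        frame[f"si_{suffix}"], frame[f"adbh_{suffix}"], frame[f"sdi_{suffix}"] = si, adbh, sdi
    frame["sba_p"] = w * t_hat
    frame["sba_b"] = t_hat - w * t_hat
    frame["sba_t"] = t_hat
    return PlotTable(pd.DataFrame(frame)), truth


class TestPredictAp:
    def test_components_sum_exactly(self):
        rng = np.random.default_rng(12)
        n = 200
        covs = {s: random_covariates(rng, n) for s in ("P", "B", "total")}
        p, b, t = predict_ap_params(
            "M1", [0.016, 0.264, 3.155, 1.001],
            {"P": "M6", "B": "M1"},
            {"P": np.array(reference.AP_COEFFICIENTS["P"].b),
             "B": np.array(reference.AP_COEFFICIENTS["B"].b)},
            covs["P"], covs["B"], covs["total"],
        )
        assert np.max(np.abs(p + b - t)) < 1e-10

    def test_identical_species_split_in_half(self):
        rng = np.random.default_rng(3)
        cov = random_covariates(rng, 30)
        params = {"P": np.array([0.012, 0.285, 3.867, 1.030])}
        params["B"] = params["P"].copy()
        p, b, t = predict_ap_params(
            "M1", [0.016, 0.264, 3.155, 1.001],
            {"P": "M1", "B": "M1"}, params, cov, cov, cov,
        )
        np.testing.assert_allclose(p, t / 2, rtol=1e-12)
        np.testing.assert_allclose(b, t / 2, rtol=1e-12)

    def test_shares_match_hand_evaluation_at_mean_covariates(self, mean_covariates):
        # independent hand implementation of the weight formula
        import math

        bP = reference.AP_COEFFICIENTS["P"].b
        bB = reference.AP_COEFFICIENTS["B"].b
        bT = reference.AP_COEFFICIENTS["total"].b
        si, adbh, sdi = 14.7, 26.0, 469.2
        f_p = bP[0] * si ** bP[1] * (1 - math.exp(-bP[2] * (sdi / 1000) ** bP[3] * adbh)) ** bP[4]
        si, adbh, sdi = 14.8, 29.0, 242.7
        f_b = bB[0] * si ** bB[1] * math.exp(-bB[2] / adbh) * sdi ** bB[3]
        si, adbh, sdi = 15.8, 28.0, 698.3
        f_t = bT[0] * si ** bT[1] * math.exp(-bT[2] / adbh) * sdi ** bT[3]
        w = f_p / (f_p + f_b)
        p, b, t = predict_ap_params(
            "M1", bT, {"P": "M6", "B": "M1"},
            {"P": np.array(bP), "B": np.array(bB)},
            mean_covariates["P"], mean_covariates["B"], mean_covariates["total"],
        )
        assert t[0] == pytest.approx(f_t, rel=1e-12)
        assert p[0] == pytest.approx(w * f_t, rel=1e-12)
        assert b[0] == pytest.approx((1 - w) * f_t, rel=1e-12)

    def test_degenerate_weights_name_the_plot(self):
        cov = CovariateSet(si=np.r_[14.0, 15.0], adbh=np.r_[25.0, 30.0], sdi=np.r_[400.0, 500.0])
        with pytest.raises(EvaluationError, match="plot"):
            predict_ap_params(
                "M1", [0.016, 0.264, 3.155, 1.001],
                {"P": "M6", "B": "M6"},
                {"P": np.array([10.0, 0.3, 0.0, 1.0, 0.5]),
                 "B": np.array([10.0, 0.3, 0.0, 1.0, 0.5])},
                cov, cov, cov,
            )


class TestFitAp:
    def test_noiseless_self_consistency(self):
        table, truth = _exact_share_table(n=60, seed=4)
        fit = fit_ap(
            "M1", {"P": "M6", "B": "M1"}, table, seed=0, n_starts=1,
            init_total=truth["total"],
            init_species={"P": truth["P"], "B": truth["B"]},
        )
        assert fit.stage2_sse < 1e-10
        p, b, t = predict_ap(
            fit, table.covariates("P"), table.covariates("B"), table.covariates("total")
        )
        np.testing.assert_allclose(p, table.sba("P"), atol=1e-5)
        np.testing.assert_allclose(t, table.sba("total"), atol=1e-5)

    def test_weight_invariance_documents_identifiability_defect(self):
        table, truth = _exact_share_table(n=60, seed=5)
        fit = fit_ap(
            "M1", {"P": "M6", "B": "M1"}, table, seed=0, n_starts=1,
            init_total=truth["total"],
            init_species={"P": truth["P"], "B": truth["B"]},
        )
        drift = ap_weight_invariance(
            fit, table.covariates("P"), table.covariates("B"), table.covariates("total"),
            factor=5.0,
        )
        assert drift < 1e-9

    def test_share_generated_data_recovers_identified_parameters(self):
        """One replicate of the recovery design: total coefficients and the
        identified (non-scale) species coefficients land within 3 SE."""
        cfg = replace(default_config(n_plots=300, mode="share"),
                      seed=513, sigma_p=0.5, sigma_t=0.5)
        table = generate_plots(cfg).table
        fit = fit_ap("M1", {"P": "M6", "B": "M1"}, table, seed=13)
        z_total = np.abs(
            fit.total_fit.params - reference.AP_COEFFICIENTS["total"].values
        ) / fit.total_fit.se
        assert np.all(z_total < 3)
        truth_b = reference.AP_COEFFICIENTS["B"].values
        z_b = np.abs(fit.species_params["B"][1:] - truth_b[1:]) / fit.species_se["B"][1:]
        assert np.all(z_b < 3)
        # exponents of the P surface (its scale/rate pair rides a weakly
        # identified ridge and is assessed distribution-wide elsewhere)
        truth_p = reference.AP_COEFFICIENTS["P"].values
        for j in (1, 3, 4):
            assert abs(fit.species_params["P"][j] - truth_p[j]) < 3 * fit.species_se["P"][j]

    def test_simultaneous_flag_close_to_two_stage(self):
        table, truth = _exact_share_table(n=60, seed=6)
        fit = fit_ap(
            "M1", {"P": "M6", "B": "M1"}, table, seed=0, n_starts=1,
            init_total=truth["total"],
            init_species={"P": truth["P"], "B": truth["B"]},
            simultaneous=True,
        )
        # with exact share data both estimators interpolate
        assert fit.stage2_sse < 1e-8
        np.testing.assert_allclose(fit.total_fit.params, truth["total"], rtol=1e-4)
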