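"""Fit statistics, percent-change comparison, and k-fold cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sbamix import (
    CovariateSet,
    compute_metrics,
    cross_validate,
    fit_nls,
    percent_change,
)
from sbamix.exceptions import DomainError
from sbamix.metrics import make_folds
from sbamix.simulate import default_config, generate_plots
from dataclasses import replace


def loop_metrics(y, yhat, p):
    """Naive loop-based oracle for the five fit statistics."""
    n = len(y)
    abs_sum = sq_sum = 0.0
    for a, b in zip(y, yhat):
        abs_sum += abs(a - b)
        sq_sum += (a - b) ** 2
    ybar = sum(y) / n
    sst = sum((a - ybar) ** 2 for a in y)
    mae = abs_sum / n
    mpe = abs_sum / sum(y) * 100.0
    rmse = (sq_sum / n) ** 0.5
    r2 = 1 - sq_sum / sst
    r2_adj = 1 - (n - 1) / (n - p) * (1 - r2)
    return mae, mpe, rmse, r2, r2_adj


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([1, 2, 3], [1, 2, 3], 1)
        assert (m.mae, m.mpe, m.rmse, m.r2, m.r2_adj) == (0, 0, 0, 1, 1)

    def test_hand_derived_case(self):
        # errors (1, −1): Σ|e| = 2, Σy = 6, Σ(y−ȳ)² = 2
        m = compute_metrics([2, 4], [1, 5], 1)
        assert m.mae == pytest.approx(1.0, abs=1e-10)
        assert m.mpe == pytest.approx(100.0 / 3.0, abs=1e-10)
        assert m.rmse == pytest.approx(1.0, abs=1e-10)
        assert m.r2 == pytest.approx(0.0, abs=1e-10)
        assert m.mpe_proportion == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_adjusted_r2_closed_form(self):
        # n=10, p=3, R²=0.9 → 1 − (9/7)·0.1
        rng = np.random.default_rng(5)
        # build a vector pair with R² exactly 0.9
        y = np.arange(10, dtype=float)
        e = rng.standard_normal(10)
        e -= e.mean()
        e -= (e @ (y - y.mean())) / ((y - y.mean()) @ (y - y.mean())) * (y - y.mean())
        sst = ((y - y.mean()) ** 2).sum()
        e *= np.sqrt(0.1 * sst / (e @ e))
        m = compute_metrics(y, y - e, 3)
        assert m.r2 == pytest.approx(0.9, abs=1e-12)
        assert m.r2_adj == pytest.approx(1 - (9 / 7) * 0.1, abs=1e-10)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_loop_oracle(self, data):
        n = data.draw(st.integers(3, 40))
        vals = st.floats(min_value=0.1, max_value=100, allow_nan=False)
        y = np.array([data.draw(vals) for _ in range(n)])
        yhat = np.array([data.draw(vals) for _ in range(n)])
        if float(np.sum((y - y.mean()) ** 2)) < 1e-6:
            return  # near-constant y: R² ill-conditioned for any oracle
        p = data.draw(st.integers(1, min(5, n - 1)))
        m = compute_metrics(y, yhat, p)
        for got, want in zip((m.mae, m.mpe, m.rmse, m.r2, m.r2_adj), loop_metrics(y, yhat, p)):
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_undefined_metrics_flagged_not_raised(self):
        m = compute_metrics([1.0, 1.0, 1.0], [1.1, 0.9, 1.0], 1)
        assert "r2" in m.undefined and np.isnan(m.r2)

    def test_rmse_squared_times_n_equals_sse(self):
        """Consistency between reported metrics and the fitted SSE."""
        rec = generate_plots(replace(default_config(n_plots=80), seed=9))
        t = rec.table
        fit = fit_nls("M1", t.sba("B"), t.covariates("B"), seed=0, n_starts=2)
        assert fit.metrics.rmse**2 * fit.n_obs == pytest.approx(fit.sse, rel=1e-8)
        assert np.sum(fit.residuals**2) == pytest.approx(fit.sse, rel=1e-8)


class TestPercentChange:
    def test_published_method_comparison_values(self):
        # total-stand RMSE, basic NLS fit vs AP system / NSUR system
        c = percent_change(1.776, 1.170)
        assert c.direction == "decrease"
        assert c.percent == pytest.approx(34.12, abs=0.005)
        c = percent_change(1.354, 0.481)
        assert c.direction == "decrease"
        assert c.percent == pytest.approx(64.48, abs=0.005)

    def test_no_change(self):
        c = percent_change(2.5, 2.5)
        assert c.percent == 0.0 and c.direction == "unchanged"

    def test_increase_convention_and_sign(self):
        c = percent_change(1.0, 1.25)
        assert c.direction == "increase"
        assert c.percent == pytest.approx(25.0)
        assert c.signed == pytest.approx(25.0)
        assert percent_change(1.25, 1.0).signed == pytest.approx(-20.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(DomainError):
            percent_change(0.0, 1.0)


class TestCrossValidation:
    def test_fold_sizes_58_plots_10_folds(self):
        folds = make_folds(58, 10, seed=4)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [5, 5, 6, 6, 6, 6, 6, 6, 6, 6]
        assert sorted(np.concatenate(folds)) == list(range(58))

    def test_same_seed_reproduces_assignment(self):
        rec = generate_plots(replace(default_config(n_plots=58), seed=2))

        def fit(train):
            f = fit_nls("M1", train.sba("B"), train.covariates("B"), n_starts=2, seed=0)
            return lambda test: f.predict(test.covariates("B"))

        r1 = cross_validate(fit, rec.table, "B", n_params=4, k=10, seed=11)
        r2 = cross_validate(fit, rec.table, "B", n_params=4, k=10, seed=11)
        assert r1.fold_assignments == r2.fold_assignments
        assert r1.pooled.rmse == r2.pooled.rmse
        counts = np.bincount(list(r1.fold_assignments.values()))[1:]
        assert sorted(counts.tolist()) == [5, 5, 6, 6, 6, 6, 6, 6, 6, 6]

    def test_noiseless_cv_matches_training_fit(self):
        cfg = replace(default_config(n_plots=60), seed=3, sigma_p=0.0, sigma_b=0.0)
        table = generate_plots(cfg).table
        truth = np.array(cfg.species["B"].coefficients)

        def fit(train):
            f = fit_nls("M1", train.sba("B"), train.covariates("B"), init=truth, n_starts=1)
            return lambda test: f.predict(test.covariates("B"))

        report = cross_validate(fit, table, "B", n_params=4, k=5, seed=0)
        assert report.pooled.rmse == pytest.approx(0.0, abs=1e-6)
        assert not report.has_failures

    def test_failed_fold_is_reported_not_fatal(self):
        rec = generate_plots(replace(default_config(n_plots=30), seed=6))
        calls = {"n": 0}

        def fit(train):
            calls["n"] += 1
            if calls["n"] == 2:
                raise RuntimeError("synthetic failure")
            f = fit_nls("M1", train.sba("B"), train.covariates("B"), n_starts=1, seed=0)
            return lambda test: f.predict(test.covariates("B"))

        report = cross_validate(fit, rec.table, "B", n_params=4, k=5, seed=1)
        assert report.has_failures and len(report.failures) == 1
        assert report.per_fold[1] is None
        assert np.isfinite(report.pooled.rmse)
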