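"""Ten-fold cross-validation of a species basal-area equation.

Folds are a seeded shuffle split into near-equal contiguous blocks; each
fold is predicted by a model refitted to the other nine. Pooled
out-of-fold metrics estimate predictive (not in-sample) accuracy.
"""

from dataclasses import replace

from sbamix import cross_validate, default_config, fit_nls, generate_plots

cfg = replace(default_config(n_plots=58), seed=6)  # the study's sample size
table = generate_plots(cfg).table


def fit(train):
    f = fit_nls("M1", train.sba("B"), train.covariates("B"), seed=0, n_starts=4)
    return lambda test: f.predict(test.covariates("B"))


report = cross_validate(fit, table, response="B", n_params=4, k=10, seed=1)
sizes = sorted(
    list(report.fold_assignments.values()).count(k) for k in range(1, 11)
)
print(f"fold sizes: {sizes}")
m = report.pooled
print(f"pooled out-of-fold: MAE {m.mae:.3f}  MPE {m.mpe:.2f}%  "
      f"RMSE {m.rmse:.3f}  R2 {m.r2:.3f}")

train_fit = fit_nls("M1", table.sba("B"), table.covariates("B"), seed=0, n_starts=4)
print(f"in-sample          : MAE {train_fit.metrics.mae:.3f}  "
      f"MPE {train_fit.metrics.mpe:.2f}%  RMSE {train_fit.metrics.rmse:.3f}")
# Out-of-fold errors are slightly larger than in-sample ones — the honest
# estimate of how the equation would predict new plots.
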