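"""Fit and rank candidate basal-area model forms for one species.

Equation-wise nonlinear least squares on a synthetic table, comparing the
Korf-type (M1) and Richards-type (M6) extended forms for the P. davidiana
stratum, ranked by adjusted R².
"""

from dataclasses import replace

from sbamix import default_config, generate_plots, rank_models

cfg = replace(default_config(n_plots=200), seed=7)
table = generate_plots(cfg).table  # generated from an M6 surface for P

ranked = rank_models(["M1", "M6"], table.sba("P"), table.covariates("P"),
                     seed=0, n_starts=4)
print(f"{'form':5s} {'R2adj':>7s} {'RMSE':>7s} {'MAE':>7s} params")
for fit in ranked:
    m = fit.metrics
    bs = ", ".join(f"{v:.4g}" for v in fit.params)
    print(f"{fit.form.form_id:5s} {m.r2_adj:7.4f} {m.rmse:7.3f} {m.mae:7.3f}  [{bs}]")
# The generating Richards-type form (M6) should rank first; the gap in
# adjusted R² over M1 mirrors the species-level model selection reported
# for these stands.
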