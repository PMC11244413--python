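"""Proportional-adjustment (AP) additive system.

The whole-stand basal area is modelled directly and the two species'
basal areas are model-based shares of it:

.. math::

    SBA_P &= \\frac{f_P(b, X_P)}{f_P(b, X_P) + f_B(b, X_B)}\\, SBA_t + \\varepsilon_P \\\\
    SBA_B &= \\frac{f_B(b, X_B)}{f_P(b, X_P) + f_B(b, X_B)}\\, SBA_t + \\varepsilon_B \\\\
    SBA_t &= f_t(b, X_t) + \\varepsilon_t

Because the total equation carries only total-model parameters and the
share equations only species parameters, estimation separates into two
stages: (1) fit :math:`f_t` by NLS; (2) estimate both species' parameters
jointly by minimising the stacked SSE of the two share equations, with the
*observed* total on the right-hand side (the share weights couple the two
species, so they cannot be fitted one at a time). Prediction replaces the
observed total by :math:`\\hat f_t`, so predicted components always sum to
the predicted total. A single-stage simultaneous fit of all three
equations is available via ``simultaneous=True`` for comparison.

Identifiability: rescaling both species surfaces by a common positive
constant leaves every share weight — hence the entire fit — unchanged.
The species scale parameters are therefore only determined up to this
common factor; no normalisation is imposed, matching published practice
for this system, and :func:`ap_weight_invariance` documents the defect.
With additive data the two share-equation residual vectors are exact
negatives of each other, so standard errors are computed from n effective
observations rather than 2n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .data import PlotTable
from .exceptions import ConvergenceError, DomainError, EvaluationError
from .forms import CovariateSet, ModelForm, get_form, predict_unchecked
from .metrics import MetricsReport, compute_metrics
from .nls import (
    FitResult,
    _from_theta,
    _PENALTY,
    _perturb,
    _start_centres,
    _to_theta,
    FTOL,
    MAX_ITER,
    fit_nls,
)

__all__ = ["APSystemFit", "fit_ap", "predict_ap"]

_WEIGHT_EPS = 1e-12


@dataclass
class APSystemFit:
    """A fitted proportional-adjustment system."""

    total_fit: FitResult
    species_forms: dict[str, ModelForm]
    species_params: dict[str, np.ndarray]
    species_se: dict[str, np.ndarray]
    residuals: dict[str, np.ndarray]
    metrics: dict[str, MetricsReport]
    stage2_sse: float
    converged: bool
    n_obs: int
    seed: int | None = None
    flags: tuple[str, ...] = ()
    #: identified species scale contrast b0_P / b0_B and its SE (the
    #: individual b0's are only determined up to a common factor)
    scale_ratio: float = float("nan")
    scale_ratio_se: float = float("nan")

    def predict(self, cov_p: CovariateSet, cov_b: CovariateSet, cov_t: CovariateSet):
        return predict_ap(self, cov_p, cov_b, cov_t)


def _weights(
    forms: dict[str, ModelForm],
    params: dict[str, np.ndarray],
    cov_p: CovariateSet,
    cov_b: CovariateSet,
    plot_ids=None,
    strict: bool = True,
):
    """Share weight w_P = f_P / (f_P + f_B); returns (w_P, f_P, f_B)."""
    f_p = np.atleast_1d(predict_unchecked(forms["P"], params["P"], cov_p))
    f_b = np.atleast_1d(predict_unchecked(forms["B"], params["B"], cov_b))
    denom = f_p + f_b
    bad = ~np.isfinite(denom) | (denom <= _WEIGHT_EPS)
    if np.any(bad):
        if strict:
            i = int(np.argmax(bad))
            pid = plot_ids[i] if plot_ids is not None else i
            raise EvaluationError(
                f"degenerate share weights at plot {pid!r}: f_P + f_B = "
                f"{denom[i]!r} (must be positive)"
            )
        return None, f_p, f_b
    return f_p / denom, f_p, f_b


def _stage2_residuals(theta, forms, split, cov_p, cov_b, total, y_p, y_b):
    b_p = _from_theta(forms["P"], theta[:split])
    b_b = _from_theta(forms["B"], theta[split:])
    w, f_p, f_b = _weights(forms, {"P": b_p, "B": b_b}, cov_p, cov_b, strict=False)
    if w is None:
        return np.full(2 * y_p.size, _PENALTY)
    r = np.concatenate([y_p - w * total, y_b - (1.0 - w) * total])
    return np.where(np.isfinite(r) & (np.abs(r) < _PENALTY), r, _PENALTY)


def fit_ap(
    total_form: "ModelForm | str",
    species_forms: dict[str, "ModelForm | str"],
    table: PlotTable,
    seed: int = 0,
    n_starts: int = 6,
    init_total=None,
    init_species: dict | None = None,
    simultaneous: bool = False,
) -> APSystemFit:
    """Fit the AP additive system on complete P/B/total triples.

    Parameters
    ----------
    total_form:
        Form of the whole-stand model :math:`f_t`.
    species_forms:
        ``{"P": form, "B": form}`` for the species surfaces that define
        the share weights.
    table:
        Plot table; rows missing any observed SBA are dropped.
    init_total, init_species:
        Optional explicit starts per stage.
    simultaneous:
        Fit all three equations in one stacked least-squares problem
        instead of the default two-stage estimation.
    """
    table = table.complete_triples()
    forms = {k: get_form(v) for k, v in species_forms.items()}
    if set(forms) != {"P", "B"}:
        raise DomainError("species_forms must have exactly the keys 'P' and 'B'")
    total_form = get_form(total_form)
    n = len(table)
    p_p, p_b = forms["P"].n_params, forms["B"].n_params
    cov_p, cov_b, cov_t = (table.covariates(s) for s in ("P", "B", "total"))
    y_p, y_b, y_t = (table.sba(s) for s in ("P", "B", "total"))
    if n <= max(total_form.n_params, p_p + p_b):
        raise DomainError(f"too few complete plots (n={n}) for the system")

    # Stage 1: whole-stand model.
    total_fit = fit_nls(total_form, y_t, cov_t, init=init_total, n_starts=n_starts, seed=seed)
    if not total_fit.converged:
        raise ConvergenceError(
            "stage 1 (total model) did not converge: " + total_fit.message
        )

    # Stage 2: joint share-equation fit, started from equation-wise NLS
    # estimates of the species surfaces (the standard system-fit start).
    rng = np.random.default_rng(seed + 1)
    init_species = init_species or {}
    centres_p = _start_centres(forms["P"], y_p, cov_p, init_species.get("P"))
    centres_b = _start_centres(forms["B"], y_b, cov_b, init_species.get("B"))
    if not init_species:
        try:
            eq_p = fit_nls(forms["P"], y_p, cov_p, n_starts=n_starts, seed=seed + 2)
            eq_b = fit_nls(forms["B"], y_b, cov_b, n_starts=n_starts, seed=seed + 3)
            centres_p.insert(0, eq_p.params)
            centres_b.insert(0, eq_b.params)
        except Exception:
            pass  # fall back to published/heuristic centres
    n_centres = max(len(centres_p), len(centres_b))
    starts = []
    for i in range(max(1, n_starts)):
        bp = centres_p[i % len(centres_p)]
        bb = centres_b[i % len(centres_b)]
        if i >= n_centres:
            bp, bb = _perturb(forms["P"], bp, rng), _perturb(forms["B"], bb, rng)
        starts.append((bp, bb))

    split = p_p
    best = None
    for bp, bb in starts:
        try:
            theta0 = np.concatenate([_to_theta(forms["P"], bp), _to_theta(forms["B"], bb)])
        except DomainError:
            continue
        if simultaneous:
            tt0 = _to_theta(total_form, total_fit.params)
            theta0 = np.concatenate([theta0, tt0])

            def resid(th):
                th_s, th_t = th[: split + p_b], th[split + p_b :]
                b_t = _from_theta(total_form, th_t)
                t_hat = np.atleast_1d(predict_unchecked(total_form, b_t, cov_t))
                r_sp = _stage2_residuals(th_s, forms, split, cov_p, cov_b, y_t, y_p, y_b)
                rt = y_t - t_hat
                r_t = np.where(np.isfinite(rt) & (np.abs(rt) < _PENALTY), rt, _PENALTY)
                return np.concatenate([r_sp, r_t])

        else:

            def resid(th):
                return _stage2_residuals(th, forms, split, cov_p, cov_b, y_t, y_p, y_b)

        try:
            res = least_squares(
                resid, theta0, method="trf", ftol=FTOL, xtol=1e-12, gtol=1e-10,
                max_nfev=MAX_ITER * (theta0.size + 1),
            )
        except Exception:
            continue
        if np.any(np.abs(res.fun) >= _PENALTY):
            continue
        # numerically tied optima keep the earlier start (ridge stability)
        if best is None or 2 * res.cost < best[0] * (1 - 1e-9):
            best = (2 * res.cost, res)
    if best is None:
        raise ConvergenceError("stage 2 (share equations) found no admissible fit")
    sse2, res = best
    th = res.x
    if simultaneous:
        b_t = _from_theta(total_form, th[split + p_b :])
        total_fit = _refresh_total(total_form, b_t, y_t, cov_t, total_fit)
        th = th[: split + p_b]
    params = {
        "P": _from_theta(forms["P"], th[:split]),
        "B": _from_theta(forms["B"], th[split:]),
    }

    plot_ids = table.df["plot_id"].to_numpy()
    w, _, _ = _weights(forms, params, cov_p, cov_b, plot_ids)
    pred_p_fit = w * y_t          # share of the observed total (estimation scale)
    res_p = y_p - pred_p_fit
    res_b = y_b - (1.0 - w) * y_t
    sse2 = float(res_p @ res_p + res_b @ res_b)

    se, se_flags, ratio, ratio_se = _stage2_se(
        forms, params, split, cov_p, cov_b, y_t, res_p, res_b, n
    )

    # Reported residuals/metrics use the prediction pathway (fitted total).
    pred_p, pred_b, pred_t = predict_ap_params(
        total_form, total_fit.params, forms, params, cov_p, cov_b, cov_t
    )
    residuals = {"P": y_p - pred_p, "B": y_b - pred_b, "total": y_t - pred_t}
    metrics = {
        "P": compute_metrics(y_p, pred_p, p_p),
        "B": compute_metrics(y_b, pred_b, p_b),
        "total": compute_metrics(y_t, pred_t, total_form.n_params),
    }
    return APSystemFit(
        total_fit=total_fit,
        species_forms=forms,
        species_params=params,
        species_se={"P": se[:split], "B": se[split:]},
        residuals=residuals,
        metrics=metrics,
        stage2_sse=sse2,
        converged=bool(res.status > 0),
        n_obs=n,
        seed=seed,
        flags=se_flags,
        scale_ratio=float(ratio),
        scale_ratio_se=float(ratio_se),
    )


def _refresh_total(total_form, b_t, y_t, cov_t, old: FitResult) -> FitResult:
    from .nls import standard_errors

    pred = np.atleast_1d(predict_unchecked(total_form, b_t, cov_t))
    resid = y_t - pred
    sse = float(resid @ resid)
    se, flags = standard_errors(total_form, b_t, cov_t, sse, y_t.size)
    return FitResult(
        form=total_form, params=b_t, se=se, residuals=resid, sse=sse,
        converged=old.converged, n_obs=y_t.size,
        metrics=compute_metrics(y_t, pred, total_form.n_params),
        seed=old.seed, flags=flags, message="simultaneous system fit",
    )


def _stage2_se(forms, params, split, cov_p, cov_b, total, res_p, res_b, n):
    """SEs for the share-equation parameters.

    The stacked residual pair (r_P, r_B) is exactly linearly dependent for
    additive data (r_B = −r_P), so the information matrix uses n, not 2n,
    observations. Differentiation happens in the working (log) space and
    is mapped back by the delta method; the common-scale direction of the
    two species' b0 is flat (share-weight identifiability) and handled by
    pseudo-inversion, flagged.
    """
    from .nls import _covariance_from_information, param_scales

    p_all = split + params["B"].size
    theta = np.concatenate(
        [_to_theta(forms["P"], params["P"]), _to_theta(forms["B"], params["B"])]
    )

    def wfun(th):
        pr = {
            "P": _from_theta(forms["P"], th[:split]),
            "B": _from_theta(forms["B"], th[split:]),
        }
        w, _, _ = _weights(forms, pr, cov_p, cov_b, strict=False)
        return w

    nanres = (np.full(p_all, np.nan), ("jacobian_not_finite",), np.nan, np.nan)
    J = np.empty((n, p_all))
    for j in range(p_all):
        h = 1e-6 * max(abs(theta[j]), 1.0)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        wp, wm = wfun(tp), wfun(tm)
        if wp is None or wm is None:
            return nanres
        J[:, j] = (wp - wm) / (2 * h) * total  # d(pred_P)/dθ
    sse = float(res_p @ res_p)  # one copy of the information
    dof = n - p_all
    if dof <= 0 or sse <= 1e-12 * n:
        return (np.zeros(p_all), ("degenerate_residual_variance",), np.nan, np.nan)
    s2 = sse / dof
    covm, deficient = _covariance_from_information(J.T @ J)
    covm = covm * s2
    scales = np.concatenate(
        [param_scales(forms["P"], params["P"]), param_scales(forms["B"], params["B"])]
    )
    se = np.sqrt(np.clip(np.diag(covm), 0, None)) * np.abs(scales)
    flags = ("rank_deficient_jacobian",) if deficient else ()
    # identified scale contrast b0_P/b0_B (orthogonal to the flat common-
    # scale direction), when both scales are log-reparameterised
    ratio = ratio_se = np.nan
    from .nls import _log_indices

    if 0 in _log_indices(forms["P"]) and 0 in _log_indices(forms["B"]):
        ratio = params["P"][0] / params["B"][0]
        var_log = covm[0, 0] + covm[split, split] - 2 * covm[0, split]
        ratio_se = abs(ratio) * np.sqrt(max(var_log, 0.0))
    return se, flags, ratio, ratio_se


def predict_ap_params(
    total_form, total_params, species_forms, species_params, cov_p, cov_b, cov_t
):
    """Prediction pathway from raw parameter sets (see :func:`predict_ap`)."""
    t_hat = np.atleast_1d(predict_unchecked(get_form(total_form), total_params, cov_t))
    if np.any(~np.isfinite(t_hat)):
        raise EvaluationError("total model not evaluable at the given covariates")
    w, _, _ = _weights(
        {k: get_form(v) for k, v in species_forms.items()}, species_params, cov_p, cov_b
    )
    sba_p = w * t_hat
    sba_b = t_hat - sba_p  # exact structural additivity
    return sba_p, sba_b, t_hat


def predict_ap(
    fit: APSystemFit, cov_p: CovariateSet, cov_b: CovariateSet, cov_t: CovariateSet
):
    """Predict (SBA_P, SBA_B, SBA_t) from a fitted AP system.

    The total is the fitted whole-stand model; species values are its
    share-weighted split, so components sum to the total exactly.
    """
    return predict_ap_params(
        fit.total_fit.form, fit.total_fit.params, fit.species_forms,
        fit.species_params, cov_p, cov_b, cov_t,
    )


def ap_weight_invariance(
    fit: APSystemFit, cov_p: CovariateSet, cov_b: CovariateSet, cov_t: CovariateSet,
    factor: float = 3.0,
) -> float:
    """Max absolute change in predictions when both species scales are
    multiplied by a common factor — identically 0 up to round-off,
    documenting the share-weight identifiability defect."""
    base = predict_ap(fit, cov_p, cov_b, cov_t)
    scaled = {k: v.copy() for k, v in fit.species_params.items()}
    for k in scaled:
        scaled[k][0] *= factor
    alt = predict_ap_params(
        fit.total_fit.form, fit.total_fit.params, fit.species_forms, scaled,
        cov_p, cov_b, cov_t,
    )
    return float(max(np.max(np.abs(a - b)) for a, b in zip(base, alt)))
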