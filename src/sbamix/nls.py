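"""Equation-wise nonlinear least squares for SBA model forms.

The estimator minimises :math:`\\sum_i (y_i - f(b, X_i))^2` with a
trust-region least-squares solver, multi-start initialisation, and
positivity of scale-type parameters enforced by log-reparameterisation
(``b0`` everywhere except the log-linear Schumacher forms M3/M4, whose
leading coefficient is already on the log scale and may be negative; plus
the Richards rate parameter, which must be positive for the saturation
bracket to be defined).

Start centres default to the published coefficient sets for the matching
form, plus a data-driven centre (exact log-scale OLS where the form is
log-linear), each perturbed log-uniformly (±1 order of magnitude on the
scale, ±50% elsewhere). Asymptotic standard errors come from
:math:`s^2 (J^T J)^{-1}` with :math:`s^2 = SSE/(n-p)`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import reference
from .exceptions import ConvergenceError, DomainError
from .forms import CovariateSet, ModelForm, get_form, predict_unchecked
from .metrics import MetricsReport, compute_metrics

__all__ = ["FitResult", "fit_nls", "rank_models"]

#: Residual value substituted where a parameter proposal is inadmissible.
_PENALTY = 1e6

#: Relative-SSE convergence tolerance and iteration cap per start.
FTOL = 1e-10
MAX_ITER = 500


def _log_indices(form: ModelForm) -> tuple[int, ...]:
    """Indices of parameters constrained positive via log-reparameterisation."""
    fid = form.form_id
    if fid in ("M3", "M4"):
        return ()
    if fid == "richards":
        return (0, 1)  # scale and rate
    if fid in ("M5", "M6"):
        return (0, 2)  # scale and rate
    return (0,)


def _to_theta(form: ModelForm, b: np.ndarray) -> np.ndarray:
    theta = np.array(b, dtype=float)
    for i in _log_indices(form):
        if theta[i] <= 0:
            raise DomainError(
                f"parameter b{i} of form {form.form_id} must be positive"
            )
        theta[i] = np.log(theta[i])
    return theta

def _from_theta(form: ModelForm, theta: np.ndarray) -> np.ndarray:
    b = np.array(theta, dtype=float)
    with np.errstate(over="ignore"):  # inf scale is penalised downstream
        for i in _log_indices(form):
            b[i] = np.exp(b[i])
    return b


def _loglinear_start(form: ModelForm, y: np.ndarray, cov: CovariateSet) -> np.ndarray | None:
    """Exact OLS start on the log scale for the log-linear forms."""
    si, adbh, sdi = cov.arrays()
    s = sdi / 1000.0 if form.sdi_scaled else sdi
    pos = y > 0
    if pos.sum() < form.n_params + 1:
        return None
    ly = np.log(y[pos])
    fid = form.form_id
    if fid in ("M1", "M2"):
        X = np.column_stack([np.ones(pos.sum()), np.log(si[pos]), 1 / adbh[pos], np.log(s[pos])])
        c, *_ = np.linalg.lstsq(X, ly, rcond=None)
        return np.array([np.exp(c[0]), c[1], -c[2], c[3]])
    if fid in ("M3", "M4"):
        X = np.column_stack([
            np.ones(pos.sum()), 1 / adbh[pos], np.log(s[pos]), np.log(si[pos]),
            np.log(s[pos]) / adbh[pos], np.log(si[pos]) / adbh[pos],
        ])
        c, *_ = np.linalg.lstsq(X, ly, rcond=None)
        return np.array([c[0], c[1], c[2], c[3], c[4], c[5]])
    if fid == "schumacher":
        X = np.column_stack([np.ones(pos.sum()), 1 / adbh[pos]])
        c, *_ = np.linalg.lstsq(X, ly, rcond=None)
        return np.array([np.exp(c[0]), -c[1]])
    if fid == "korf":
        X = np.column_stack([np.ones(pos.sum()), 1 / adbh[pos]])
        c, *_ = np.linalg.lstsq(X, ly, rcond=None)
        return np.array([np.exp(c[0]), max(-c[1], 1e-3), 1.0])
    return None


def _heuristic_start(form: ModelForm, y: np.ndarray, cov: CovariateSet) -> np.ndarray:
    si, adbh, sdi = cov.arrays()
    fid = form.form_id
    ymax = max(float(np.max(y)), 1e-3)
    if fid == "richards":
        return np.array([1.2 * ymax, 3.0 / float(np.median(adbh)), 1.0])
    if fid in ("M5", "M6"):
        b1 = 0.29
        b2, b3, b4 = (0.001, 6.6, 0.16) if form.sdi_scaled else (0.002, 2.2, 0.5)
        b0 = 1.3 * ymax / float(np.median(si)) ** b1
        return np.array([b0, b1, b2, b3, b4])
    start = _loglinear_start(form, y, cov)
    if start is not None:
        return start
    return np.concatenate([[ymax], np.full(form.n_params - 1, 0.1)])


def _start_centres(
    form: ModelForm, y: np.ndarray, cov: CovariateSet, init
) -> list[np.ndarray]:
    if init is not None:
        return [np.asarray(init, dtype=float)]
    centres = [_heuristic_start(form, y, cov)]
    centres += reference.start_centres(form.form_id)
    return centres


def _perturb(form: ModelForm, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.array(b, dtype=float)
    for j in range(out.size):
        if j in _log_indices(form) and j == 0:
            out[j] *= 10.0 ** rng.uniform(-1, 1)
        elif out[j] != 0:
            out[j] *= 1.0 + rng.uniform(-0.5, 0.5)
        else:
            out[j] = rng.uniform(-0.1, 0.1)
    for i in _log_indices(form):
        out[i] = abs(out[i]) if out[i] != 0 else 1e-6
    return out


@dataclass
class FitResult:
    """A fitted equation: estimates, uncertainty, residuals and metrics."""

    form: ModelForm
    params: np.ndarray
    se: np.ndarray
    residuals: np.ndarray
    sse: float
    converged: bool
    n_obs: int
    metrics: MetricsReport
    gradient_norm: float = float("nan")
    seed: int | None = None
    n_starts: int = 1
    flags: tuple[str, ...] = ()
    message: str = ""

    def predict(self, cov: CovariateSet):
        from .forms import predict

        return predict(self.form, self.params, cov)


def param_scales(form: ModelForm, b: np.ndarray) -> np.ndarray:
    """Diagonal of db/dθ for the log-reparameterisation (delta method)."""
    s = np.ones_like(np.asarray(b, dtype=float))
    for i in _log_indices(form):
        s[i] = b[i]
    return s


def theta_jacobian(
    form: ModelForm, b: np.ndarray, cov: CovariateSet, step: float = 1e-6
) -> np.ndarray:
    """Central-difference Jacobian of the model surface w.r.t. the working
    parameters θ (log scale for positivity-constrained coefficients).

    Differencing in θ keeps every evaluation inside the parameter domain
    and stays well-conditioned even on weakly identified ridges where the
    raw coefficients span many orders of magnitude.
    """
    theta = _to_theta(form, np.asarray(b, dtype=float))
    n = cov.arrays()[0].size
    J = np.empty((n, theta.size))
    for j in range(theta.size):
        h = step * max(abs(theta[j]), 1.0)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        fp = predict_unchecked(form, _from_theta(form, tp), cov)
        fm = predict_unchecked(form, _from_theta(form, tm), cov)
        J[:, j] = (np.atleast_1d(fp) - np.atleast_1d(fm)) / (2 * h)
    return J


def _covariance_from_information(info: np.ndarray) -> tuple[np.ndarray, bool]:
    """Invert an information matrix, falling back to pseudo-inverse on a
    (near-)singular ridge; returns (covariance, rank_deficient)."""
    p = info.shape[0]
    if not np.all(np.isfinite(info)):
        return np.full((p, p), np.nan), True
    tol = 1e-12 * max(np.trace(info) / p, 1e-300)
    try:
        rank = np.linalg.matrix_rank(info, tol=tol, hermitian=True)
    except np.linalg.LinAlgError:
        rank = 0
    if rank < p:
        return np.linalg.pinv(info, hermitian=True), True
    return np.linalg.inv(info), False


def standard_errors(
    form: ModelForm, b: np.ndarray, cov: CovariateSet, sse: float, n: int
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Asymptotic SEs from s²(JᵀJ)⁻¹ with s² = SSE/(n−p).

    Computed in the working parameterisation and mapped back by the delta
    method. Degenerate residual variance → zeros, flagged; rank-deficient
    Jacobian → pseudo-inverse, flagged.
    """
    p = b.size
    if sse <= 1e-12 * n:
        return np.zeros(p), ("degenerate_residual_variance",)
    J = theta_jacobian(form, b, cov)
    if not np.all(np.isfinite(J)):
        return np.full(p, np.nan), ("jacobian_not_finite",)
    covm, deficient = _covariance_from_information(J.T @ J)
    s2 = sse / (n - p)
    se_theta = np.sqrt(np.clip(np.diag(covm) * s2, 0, None))
    se = se_theta * np.abs(param_scales(form, b))
    return se, ("rank_deficient_jacobian",) if deficient else ()


def fit_nls(
    form: "ModelForm | str",
    y,
    cov: CovariateSet,
    init=None,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Fit one SBA equation by nonlinear least squares.

    Parameters
    ----------
    form:
        Model form (identifier or :class:`ModelForm`).
    y:
        Observed SBA vector (m² ha⁻¹).
    cov:
        Covariate arrays aligned with ``y``.
    init:
        Optional explicit start; otherwise published sets for the form
        plus a data-driven centre are used.
    n_starts:
        Total number of starts (centres plus log-uniform perturbations);
        the best final SSE wins.
    seed:
        Seed for start perturbations (estimation itself is deterministic).

    Raises
    ------
    DomainError
        If ``n_obs <= n_params`` or covariates are invalid.
    """
    form = get_form(form)
    y = np.asarray(y, dtype=float).ravel()
    cov.validate()
    n = y.size
    p = form.n_params
    if n <= p:
        raise DomainError(
            f"need more observations than parameters (n={n}, p={p})"
        )
    rng = np.random.default_rng(seed)
    centres = _start_centres(form, y, cov, init)
    starts = list(centres[: max(1, n_starts)])
    i = 0
    while len(starts) < n_starts:
        starts.append(_perturb(form, centres[i % len(centres)], rng))
        i += 1

    def resid(theta: np.ndarray) -> np.ndarray:
        pred = predict_unchecked(form, _from_theta(form, theta), cov)
        r = y - pred
        return np.where(np.isfinite(r) & (np.abs(r) < _PENALTY), r, _PENALTY)

    best = None
    messages = []
    for b0 in starts:
        try:
            theta0 = _to_theta(form, b0)
        except DomainError:
            continue
        try:
            res = least_squares(
                resid, theta0, method="trf", ftol=FTOL, xtol=1e-12, gtol=1e-10,
                max_nfev=MAX_ITER * (p + 1),
            )
        except Exception as exc:  # singular trust region etc.
            messages.append(str(exc))
            continue
        sse = 2 * res.cost
        if np.any(np.abs(res.fun) >= _PENALTY):
            continue
        # strictly better wins; numerically tied optima (common on weakly
        # identified ridges) keep the earlier start, for determinism and to
        # avoid drifting to extreme ridge coordinates
        if best is None or sse < best[0] * (1 - 1e-9):
            best = (sse, res)
    if best is None:
        raise ConvergenceError(
            f"no start produced an admissible fit for form {form.form_id}: "
            + "; ".join(messages[:3])
        )
    sse, res = best
    b = _from_theta(form, res.x)
    residuals = y - np.atleast_1d(predict_unchecked(form, b, cov))
    sse = float(np.dot(residuals, residuals))
    gradient_norm = float(np.linalg.norm(res.grad, np.inf))
    converged = bool(res.status > 0)
    se, flags = standard_errors(form, b, cov, sse, n)
    metrics = compute_metrics(y, y - residuals, p)
    return FitResult(
        form=form, params=b, se=se, residuals=residuals, sse=sse,
        converged=converged, n_obs=n, metrics=metrics,
        gradient_norm=gradient_norm, seed=seed, n_starts=len(starts),
        flags=flags, message=res.message if converged else "did not converge",
    )


def rank_models(
    candidates, y, cov: CovariateSet, **fit_kwargs
) -> list[FitResult]:
    """Fit several candidate forms and rank them.

    Converged fits are ordered by descending adjusted R², ties broken by
    ascending RMSE then ascending parameter count; non-converged fits are
    listed last. Raises :class:`ConvergenceError` with per-form
    diagnostics if every candidate fails.
    """
    results: list[FitResult] = []
    errors: list[str] = []
    for form in candidates:
        try:
            results.append(fit_nls(form, y, cov, **fit_kwargs))
        except Exception as exc:
            errors.append(f"{get_form(form).form_id}: {type(exc).__name__}: {exc}")
    if not results:
        raise ConvergenceError("all candidate forms failed: " + " | ".join(errors))

    def key(r: FitResult):
        return (
            0 if r.converged else 1,
            -(r.metrics.r2_adj if np.isfinite(r.metrics.r2_adj) else -np.inf),
            r.metrics.rmse,
            r.form.n_params,
        )

    return sorted(results, key=key)
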