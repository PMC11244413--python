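"""Stand basal area (SBA) model forms and stand-variable transforms.

The package models plot-level stand basal area (m² ha⁻¹) as a nonlinear
function of three stand covariates:

* ``SI``   — site index, taken as dominant height (m),
* ``ADBH`` — stand age at breast height, 1.3 m above ground (years),
* ``SDI``  — Reineke stand density index (trees ha⁻¹),
  ``SDI = N · (D0/Dg)^−1.605`` with reference diameter ``D0 = 20`` cm.

Three classic base growth functions (Korf, Schumacher, Richards) use age
alone; six extended forms (M1–M6) add site index and stand density:

* ``M1``: ``b0 · SI^b1 · exp(−b2/ADBH) · SDI^b3``               (Korf type)
* ``M2``: M1 with ``SDI/1000`` in place of ``SDI``
* ``M3``: ``exp(b0 + b1/ADBH) · SDI^(b2 + b4/ADBH) · SI^(b3 + b5/ADBH)``
  (Schumacher type)
* ``M4``: M3 with ``SDI/1000``
* ``M5``: ``b0 · SI^b1 · [1 − exp(−b2 · SDI^b3 · ADBH)]^b4``    (Richards type)
* ``M6``: M5 with ``SDI/1000``

All predictors are evaluated in log space and refuse (rather than clamp)
results whose log magnitude exceeds 700, so that fitting code can penalise
divergent parameter proposals instead of silently saturating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, EvaluationError

__all__ = [
    "ModelForm",
    "CovariateSet",
    "FORMS",
    "FORM_IDS",
    "get_form",
    "compute_sdi",
    "predict",
]

#: Reineke reference diameter (cm) and exponent.
SDI_REFERENCE_DIAMETER = 20.0
SDI_EXPONENT = -1.605

#: Absolute bound on the log prediction before declaring overflow.
_LOG_BOUND = 700.0


@dataclass(frozen=True)
class ModelForm:
    """One parametric SBA predictor.

    Attributes
    ----------
    form_id:
        ``"korf"``, ``"schumacher"``, ``"richards"`` or ``"M1"``…``"M6"``.
    n_params:
        Number of free coefficients ``b0…``.
    sdi_scaled:
        True when the form uses ``SDI/1000`` (M2, M4, M6).
    uses_stand_covariates:
        False for the three age-only base forms.
    """

    form_id: str
    n_params: int
    sdi_scaled: bool
    uses_stand_covariates: bool = True


FORMS: dict[str, ModelForm] = {
    "korf": ModelForm("korf", 3, False, uses_stand_covariates=False),
    "schumacher": ModelForm("schumacher", 2, False, uses_stand_covariates=False),
    "richards": ModelForm("richards", 3, False, uses_stand_covariates=False),
    "M1": ModelForm("M1", 4, False),
    "M2": ModelForm("M2", 4, True),
    "M3": ModelForm("M3", 6, False),
    "M4": ModelForm("M4", 6, True),
    "M5": ModelForm("M5", 5, False),
    "M6": ModelForm("M6", 5, True),
}

FORM_IDS = tuple(FORMS)


def get_form(form: "ModelForm | str") -> ModelForm:
    """Resolve a form identifier (string or ModelForm) to a ModelForm."""
    if isinstance(form, ModelForm):
        return form
    try:
        return FORMS[form]
    except KeyError:
        raise DomainError(
            f"unknown model form {form!r}; expected one of {FORM_IDS}"
        ) from None


@dataclass(frozen=True)
class CovariateSet:
    """Stand covariates for one stratum; scalars or aligned arrays.

    ``si`` in m, ``adbh`` in years, ``sdi`` in trees ha⁻¹; all strictly
    positive.
    """

    si: "np.ndarray | float"
    adbh: "np.ndarray | float"
    sdi: "np.ndarray | float"

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        si, adbh, sdi = np.broadcast_arrays(
            np.asarray(self.si, dtype=float),
            np.asarray(self.adbh, dtype=float),
            np.asarray(self.sdi, dtype=float),
        )
        return si, adbh, sdi

    def validate(self) -> None:
        si, adbh, sdi = self.arrays()
        for name, v in (("si", si), ("adbh", adbh), ("sdi", sdi)):
            if not np.all(np.isfinite(v)) or np.any(v <= 0):
                raise DomainError(f"covariate {name!r} must be finite and > 0")


def compute_sdi(
    n_stems: "np.ndarray | float",
    dg: "np.ndarray | float",
    d0: float = SDI_REFERENCE_DIAMETER,
    exponent: float = SDI_EXPONENT,
) -> "np.ndarray | float":
    """Reineke stand density index ``SDI = N · (D0/Dg)^−1.605``.

    Parameters
    ----------
    n_stems:
        Stem count per hectare (trees ha⁻¹), > 0.
    dg:
        Quadratic mean diameter at breast height (cm), > 0.
    d0:
        Reference diameter (cm); default 20.
    exponent:
        Reineke exponent; default −1.605.

    Returns
    -------
    SDI in trees ha⁻¹, strictly increasing in ``dg`` for fixed ``n_stems``.
    """
    n = np.asarray(n_stems, dtype=float)
    d = np.asarray(dg, dtype=float)
    if np.any(~np.isfinite(n)) or np.any(n <= 0):
        raise DomainError("n_stems must be finite and > 0")
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise DomainError("dg must be finite and > 0")
    out = n * (d0 / d) ** exponent
    if np.isscalar(n_stems) and np.isscalar(dg):
        return float(out)
    return out


def _check_params(form: ModelForm, b: np.ndarray) -> np.ndarray:
    b = np.asarray(b, dtype=float).ravel()
    if b.size != form.n_params:
        raise DomainError(
            f"form {form.form_id} takes {form.n_params} parameters, got {b.size}"
        )
    return b


def _log_predict(form: ModelForm, b: np.ndarray, si, adbh, sdi) -> np.ndarray:
    """Log prediction; −inf marks a structural zero, NaN an invalid point."""
    fid = form.form_id
    s = sdi / 1000.0 if form.sdi_scaled else sdi
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        if fid == "korf":
            b0, b1, b2 = b
            return _log_scale(b0) - b1 * adbh ** (-b2)
        if fid == "schumacher":
            b0, b1 = b
            return _log_scale(b0) - b1 / adbh
        if fid == "richards":
            b0, b1, b2 = b
            bracket = -np.expm1(-b1 * adbh)
            return _log_scale(b0) + b2 * _log_bracket(bracket)
        if fid in ("M1", "M2"):
            b0, b1, b2, b3 = b
            return _log_scale(b0) + b1 * np.log(si) - b2 / adbh + b3 * np.log(s)
        if fid in ("M3", "M4"):
            b0, b1, b2, b3, b4, b5 = b
            return (
                b0
                + b1 / adbh
                + (b2 + b4 / adbh) * np.log(s)
                + (b3 + b5 / adbh) * np.log(si)
            )
        if fid in ("M5", "M6"):
            b0, b1, b2, b3, b4 = b
            bracket = -np.expm1(-b2 * s**b3 * adbh)
            return _log_scale(b0) + b1 * np.log(si) + b4 * _log_bracket(bracket)
    raise DomainError(f"unknown form {fid!r}")  # pragma: no cover


def _log_scale(b0: float) -> float:
    # b0 == 0 is the continuous limit "prediction 0"; b0 < 0 is invalid.
    if b0 > 0:
        return float(np.log(b0))
    return -np.inf if b0 == 0 else np.nan


def _log_bracket(bracket: np.ndarray) -> np.ndarray:
    """log of the Richards saturation term; 0 → −inf, negative → NaN."""
    out = np.full_like(np.asarray(bracket, dtype=float), np.nan)
    pos = bracket > 0
    out = np.where(pos, np.log(np.where(pos, bracket, 1.0)), out)
    out = np.where(bracket == 0, -np.inf, out)
    return out


def predict_unchecked(
    form: "ModelForm | str",
    params,
    cov: CovariateSet,
) -> np.ndarray:
    """Like :func:`predict`, but returns NaN where evaluation fails.

    Used by fitting code, which penalises invalid parameter proposals
    instead of aborting.
    """
    form = get_form(form)
    b = _check_params(form, params)
    si, adbh, sdi = cov.arrays()
    logp = _log_predict(form, b, si, adbh, sdi)
    logp = np.asarray(logp, dtype=float)
    out = np.where(logp == -np.inf, 0.0, np.exp(np.clip(logp, None, _LOG_BOUND + 1)))
    bad = np.isnan(logp) | (np.abs(logp) > _LOG_BOUND)
    bad &= logp != -np.inf
    out = np.where(bad, np.nan, out)
    return out


def predict(form: "ModelForm | str", params, cov: CovariateSet) -> "np.ndarray | float":
    """Evaluate an SBA model form.

    Parameters
    ----------
    form:
        A :class:`ModelForm` or its string identifier.
    params:
        Coefficient vector ``b0…`` of length ``form.n_params``.
    cov:
        Covariates; ``sdi`` is always supplied unscaled — forms M2/M4/M6
        divide by 1000 internally. Base forms use ``adbh`` as the age
        variable ``t`` and ignore ``si``/``sdi``.

    Returns
    -------
    SBA in m² ha⁻¹ (scalar in → scalar out).

    Raises
    ------
    DomainError
        Invalid covariates or a parameter-length mismatch.
    EvaluationError
        Overflow (|log prediction| > 700) or an undefined Richards bracket,
        reporting the offending covariate values.
    """
    form = get_form(form)
    cov.validate()
    out = predict_unchecked(form, params, cov)
    bad = ~np.isfinite(out)
    if np.any(bad):
        si, adbh, sdi = cov.arrays()
        i = int(np.argmax(np.atleast_1d(bad)))
        raise EvaluationError(
            f"form {form.form_id} could not be evaluated at "
            f"SI={np.atleast_1d(si)[i]:g}, ADBH={np.atleast_1d(adbh)[i]:g}, "
            f"SDI={np.atleast_1d(sdi)[i]:g} (overflow or undefined term)"
        )
    scalar = all(np.isscalar(v) for v in (cov.si, cov.adbh, cov.sdi))
    return float(out) if scalar else out
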