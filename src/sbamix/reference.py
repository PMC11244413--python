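"""Published reference values for *Populus davidiana* × *Betula platyphylla*
broad-leaved mixed stands (Mulan Rangeland State Forest, Hebei, China;
58 plots of 30 m × 30 m).

Three coefficient collections are kept:

* :data:`NLS_COEFFICIENTS` — equation-wise nonlinear least-squares estimates
  of the six extended forms, per species;
* :data:`AP_COEFFICIENTS` — the proportional-adjustment (AP) additive
  system (species shares of a total-stand model);
* :data:`NSUR_COEFFICIENTS` — the nonlinear seemingly-unrelated-regression
  additive system.

plus per-method goodness-of-fit metrics (:data:`METHOD_METRICS`) and the
covariate summary (:data:`COVARIATE_SUMMARY`) used to calibrate the
synthetic plot generator. Species keys: ``"P"`` (*P. davidiana*), ``"B"``
(*B. platyphylla*), ``"total"`` (whole stand).

These values serve as default optimizer starting points and as generating
truths for simulation; they are not substitutes for fitting to data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CoefficientSet",
    "NLS_COEFFICIENTS",
    "AP_COEFFICIENTS",
    "NSUR_COEFFICIENTS",
    "METHOD_METRICS",
    "COVARIATE_SUMMARY",
    "coefficient_set",
    "start_centres",
]


@dataclass(frozen=True)
class CoefficientSet:
    """A published coefficient vector with its reported uncertainty/fit."""

    form_id: str
    b: tuple[float, ...]
    se: tuple[float, ...]
    rmse: float | None = None
    r2_adj: float | None = None

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.b, dtype=float)


# Equation-wise NLS fits of the extended forms, by species then form.
NLS_COEFFICIENTS: dict[str, dict[str, CoefficientSet]] = {
    "P": {
        "M1": CoefficientSet("M1", (0.013, 0.289, 4.454, 1.029), (0.002, 0.032, 1.042, 0.020)),
        "M2": CoefficientSet("M2", (14.026, 0.290, 2.196, 1.020), (1.661, 0.034, 0.769, 0.020)),
        "M3": CoefficientSet("M3", (-3.377, -30.547, 0.801, 0.452, 6.049, -4.446), (0.650, 16.450, 0.123, 0.162, 3.223, 4.101)),
        "M4": CoefficientSet("M4", (2.105, 12.677, 0.894, 0.485, 3.559, -5.384), (0.257, 6.345, 0.093, 0.086, 2.385, 2.224)),
        "M5": CoefficientSet("M5", (31.156, 0.216, 0.002, 2.243, 0.483), (13.690, 0.043, 0.004, 0.271, 0.066)),
        "M6": CoefficientSet("M6", (23.576, 0.288, 0.001, 6.593, 0.157), (18.991, 0.032, 0.001, 1.808, 0.041)),
    },
    "B": {
        "M1": CoefficientSet("M1", (0.012, 0.285, 3.867, 1.030), (0.002, 0.033, 1.131, 0.020)),
        "M2": CoefficientSet("M2", (10.301, 0.423, 1.443, 1.034), (1.770, 0.062, 0.893, 0.017)),
        "M3": CoefficientSet("M3", (-4.862, 1.667, 1.073, 0.374, -1.466, 1.531), (1.308, 4.418, 0.110, 0.334, 3.450, 8.214)),
        "M4": CoefficientSet("M4", (2.163, 2.644, 1.053, 0.505, -0.648, -2.134), (0.414, 9.992, 0.074, 0.183, 2.272, 4.570)),
        "M5": CoefficientSet("M5", (16.121, 0.775, 0.013, 1.014, 0.424), (40.244, 0.474, 0.047, 1.597, 0.623)),
        "M6": CoefficientSet("M6", (19.954, 0.728, 0.002, 0.537, 0.931), (42.750, 0.417, 0.063, 0.317, 0.828)),
    },
}

# AP additive system: species M6/M1 shares of a Korf-type (M1-form) total.
AP_COEFFICIENTS: dict[str, CoefficientSet] = {
    "P": CoefficientSet("M6", (19.254, 0.307, 0.003, 6.808, 0.157), (10.378, 0.049, 0.001, 2.801, 0.065), rmse=0.709, r2_adj=0.981),
    "B": CoefficientSet("M1", (0.010, 0.377, 3.343, 1.032), (0.004, 0.081, 1.637, 0.029), rmse=0.678, r2_adj=0.979),
    "total": CoefficientSet("M1", (0.016, 0.264, 3.155, 1.001), (0.005, 0.048, 1.201, 0.028), rmse=1.776, r2_adj=0.939),
}

# NSUR additive system: species equations only; the total is structural.
NSUR_COEFFICIENTS: dict[str, CoefficientSet] = {
    "P": CoefficientSet("M6", (30.3645, 0.2701, 0.0002, 6.6979, 0.1498), (13.4303, 0.0315, 0.0001, 1.8965, 0.0429), rmse=0.6297, r2_adj=0.9870),
    "B": CoefficientSet("M1", (0.0080, 0.4216, 1.4756, 1.0338), (0.0026, 0.0615, 0.8851, 0.0210), rmse=0.4092, r2_adj=0.9858),
}
NSUR_TOTAL_RMSE = 0.6263
NSUR_TOTAL_R2_ADJ = 0.9757

# Goodness-of-fit of the three estimation methods, by stratum.
# MPE is reported on the proportion scale (Eq-literal percent / 100).
METHOD_METRICS: dict[str, dict[str, dict[str, float]]] = {
    "NLS": {
        "P": {"mae": 0.973, "mpe": 0.071, "rmse": 1.438, "r2": 0.965, "r2_adj": 0.963},
        "B": {"mae": 0.515, "mpe": 0.091, "rmse": 0.749, "r2": 0.963, "r2_adj": 0.961},
        "total": {"mae": 1.354, "mpe": 0.069, "rmse": 1.776, "r2": 0.942, "r2_adj": 0.939},
    },
    "AP": {
        "P": {"mae": 0.560, "mpe": 0.043, "rmse": 0.709, "r2": 0.982, "r2_adj": 0.981},
        "B": {"mae": 0.511, "mpe": 0.079, "rmse": 0.678, "r2": 0.980, "r2_adj": 0.979},
        "total": {"mae": 0.921, "mpe": 0.047, "rmse": 1.170, "r2": 0.965, "r2_adj": 0.960},
    },
    "NSUR": {
        "P": {"mae": 0.524, "mpe": 0.036, "rmse": 0.630, "r2": 0.987, "r2_adj": 0.987},
        "B": {"mae": 0.353, "mpe": 0.057, "rmse": 0.409, "r2": 0.986, "r2_adj": 0.986},
        "total": {"mae": 0.481, "mpe": 0.044, "rmse": 0.626, "r2": 0.979, "r2_adj": 0.976},
    },
}

# Covariate and response summary per stratum: {var: (max, min, sd, mean)}.
COVARIATE_SUMMARY: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "total": {
        "sba": (33.1, 5.6, 5.6, 19.1),
        "si": (24.0, 8.1, 3.7, 15.8),
        "dg": (21.8, 6.3, 3.9, 15.3),
        "adbh": (42.0, 17.0, 5.0, 28.0),
        "sdi": (985.8, 317.4, 245.7, 698.3),
    },
    "P": {
        "sba": (28.5, 3.1, 6.0, 12.9),
        "si": (23.6, 7.1, 3.9, 14.7),
        "dg": (23.6, 6.2, 4.1, 14.8),
        "adbh": (44.0, 14.0, 7.0, 26.0),
        "sdi": (849.8, 105.8, 185.8, 469.2),
    },
    "B": {
        "sba": (14.6, 2.7, 2.8, 6.2),
        "si": (21.4, 8.1, 3.2, 14.8),
        "dg": (27.6, 6.8, 5.2, 16.1),
        "adbh": (45.0, 13.0, 6.0, 29.0),
        "sdi": (547.1, 50.6, 183.1, 242.7),
    },
}

N_PLOTS = 58


def coefficient_set(method: str, stratum: str, form_id: str | None = None) -> CoefficientSet:
    """Look up a published coefficient set.

    ``method`` ∈ {"NLS", "AP", "NSUR"}; for NLS a ``form_id`` is required.
    """
    method = method.upper()
    if method == "NLS":
        if form_id is None:
            raise KeyError("NLS lookup needs a form_id (M1..M6)")
        return NLS_COEFFICIENTS[stratum][form_id]
    if method == "AP":
        return AP_COEFFICIENTS[stratum]
    if method == "NSUR":
        return NSUR_COEFFICIENTS[stratum]
    raise KeyError(f"unknown method {method!r}")


def start_centres(form_id: str) -> list[np.ndarray]:
    """All published coefficient vectors matching a form, for use as
    optimizer start centres."""
    centres: list[np.ndarray] = []
    for table in (NSUR_COEFFICIENTS, AP_COEFFICIENTS):
        for cs in table.values():
            if cs.form_id == form_id:
                centres.append(cs.values)
    for species in NLS_COEFFICIENTS.values():
        if form_id in species:
            centres.append(species[form_id].values)
    return centres
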