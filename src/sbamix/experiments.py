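"""Repeatable simulation experiments on the additive systems.

Parameter-recovery designs: generate plot tables from the published
coefficient sets, refit with the corresponding estimator, and count how
often every coefficient lands within 3 reported standard errors of its
generating value. The NSUR design uses the component-mode generator
(species surfaces + correlated errors); the AP design uses the share-mode
generator (total surface + share split).

A caveat the results make visible: at the published generating values the
Richards-type species surface (M6) operates with its saturation bracket in
the linear regime, so its scale and rate (b0, b2) are identified only
through the product b0·b2^b4. Point estimates then land on a weakly
identified ridge and per-coefficient Wald intervals for the scale pair
under-cover, however the standard errors are computed. The experiment
reports the strict every-coefficient rates alongside rates for the
well-identified subsets so the two effects can be told apart.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import reference
from .ap import fit_ap
from .nsur import fit_nsur
from .simulate import default_config, generate_plots

__all__ = ["nsur_recovery", "ap_recovery"]


def _rep_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def nsur_recovery(
    n_reps: int = 100,
    n_plots: int = 400,
    sigma_p: float = 0.6,
    sigma_b: float = 0.4,
    rho: float = 0.5,
    seed: int = 0,
) -> dict[str, float]:
    """NSUR recovery of the published system coefficients.

    Returns rates in percent: ``all`` (every coefficient of both species
    within 3 reported SE), ``species_p`` / ``species_b`` per equation, and
    ``identified`` (both species excluding the weakly identified M6
    scale/rate pair).
    """
    truth = {k: cs.values for k, cs in reference.NSUR_COEFFICIENTS.items()}
    forms = {k: cs.form_id for k, cs in reference.NSUR_COEFFICIENTS.items()}
    base = default_config(n_plots=n_plots, mode="component")
    hits = {"all": 0, "species_p": 0, "species_b": 0, "identified": 0}
    seeds = _rep_seeds(seed, n_reps)
    for rep, s in enumerate(seeds):
        cfg = replace(base, seed=int(s), sigma_p=sigma_p, sigma_b=sigma_b, rho=rho)
        table = generate_plots(cfg).table
        fit = fit_nsur(forms, table, seed=int(s) % 10_000)
        z = {
            k: np.abs(fit.species_params[k] - truth[k]) / fit.species_se[k]
            for k in ("P", "B")
        }
        ok_p = bool(np.all(z["P"] < 3))
        ok_b = bool(np.all(z["B"] < 3))
        hits["species_p"] += ok_p
        hits["species_b"] += ok_b
        hits["all"] += ok_p and ok_b
        # exclude the M6 (b0, b2) ridge pair from the identified subset
        ident_p = np.all(z["P"][[1, 3, 4]] < 3) if forms["P"] == "M6" else ok_p
        hits["identified"] += bool(ident_p) and ok_b
    return {k: 100.0 * v / n_reps for k, v in hits.items()}


def ap_recovery(
    n_reps: int = 100,
    n_plots: int = 300,
    sigma: float = 0.5,
    seed: int = 0,
) -> dict[str, float]:
    """AP recovery of the published system coefficients from share-mode data.

    ``sigma`` is used for both the total-equation and the share noise.
    Returns rates in percent: ``all`` (every coefficient of the total and
    both species equations within 3 reported SE), ``total`` for the
    whole-stand equation alone, and ``identified`` (total coefficients,
    non-scale species coefficients and the species scale ratio — the
    quantities the share structure actually determines).
    """
    truth = {k: cs.values for k, cs in reference.AP_COEFFICIENTS.items()}
    species_forms = {k: reference.AP_COEFFICIENTS[k].form_id for k in ("P", "B")}
    total_form = reference.AP_COEFFICIENTS["total"].form_id
    true_ratio = truth["P"][0] / truth["B"][0]
    base = default_config(n_plots=n_plots, mode="share")
    hits = {"all": 0, "total": 0, "identified": 0}
    seeds = _rep_seeds(seed + 1, n_reps)
    for rep, s in enumerate(seeds):
        cfg = replace(base, seed=int(s), sigma_p=sigma, sigma_t=sigma)
        table = generate_plots(cfg).table
        fit = fit_ap(total_form, species_forms, table, seed=int(s) % 10_000)
        z_t = np.abs(fit.total_fit.params - truth["total"]) / fit.total_fit.se
        z_p = np.abs(fit.species_params["P"] - truth["P"]) / fit.species_se["P"]
        z_b = np.abs(fit.species_params["B"] - truth["B"]) / fit.species_se["B"]
        ok_t = bool(np.all(z_t < 3))
        hits["total"] += ok_t
        hits["all"] += ok_t and bool(np.all(z_p < 3)) and bool(np.all(z_b < 3))
        z_ratio = abs(fit.scale_ratio - true_ratio) / fit.scale_ratio_se
        ident = (
            ok_t
            and bool(np.all(z_p[[1, 3, 4]] < 3))  # M6 exponents
            and bool(np.all(z_b[1:] < 3))
            and bool(z_ratio < 3)
        )
        hits["identified"] += ident
    return {k: 100.0 * v / n_reps for k, v in hits.items()}
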