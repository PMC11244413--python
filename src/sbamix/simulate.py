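"""Synthetic plot-table generator.

Emulates the covariate structure of the study stands (58 plots of
*P. davidiana* × *B. platyphylla* mixed forest): site index, breast-height
age, quadratic mean DBH and stand density index are drawn independently
per stratum from truncated normals calibrated to the published per-stratum
summary (mean, SD, min, max), and responses are generated from published
coefficient sets with cross-species correlated Gaussian errors.

Two generation modes:

* ``"component"`` (default) — species SBAs are their model surfaces plus a
  correlated error pair (σ_P, σ_B, ρ); the stand total is the *exact*
  component sum. This is the data-generating scheme matching the NSUR
  system, calibrated by default to its published coefficient sets.
* ``"share"`` — the stand total follows the whole-stand surface plus noise
  (σ_t), and the species SBAs are share-weighted splits of the observed
  total with share noise (σ_P on SBA_P; SBA_B is the complement, so
  additivity is exact). This matches the AP system, calibrated by default
  to its published sets.

Negative basal areas are handled by rejection (redrawing the error, up to
``max_attempts`` per plot) rather than truncation, to avoid biasing the
error distribution near the boundary. Regeneration from the same
(config, seed) is bit-identical.

The study's true residual SDs and cross-species error correlation are not
published; the defaults (σ_P = 0.63, σ_B = 0.41 from the reported species
RMSEs, ρ = 0.5) are documented stand-ins.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import reference
from .data import PlotTable
from .exceptions import ConfigError
from .forms import CovariateSet, get_form, predict_unchecked

__all__ = [
    "CovariateSpec",
    "StratumSpec",
    "GeneratingEquation",
    "SyntheticConfig",
    "GenerationRecord",
    "default_config",
    "generate_plots",
]


@dataclass(frozen=True)
class CovariateSpec:
    """Truncated-normal spec: mean/sd on [minimum, maximum]."""

    mean: float
    sd: float
    minimum: float
    maximum: float

    def validate(self, name: str = "covariate") -> None:
        if not (self.minimum < self.mean < self.maximum):
            raise ConfigError(f"{name}: need min < mean < max")
        if self.sd <= 0:
            raise ConfigError(f"{name}: sd must be > 0")

    def rvs(self, rng: np.random.Generator, n: int) -> np.ndarray:
        a = (self.minimum - self.mean) / self.sd
        b = (self.maximum - self.mean) / self.sd
        return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)


@dataclass(frozen=True)
class StratumSpec:
    si: CovariateSpec
    adbh: CovariateSpec
    sdi: CovariateSpec
    dg: CovariateSpec

    def validate(self, stratum: str) -> None:
        for name in ("si", "adbh", "sdi", "dg"):
            getattr(self, name).validate(f"{stratum}.{name}")


@dataclass(frozen=True)
class GeneratingEquation:
    """A model form plus the coefficient vector generating the response."""

    form_id: str
    coefficients: tuple[float, ...]

    def surface(self, cov: CovariateSet) -> np.ndarray:
        return np.atleast_1d(
            predict_unchecked(self.form_id, np.asarray(self.coefficients), cov)
        )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of one synthetic plot table."""

    n_plots: int = reference.N_PLOTS
    seed: int = 0
    mode: str = "component"
    covariates: dict[str, StratumSpec] = field(default_factory=dict)
    species: dict[str, GeneratingEquation] = field(default_factory=dict)
    total: GeneratingEquation | None = None
    sigma_p: float = 0.63
    sigma_b: float = 0.41
    rho: float = 0.5
    sigma_t: float = 1.776
    max_attempts: int = 100

    def validate(self) -> None:
        if self.n_plots < 1:
            raise ConfigError("n_plots must be >= 1")
        if self.mode not in ("component", "share"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if set(self.covariates) != {"P", "B", "total"}:
            raise ConfigError("covariates must cover strata P, B and total")
        for k, spec in self.covariates.items():
            spec.validate(k)
        if set(self.species) != {"P", "B"}:
            raise ConfigError("species equations must cover P and B")
        if self.sigma_p < 0 or self.sigma_b < 0 or self.sigma_t < 0:
            raise ConfigError("error SDs must be >= 0")
        if not -1 < self.rho < 1:
            raise ConfigError("|rho| must be < 1")
        if self.mode == "share" and self.total is None:
            raise ConfigError("share mode needs a total generating equation")
        if self.max_attempts < 1:
            raise ConfigError("max_attempts must be >= 1")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=repr)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class GenerationRecord:
    """A generated table plus the truth behind it."""

    table: PlotTable
    true_params: dict
    true_errors: pd.DataFrame
    config: SyntheticConfig
    config_hash: str


def _stratum_spec(stratum: str) -> StratumSpec:
    s = reference.COVARIATE_SUMMARY[stratum]
    def spec(var: str) -> CovariateSpec:
        mx, mn, sd, mean = s[var]
        return CovariateSpec(mean=mean, sd=sd, minimum=mn, maximum=mx)
    return StratumSpec(si=spec("si"), adbh=spec("adbh"), sdi=spec("sdi"), dg=spec("dg"))


def default_config(
    n_plots: int = reference.N_PLOTS, seed: int = 0, mode: str = "component"
) -> SyntheticConfig:
    """The calibrated default configuration.

    Covariate distributions follow the published per-stratum summary.
    ``component`` mode generates species responses from the NSUR
    coefficient sets (P: M6, B: M1); ``share`` mode generates the total
    from the AP whole-stand set and species as shares from the AP species
    sets, with σ_t and σ_P defaulting to the corresponding reported RMSEs.
    """
    covariates = {s: _stratum_spec(s) for s in ("P", "B", "total")}
    if mode == "component":
        species = {
            k: GeneratingEquation(cs.form_id, cs.b)
            for k, cs in reference.NSUR_COEFFICIENTS.items()
        }
        return SyntheticConfig(
            n_plots=n_plots, seed=seed, mode=mode, covariates=covariates,
            species=species, sigma_p=0.63, sigma_b=0.41, rho=0.5,
        )
    if mode == "share":
        species = {
            k: GeneratingEquation(cs.form_id, cs.b)
            for k, cs in reference.AP_COEFFICIENTS.items()
            if k in ("P", "B")
        }
        tot = reference.AP_COEFFICIENTS["total"]
        return SyntheticConfig(
            n_plots=n_plots, seed=seed, mode=mode, covariates=covariates,
            species=species, total=GeneratingEquation(tot.form_id, tot.b),
            sigma_p=0.709, sigma_t=1.776,
        )
    raise ConfigError(f"unknown mode {mode!r}")


def _draw_covariates(cfg: SyntheticConfig, rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    out = {}
    for stratum in ("P", "B", "total"):
        spec = cfg.covariates[stratum]
        out[stratum] = pd.DataFrame(
            {
                "si": spec.si.rvs(rng, cfg.n_plots),
                "adbh": spec.adbh.rvs(rng, cfg.n_plots),
                "sdi": spec.sdi.rvs(rng, cfg.n_plots),
                "dg": spec.dg.rvs(rng, cfg.n_plots),
            }
        )
    return out


def _rejection_draw(
    rng: np.random.Generator,
    draw: "callable",
    accept: "callable",
    n: int,
    max_attempts: int,
    what: str,
):
    """Per-plot rejection: redraw until accepted or the budget is spent."""
    value = draw(n)
    ok = accept(value)
    attempts = np.ones(n, dtype=int)
    while not np.all(ok):
        idx = np.flatnonzero(~ok)
        if np.any(attempts[idx] >= max_attempts):
            raise ConfigError(
                f"rejection budget exhausted while drawing {what} "
                f"({max_attempts} attempts); the error spec is too wide for "
                "the mean surface"
            )
        fresh = draw(idx.size)
        if isinstance(value, tuple):
            for v, f in zip(value, fresh):
                v[idx] = f
        else:
            value[idx] = fresh
        ok = accept(value)
        attempts[idx] += 1
    return value


def generate_plots(config: SyntheticConfig) -> GenerationRecord:
    """Generate a synthetic plot table from a validated configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    covs = _draw_covariates(config, rng)
    n = config.n_plots

    def covset(stratum: str) -> CovariateSet:
        c = covs[stratum]
        return CovariateSet(
            si=c["si"].to_numpy(), adbh=c["adbh"].to_numpy(), sdi=c["sdi"].to_numpy()
        )

    mu_p = config.species["P"].surface(covset("P"))
    mu_b = config.species["B"].surface(covset("B"))
    if not (np.all(np.isfinite(mu_p)) and np.all(np.isfinite(mu_b))):
        raise ConfigError("species generating surface not evaluable at drawn covariates")

    if config.mode == "component":
        # closed-form Cholesky factor; valid for zero SDs too
        L = np.array(
            [
                [config.sigma_p, 0.0],
                [config.rho * config.sigma_b, config.sigma_b * np.sqrt(1 - config.rho**2)],
            ]
        )

        def draw_full(m):
            z = rng.standard_normal((m, 2))
            e = z @ L.T
            return e[:, 0], e[:, 1]

        if config.sigma_p == 0 and config.sigma_b == 0:
            e_p, e_b = np.zeros(n), np.zeros(n)
        else:
            e_p, e_b = _rejection_draw(
                rng,
                draw_full,
                lambda e: (mu_p + e[0] > 0) & (mu_b + e[1] > 0),
                n,
                config.max_attempts,
                "species errors",
            )
        sba_p = mu_p + e_p
        sba_b = mu_b + e_b
        sba_t = sba_p + sba_b
        true_errors = pd.DataFrame({"e_p": e_p, "e_b": e_b})
    else:  # share mode
        mu_t = config.total.surface(covset("total"))
        if not np.all(np.isfinite(mu_t)):
            raise ConfigError("total generating surface not evaluable at drawn covariates")
        if config.sigma_t == 0:
            e_t = np.zeros(n)
        else:
            e_t = _rejection_draw(
                rng,
                lambda m: rng.normal(0.0, config.sigma_t, m),
                lambda e: mu_t + e > 0,
                n,
                config.max_attempts,
                "total errors",
            )
        sba_t = mu_t + e_t
        w = mu_p / (mu_p + mu_b)
        if config.sigma_p == 0:
            e_p = np.zeros(n)
        else:
            e_p = _rejection_draw(
                rng,
                lambda m: rng.normal(0.0, config.sigma_p, m),
                lambda e: (w * sba_t + e > 0) & (w * sba_t + e < sba_t),
                n,
                config.max_attempts,
                "share errors",
            )
        sba_p = w * sba_t + e_p
        sba_b = sba_t - sba_p
        true_errors = pd.DataFrame({"e_t": e_t, "e_p": e_p})

    frame = {"plot_id": [f"plot_{i+1:04d}" for i in range(n)]}
    for stratum, suffix in (("P", "p"), ("B", "b"), ("total", "t")):
        c = covs[stratum]
        frame[f"si_{suffix}"] = c["si"].to_numpy()
        frame[f"adbh_{suffix}"] = c["adbh"].to_numpy()
        frame[f"sdi_{suffix}"] = c["sdi"].to_numpy()
        frame[f"dg_{suffix}"] = c["dg"].to_numpy()
        # back out the stem count from the Reineke identity
        frame[f"n_stems_{suffix}"] = c["sdi"].to_numpy() * (20.0 / c["dg"].to_numpy()) ** 1.605
    frame["sba_p"], frame["sba_b"], frame["sba_t"] = sba_p, sba_b, sba_t
    table = PlotTable(pd.DataFrame(frame), provenance=f"synthetic:{config.hash()}")
    true_params = {
        "species": {k: dict(form=v.form_id, b=list(v.coefficients)) for k, v in config.species.items()},
        "total": None if config.total is None else dict(form=config.total.form_id, b=list(config.total.coefficients)),
        "sigma_p": config.sigma_p, "sigma_b": config.sigma_b, "rho": config.rho,
        "sigma_t": config.sigma_t, "mode": config.mode,
    }
    return GenerationRecord(table, true_params, true_errors, config, config.hash())
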