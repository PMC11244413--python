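"""Goodness-of-fit metrics, ten-fold cross-validation, and method
comparison arithmetic.

The five fit statistics, for observed :math:`y_i`, predicted
:math:`\\hat y_i`, :math:`n` plots and :math:`p` model parameters:

.. math::

    MAE  &= \\tfrac1n \\sum |y_i - \\hat y_i| \\\\
    MPE  &= \\frac{\\sum |y_i - \\hat y_i|}{\\sum y_i} \\times 100\\% \\\\
    RMSE &= \\sqrt{\\tfrac1n \\sum (y_i - \\hat y_i)^2} \\\\
    R^2  &= 1 - \\frac{\\sum (y_i - \\hat y_i)^2}{\\sum (y_i - \\bar y)^2} \\\\
    R^2_{adj} &= 1 - \\frac{n-1}{n-p} (1 - R^2)

MPE here is an aggregate relative absolute error. It is computed literally
on the percent scale; published comparison tables for this system print it
as a proportion, so :meth:`MetricsReport.mpe_proportion` offers that
display. Percent-change comparisons between methods are scale-invariant
either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .data import PlotTable
from .exceptions import DomainError

__all__ = [
    "MetricsReport",
    "CVReport",
    "PercentChange",
    "compute_metrics",
    "cross_validate",
    "percent_change",
    "compare_methods",
]


@dataclass(frozen=True)
class MetricsReport:
    """Fit statistics for one equation on one dataset.

    ``mae``/``rmse`` in m² ha⁻¹, ``mpe`` in percent, ``r2``/``r2_adj``
    dimensionless. ``undefined`` lists metrics that could not be computed
    (NaN-valued) rather than raising.
    """

    mae: float
    mpe: float
    rmse: float
    r2: float
    r2_adj: float
    n_obs: int
    n_params: int
    undefined: tuple[str, ...] = ()

    @property
    def mpe_proportion(self) -> float:
        """MPE on the proportion scale (percent / 100)."""
        return self.mpe / 100.0


def compute_metrics(y, yhat, n_params: int) -> MetricsReport:
    """Compute MAE, MPE, RMSE, R² and adjusted R².

    Zero total SBA (MPE) or zero response variance (R²) yield NaN for the
    affected metric, flagged in ``undefined``, not an exception.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise DomainError("y and yhat must have equal length")
    n = y.size
    if n < 2:
        raise DomainError("metrics need at least 2 observations")
    e = y - yhat
    abs_sum = float(np.sum(np.abs(e)))
    sse = float(np.dot(e, e))
    sst = float(np.sum((y - y.mean()) ** 2))
    total = float(np.sum(y))

    undefined: list[str] = []
    mae = abs_sum / n
    rmse = float(np.sqrt(sse / n))
    if total > 0:
        mpe = abs_sum / total * 100.0
    else:
        mpe = float("nan")
        undefined.append("mpe")
    if sst > 0:
        r2 = 1.0 - sse / sst
    else:
        r2 = float("nan")
        undefined.append("r2")
    if n > n_params and sst > 0:
        r2_adj = 1.0 - (n - 1) / (n - n_params) * (1.0 - r2)
    else:
        r2_adj = float("nan")
        if "r2" not in undefined:
            undefined.append("r2_adj")
    return MetricsReport(mae, mpe, rmse, r2, r2_adj, n, int(n_params), tuple(undefined))


@dataclass(frozen=True)
class PercentChange:
    """A signed relative change between two metric values.

    ``percent`` is the magnitude; ``direction`` is ``"decrease"``,
    ``"increase"`` or ``"unchanged"``. The convention: a decrease is
    reported as (before − after)/before × 100, an increase as
    (after − before)/before × 100, both as positive magnitudes.
    """

    percent: float
    direction: str

    @property
    def signed(self) -> float:
        """Signed change (after − before)/before × 100; negative = decrease."""
        return -self.percent if self.direction == "decrease" else self.percent


def percent_change(before: float, after: float) -> PercentChange:
    """Relative change of a metric between two methods."""
    if not np.isfinite(before) or before <= 0:
        raise DomainError("percent_change needs a positive, finite baseline")
    if after == before:
        return PercentChange(0.0, "unchanged")
    if after < before:
        return PercentChange((before - after) / before * 100.0, "decrease")
    return PercentChange((after - before) / before * 100.0, "increase")


def compare_methods(
    metrics_before: dict, metrics_after: dict, keys: tuple[str, ...] = ("mae", "mpe", "rmse")
) -> dict[str, PercentChange]:
    """Percent change per metric between two methods' metric dicts."""
    get = lambda m, k: m[k] if isinstance(m, dict) else getattr(m, k)
    return {k: percent_change(get(metrics_before, k), get(metrics_after, k)) for k in keys}


@dataclass
class CVReport:
    """Result of a k-fold cross-validation.

    ``fold_assignments`` maps plot_id → fold index (1…k). ``pooled`` holds
    metrics on the concatenated out-of-fold predictions; ``per_fold`` one
    report per fold (None where the training fit failed, with the message
    recorded in ``failures``).
    """

    fold_assignments: dict
    per_fold: list
    pooled: MetricsReport
    seed: int
    k: int
    failures: list = field(default_factory=list)

    @property
    def has_failures(self) -> bool:
        return len(self.failures) > 0


def make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle, then contiguous blocks; sizes differ by at most 1."""
    if n < k:
        raise DomainError(f"cannot make {k} folds from {n} plots")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(block) for block in np.array_split(perm, k)]


def cross_validate(
    fit: Callable[[PlotTable], Callable[[PlotTable], np.ndarray]],
    table: PlotTable,
    response: str,
    n_params: int,
    k: int = 10,
    seed: int = 0,
) -> CVReport:
    """k-fold cross-validation of an arbitrary fit procedure.

    Parameters
    ----------
    fit:
        ``fit(train_table)`` returns a predictor; ``predictor(test_table)``
        returns predicted SBA for the response stratum.
    table:
        The full plot table.
    response:
        Stratum whose observed SBA is scored: ``"P"``, ``"B"`` or ``"total"``.
    n_params:
        Parameter count of the refitted equation, used in adjusted R².
    k, seed:
        Fold count (default ten-fold) and shuffle seed; the same seed
        reproduces the same fold assignment exactly.
    """
    n = len(table)
    folds = make_folds(n, k, seed)
    assignments = {}
    per_fold: list = []
    failures: list = []
    oof_y: list[np.ndarray] = []
    oof_yhat: list[np.ndarray] = []
    for fold_idx, test_idx in enumerate(folds, start=1):
        for pid in table.df["plot_id"].iloc[test_idx]:
            assignments[pid] = fold_idx
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        train, test = table.subset(train_idx), table.subset(test_idx)
        try:
            predictor = fit(train)
            yhat = np.asarray(predictor(test), dtype=float)
        except Exception as exc:  # fold failure is reported, not fatal
            failures.append((fold_idx, f"{type(exc).__name__}: {exc}"))
            per_fold.append(None)
            continue
        y = test.sba(response)
        oof_y.append(y)
        oof_yhat.append(yhat)
        per_fold.append(compute_metrics(y, yhat, n_params))
    if not oof_y:
        raise DomainError("all cross-validation folds failed")
    pooled = compute_metrics(np.concatenate(oof_y), np.concatenate(oof_yhat), n_params)
    return CVReport(assignments, per_fold, pooled, seed, k, failures)
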