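"""Plot-level tabular data model and delimited-text I/O.

The canonical layout is *wide*: one row per sample plot, with per-stratum
columns suffixed ``_p`` (*P. davidiana*), ``_b`` (*B. platyphylla*) and
``_t`` (whole stand):

``plot_id, si_p, adbh_p, sdi_p, dg_p, n_stems_p, sba_p, si_b, …, sba_t``

``dg`` (quadratic mean DBH, cm) and ``n_stems`` (trees ha⁻¹) are optional;
when ``sdi`` is absent it is derived from them via the Reineke identity.
A long layout (one row per plot × stratum with a ``stratum`` column) can be
ingested and is converted to wide on read.

Physical invariant: where all three basal areas are observed,
``sba_t == sba_p + sba_b`` within 1e−6 m² ha⁻¹ — basal area is a sum, and a
larger discrepancy is a data error, not noise. Records missing an observed
SBA for some stratum are retained (usable for single-equation fits) but are
excluded from system fits, which need complete triples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError
from .forms import CovariateSet, compute_sdi

__all__ = [
    "STRATA",
    "PlotTable",
    "read_plot_table",
    "write_plot_table",
    "load_column_map",
]

#: Stratum keys and their column suffixes.
STRATA: dict[str, str] = {"P": "p", "B": "b", "total": "t"}

ADDITIVITY_TOL = 1e-6

_COVARIATE_FIELDS = ("si", "adbh", "sdi")
_OPTIONAL_FIELDS = ("dg", "n_stems")
_ALL_FIELDS = _COVARIATE_FIELDS + _OPTIONAL_FIELDS + ("sba",)


def _canonical_columns() -> list[str]:
    cols = ["plot_id"]
    for suffix in STRATA.values():
        cols += [f"{f}_{suffix}" for f in _ALL_FIELDS]
    return cols


@dataclass
class PlotTable:
    """An ordered, validated collection of plot records (wide layout)."""

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        df = self.df
        if "plot_id" not in df.columns:
            raise SchemaError("missing required column 'plot_id'")
        for suffix in STRATA.values():
            for f in _COVARIATE_FIELDS + ("sba",):
                col = f"{f}_{suffix}"
                if col not in df.columns:
                    raise SchemaError(f"missing required column {col!r}")
        if len(df) == 0:
            return
        if df["plot_id"].duplicated().any():
            dup = df.loc[df["plot_id"].duplicated(), "plot_id"].iloc[0]
            raise ValidationError(f"duplicate plot_id {dup!r}")
        for suffix in STRATA.values():
            for f in _ALL_FIELDS:
                col = f"{f}_{suffix}"
                if col not in df.columns:
                    continue
                v = pd.to_numeric(df[col], errors="coerce")
                bad = v.notna() & (v <= 0)
                if f != "sba":
                    bad |= df[col].notna() & v.isna()
                if bad.any():
                    pid = df.loc[bad, "plot_id"].iloc[0]
                    raise ValidationError(
                        f"plot {pid!r}: field {col!r} must be positive"
                    )
        complete = df[["sba_p", "sba_b", "sba_t"]].notna().all(axis=1)
        gap = (df["sba_p"] + df["sba_b"] - df["sba_t"]).abs()
        bad = complete & (gap > ADDITIVITY_TOL)
        if bad.any():
            pid = df.loc[bad, "plot_id"].iloc[0]
            raise ValidationError(
                f"plot {pid!r}: sba_p + sba_b differs from sba_t by "
                f"{gap[bad].iloc[0]:.3g} m²·ha⁻¹ (> {ADDITIVITY_TOL:g}); "
                "basal area must be additive"
            )

    # -- accessors -------------------------------------------------------
    def covariates(self, stratum: str) -> CovariateSet:
        """Covariate arrays for one stratum ('P', 'B' or 'total')."""
        s = STRATA[stratum]
        return CovariateSet(
            si=self.df[f"si_{s}"].to_numpy(float),
            adbh=self.df[f"adbh_{s}"].to_numpy(float),
            sdi=self.df[f"sdi_{s}"].to_numpy(float),
        )

    def sba(self, stratum: str) -> np.ndarray:
        return self.df[f"sba_{STRATA[stratum]}"].to_numpy(float)

    def complete_triples(self) -> "PlotTable":
        """Subset with all three observed SBAs present (for system fits)."""
        mask = self.df[["sba_p", "sba_b", "sba_t"]].notna().all(axis=1)
        return PlotTable(self.df.loc[mask].copy(), provenance=self.provenance)

    def subset(self, index) -> "PlotTable":
        return PlotTable(self.df.iloc[np.asarray(index)].copy(), provenance=self.provenance)


def load_column_map(path: "str | Path") -> dict:
    """Read a column map from a YAML or JSON config file.

    The map sends canonical names (``si_p``, ``sba_t``, …; optionally
    ``plot_id``, ``stratum``) to the column names found in the data file.
    """
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        return dict(yaml.safe_load(text))
    return dict(json.loads(text))


def _derive_sdi(df: pd.DataFrame) -> pd.DataFrame:
    for suffix in STRATA.values():
        sdi, dg, ns = f"sdi_{suffix}", f"dg_{suffix}", f"n_stems_{suffix}"
        if sdi not in df.columns:
            df[sdi] = np.nan
        need = df[sdi].isna()
        if need.any():
            if dg not in df.columns or ns not in df.columns:
                raise SchemaError(
                    f"column {sdi!r} absent and ({ns!r}, {dg!r}) not both "
                    "available to derive it"
                )
            sub = df.loc[need]
            if sub[[dg, ns]].isna().any().any():
                pid = sub.loc[sub[[dg, ns]].isna().any(axis=1), "plot_id"].iloc[0]
                raise ValidationError(
                    f"plot {pid!r}: sdi missing and (n_stems, dg) incomplete"
                )
            df.loc[need, sdi] = compute_sdi(
                sub[ns].to_numpy(float), sub[dg].to_numpy(float)
            )
    return df


def _long_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    if "stratum" not in df.columns:
        raise SchemaError("long layout requires a 'stratum' column")
    suffix_of = {**{k: v for k, v in STRATA.items()}, "p": "p", "b": "b", "t": "t"}
    wide: dict[str, pd.DataFrame] = {}
    for name, sub in df.groupby("stratum", sort=False):
        key = suffix_of.get(str(name))
        if key is None:
            raise SchemaError(f"unknown stratum label {name!r} in long layout")
        sub = sub.drop(columns=["stratum"]).set_index("plot_id")
        wide[key] = sub.add_suffix(f"_{key}")
    merged = pd.concat(wide.values(), axis=1).reset_index()
    return merged


def read_plot_table(
    path: "str | Path",
    column_map: dict | None = None,
    delimiter: str = ",",
    layout: str = "wide",
) -> PlotTable:
    """Read a delimited-text plot table.

    Parameters
    ----------
    path:
        CSV-dialect text file, UTF-8, header row, decimal point.
    column_map:
        Optional mapping from canonical column names to the names used in
        the file (inverted on read).
    delimiter:
        Field separator; comma by default.
    layout:
        ``"wide"`` (canonical) or ``"long"`` (one row per plot × stratum
        with a ``stratum`` column; converted on ingest).

    SDI is derived from ``(n_stems, dg)`` where absent. Raises
    :class:`SchemaError` for missing columns and :class:`ValidationError`
    (naming plot and field) for invariant breaches. Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise SchemaError(f"mapped column(s) {missing} not found in {path.name}")
        df = df.rename(columns=rename)
    if layout == "long":
        df = _long_to_wide(df)
    elif layout != "wide":
        raise SchemaError(f"unknown layout {layout!r}; use 'wide' or 'long'")
    if "plot_id" not in df.columns:
        raise SchemaError("missing required column 'plot_id'")
    df = _derive_sdi(df)
    return PlotTable(df, provenance=str(path))


def write_plot_table(
    table: PlotTable, path: "str | Path", delimiter: str = ","
) -> None:
    """Write a plot table; ``read(write(t))`` reproduces all numbers exactly.

    Optional columns that are entirely absent are omitted from the file.
    """
    df = table.df.copy()
    cols = [c for c in _canonical_columns() if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df = df[cols + extra]
    drop = [
        f"{f}_{s}"
        for s in STRATA.values()
        for f in _OPTIONAL_FIELDS
        if f"{f}_{s}" in df.columns and df[f"{f}_{s}"].isna().all()
    ]
    df = df.drop(columns=drop)
    # pandas writes shortest round-tripping repr for float64 by default
    df.to_csv(path, sep=delimiter, index=False)
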