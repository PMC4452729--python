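"""Cohort table I/O and derived behavioral measures.

A cohort is a pandas DataFrame with one row per animal. Design columns are
``animal_id, litter_id, prenatal, environment`` plus the binary
``perseveration`` flag and the assay ``batch``; measure columns are named
by the catalog; optional biochemical columns (protein immunoreactivity,
corticosterone) may follow. Empty cells are missing values (NaN), never
zero.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import DEFAULT_CATALOG, MeasureDefinition, measure_names, validate_catalog

logger = logging.getLogger(__name__)

PRENATAL_LEVELS = ("SAL", "VPA")
ENVIRONMENT_LEVELS = ("ST", "UE", "PE")
DESIGN_COLUMNS = ("animal_id", "litter_id", "prenatal", "environment")


def preference_index(social_sniff_s: float, object_sniff_s: float) -> float:
    """Social preference index: social / (social + object) sniffing time.

    Both times must be non-negative. If no sniffing occurred at all the
    index is undefined and NaN is returned with a warning.
    """
    social = np.asarray(social_sniff_s, dtype=float)
    obj = np.asarray(object_sniff_s, dtype=float)
    if np.any(social < 0) or np.any(obj < 0):
        raise ValueError("sniffing times must be non-negative")
    total = social + obj
    undefined = total == 0
    if np.any(undefined):
        warnings.warn("preference index undefined for zero total sniffing time")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(undefined, np.nan, social / np.where(undefined, np.nan, total))
    if out.ndim == 0:
        return float(out)
    return out


def freezing_percent(freeze_s: float, period_s: float) -> float:
    """Percent of a session spent freezing: 100 * freeze_s / period_s."""
    freeze = np.asarray(freeze_s, dtype=float)
    period = np.asarray(period_s, dtype=float)
    if np.any(period <= 0):
        raise ValueError("session period must be positive")
    if np.any(freeze < 0):
        raise ValueError("freezing time must be non-negative")
    if np.any(freeze > period):
        raise ValueError("freezing time exceeds session period")
    out = 100.0 * freeze / period
    if out.ndim == 0:
        return float(out)
    return out


def normalize_ir(
    values: Sequence[float],
    batches: Sequence,
    is_reference: Sequence[bool],
) -> np.ndarray:
    """Normalize immunoreactivity to percent of the reference-group batch mean.

    Each raw band volume is expressed as ``100 * value / mean(reference
    values of its own batch)``, where the reference animals are the
    control-group (SAL-ST) animals run in the *same* assay batch —
    normalization never pools across batches. Batches with no usable
    reference value get NaN for all their animals, with a logged warning.
    """
    values = np.asarray(values, dtype=float)
    batches = np.asarray(batches)
    ref = np.asarray(is_reference, dtype=bool)
    if not (len(values) == len(batches) == len(ref)):
        raise ValueError("values, batches and is_reference must have equal length")
    out = np.full(values.shape, np.nan)
    for b in pd.unique(batches):
        in_batch = batches == b
        ref_vals = values[in_batch & ref]
        ref_vals = ref_vals[~np.isnan(ref_vals)]
        if ref_vals.size == 0 or np.nanmean(ref_vals) <= 0:
            logger.warning("batch %r has no positive reference values; flagged missing", b)
            continue
        out[in_batch] = 100.0 * values[in_batch] / ref_vals.mean()
    return out


def _validate_design(df: pd.DataFrame, source: str) -> None:
    for col in DESIGN_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{source}: missing required design column {col!r}")
    dup = df["animal_id"][df["animal_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{source}: duplicated animal_id values: {sorted(dup.unique())}")
    for col, levels in (("prenatal", PRENATAL_LEVELS), ("environment", ENVIRONMENT_LEVELS)):
        bad = ~df[col].isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{source}: unknown {col} label {df[col].iloc[row]!r} in row {row} "
                f"(animal_id={df['animal_id'].iloc[row]!r}); allowed: {levels}"
            )


def _validate_ranges(df: pd.DataFrame, catalog: Sequence[MeasureDefinition]) -> None:
    by_name = {m.name: m for m in catalog}
    for name, m in by_name.items():
        if name not in df.columns:
            continue
        col = df[name]
        if m.unit == "%":
            bad = col.dropna()[(col.dropna() < 0) | (col.dropna() > 100)]
            if not bad.empty:
                raise ValueError(f"measure {name!r}: freezing percent outside [0, 100]")
        elif m.unit == "index":
            bad = col.dropna()[(col.dropna() < 0) | (col.dropna() > 1)]
            if not bad.empty:
                raise ValueError(f"measure {name!r}: index outside [0, 1]")
        elif m.unit in ("s", "cm", "count"):
            bad = col.dropna()[col.dropna() < 0]
            if not bad.empty:
                raise ValueError(f"measure {name!r}: negative values not allowed")


def read_cohort(
    path: str | Path,
    catalog: Sequence[MeasureDefinition] = DEFAULT_CATALOG,
) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Lines starting with ``#`` (metadata headers) are skipped. Category
    labels are validated against the allowed design levels; unknown labels
    and duplicated animal ids are hard errors naming the offending row.
    Empty numeric cells become NaN.
    """
    catalog = validate_catalog(catalog)
    df = pd.read_csv(path, comment="#", dtype={"animal_id": str, "litter_id": str})
    _validate_design(df, str(path))
    missing = [n for n in measure_names(catalog) if n not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort lacks catalog measure columns {missing}")
    if "perseveration" in df.columns:
        df["perseveration"] = df["perseveration"].astype("boolean")
    _validate_ranges(df, catalog)
    return df


def write_cohort(
    df: pd.DataFrame,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    """Write a cohort CSV with an optional ``#``-prefixed metadata header."""
    _validate_design(df, "write_cohort")
    out = df.copy()
    if "perseveration" in out.columns:
        # store booleans as 0/1 so the round-trip through CSV is exact
        out["perseveration"] = out["perseveration"].astype("boolean").astype("Int64")
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        out.to_csv(fh, index=False)
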