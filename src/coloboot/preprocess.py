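"""Parsing, validation and transformation of the per-sample table.

The pipeline applied to a raw sample table is, in order:

1. relevel the cleaning-frequency variables (coarsen ``Daily`` and
   ``Less than daily`` to the below-each-use level),
2. enforce structural applicability (teat-collected samples carry
   ``Not applicable`` for every machine/collection variable; bucket-collected
   samples additionally for every feeding-equipment variable),
3. derive the 3-level ``collection_source`` modelling variable,
4. natural-log transform both counts after adding 1,
5. drop records with missing data (no imputation),
6. centre and scale the continuous covariate on the retained records.

Standardisation parameters are computed once here and reused unchanged inside
every bootstrap replicate and cross-validation fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from . import schema
from .schema import (
    COLLECTION_POINTS,
    COLLECTION_SOURCE_MAP,
    NOT_APPLICABLE,
    NA_WHEN_NO_FEEDING,
    NA_WHEN_TEAT,
    RAW_COLUMNS,
    VARIABLES,
)


def log_transform(count):
    """Natural log of ``count + 1`` (log cfu/ml); 0 maps to 0.

    Accepts scalars or arrays; rejects negative or non-finite counts.
    """
    arr = np.asarray(count, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("count must be finite")
    if np.any(arr < 0):
        raise ValueError("count must be >= 0")
    out = np.log1p(arr)
    return float(out) if np.isscalar(count) or arr.ndim == 0 else out


def standardize(values) -> tuple[np.ndarray, float, float]:
    """Centre and scale to sample sd 1 (n-1 denominator).

    Returns ``(scaled, mean, sd)`` so the transform is invertible.
    Raises on fewer than 2 values or a constant vector.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("standardize needs at least 2 values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        raise ValueError("cannot standardize a constant variable")
    return (arr - mean) / sd, mean, sd


def unstandardize(scaled, mean: float, sd: float) -> np.ndarray:
    return np.asarray(scaled, dtype=float) * sd + mean


_FREQ_RAW_LEVELS = {"Each use", "Each calf", "Daily", "Less than daily",
                    "Less than each use", "Less than each calf", NOT_APPLICABLE}


def relevel_frequency(raw_level: str, target: str = "Less than each use") -> str:
    """Coarsen a cleaning-frequency level: sub-each-use recordings
    (``Daily``, ``Less than daily``) collapse to *target*."""
    if raw_level not in _FREQ_RAW_LEVELS:
        raise ValueError(f"unknown cleaning-frequency level: {raw_level!r}")
    if raw_level in ("Daily", "Less than daily"):
        return target
    return raw_level


def apply_structural_na(record: dict) -> dict:
    """Force management fields that are undefined for a record's collection
    point to the structural ``Not applicable`` level.

    Teat-collected samples never touch milking or feeding kit, so every
    equipment variable is undefined; bucket-collected samples are drawn before
    any feeding equipment, so the feeding-equipment variables are undefined.
    """
    rec = dict(record)
    point = rec.get("collection_point")
    if point is None:
        raise ValueError("collection_point must be populated")
    teat = point == "Cows teat"
    bucket = point == "Colostrum collection bucket"
    for var in VARIABLES:
        if var.na_rule is None or var.name not in rec:
            continue
        if var.na_rule == NA_WHEN_TEAT and teat:
            rec[var.name] = NOT_APPLICABLE
        elif var.na_rule == NA_WHEN_NO_FEEDING and (teat or bucket):
            rec[var.name] = NOT_APPLICABLE
    return rec


@dataclass
class PreprocessReport:
    """Exclusion accounting for one preprocessing run."""

    n_received: int
    n_removed_missing: int
    n_final: int
    per_rule: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_received - self.n_removed_missing != self.n_final:
            raise ValueError("inconsistent exclusion arithmetic")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2)


ExclusionRule = tuple[str, Callable[[pd.DataFrame], pd.Series]]


def default_exclusion_rules() -> list[ExclusionRule]:
    covariates = [v.name for v in VARIABLES if v.name != "collection_source"]
    return [
        ("missing_counts",
         lambda df: df[["tbc", "cc"]].isna().any(axis=1)),
        ("missing_collection_info",
         lambda df: df["collection_point"].isna()
         | df[[c for c in covariates if c in df.columns]].isna().any(axis=1)),
    ]


def filter_complete(
    df: pd.DataFrame, rules: Iterable[ExclusionRule] | None = None
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Drop records failing each named exclusion rule, tallying per rule.

    Rules are applied in order; a record already removed by an earlier rule is
    not counted again. Idempotent: re-running on the output removes nothing.
    """
    if rules is None:
        rules = default_exclusion_rules()
    n_received = len(df)
    removed = pd.Series(False, index=df.index)
    per_rule: dict[str, int] = {}
    for name, rule in rules:
        mask = rule(df).fillna(False).astype(bool) & ~removed
        per_rule[name] = int(mask.sum())
        removed |= mask
    kept = df.loc[~removed].copy()
    report = PreprocessReport(
        n_received=n_received,
        n_removed_missing=int(removed.sum()),
        n_final=len(kept),
        per_rule=per_rule,
    )
    return kept, report


@dataclass
class Dataset:
    """The analysis-ready sample table plus its variable metadata.

    ``frame`` holds one row per retained sample with the raw covariate levels,
    counts and their log transforms; ``standardization`` maps each continuous
    variable to the (mean, sd) computed on this dataset.
    """

    frame: pd.DataFrame
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def n_farms(self) -> int:
        return self.frame["farm_id"].nunique()

    def validate(self, for_modelling: bool = True) -> None:
        df = self.frame
        for var in VARIABLES:
            if var.kind != "categorical" or var.name not in df.columns:
                continue
            bad = set(df[var.name].dropna()) - set(var.levels)
            if bad:
                raise ValueError(f"{var.name}: values outside level set: {sorted(bad)}")
        if for_modelling and self.n_farms < 2:
            raise ValueError("modelling requires >= 2 distinct farms")

    def standardized(self, name: str) -> np.ndarray:
        """Continuous covariate on the frozen standardized scale."""
        mean, sd = self.standardization[name]
        return (self.frame[name].to_numpy(dtype=float) - mean) / sd

    def subset(self, indices) -> "Dataset":
        """Row subset (e.g. a bootstrap resample) keeping the frozen
        standardization parameters."""
        return Dataset(
            frame=self.frame.iloc[np.asarray(indices)].reset_index(drop=True),
            standardization=dict(self.standardization),
        )


def _relevel_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for name, target in (
        ("collection_cleaning_freq", "Less than each use"),
        ("feeding_cleaning_freq", "Less than each calf"),
    ):
        if name in df.columns:
            df[name] = df[name].map(
                lambda x: x if pd.isna(x) else relevel_frequency(str(x), target)
            )
    return df


def prepare(
    df: pd.DataFrame,
    rules: Iterable[ExclusionRule] | None = None,
) -> tuple[Dataset, PreprocessReport]:
    """Run the full preprocessing pipeline on a raw sample table."""
    missing_cols = [c for c in RAW_COLUMNS if c not in df.columns and c != "cow_id"]
    if missing_cols:
        raise ValueError(f"raw table missing columns: {missing_cols}")
    unknown_points = set(df["collection_point"].dropna()) - set(COLLECTION_POINTS)
    if unknown_points:
        raise ValueError(f"unknown collection points: {sorted(unknown_points)}")

    df = _relevel_frame(df)
    records = [apply_structural_na(rec) for rec in df.to_dict("records")]
    df = pd.DataFrame(records, columns=df.columns)
    df["collection_source"] = df["collection_point"].map(COLLECTION_SOURCE_MAP)

    kept, report = filter_complete(df, rules)
    kept["log_tbc"] = log_transform(kept["tbc"].to_numpy(dtype=float))
    kept["log_cc"] = log_transform(kept["cc"].to_numpy(dtype=float))

    standardization: dict[str, tuple[float, float]] = {}
    for name in schema.CONTINUOUS_TERMS:
        if name in kept.columns and len(kept) >= 2:
            _, mean, sd = standardize(kept[name].to_numpy(dtype=float))
            standardization[name] = (mean, sd)

    ds = Dataset(frame=kept.reset_index(drop=True), standardization=standardization)
    ds.validate(for_modelling=False)
    return ds, report


def read_csv(path) -> pd.DataFrame:
    """Read a raw sample CSV (UTF-8, comma-separated, canonical header)."""
    df = pd.read_csv(path, dtype={"farm_id": str, "cow_id": str})
    return df


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_dataset(path, rules=None) -> tuple[Dataset, PreprocessReport]:
    return prepare(read_csv(path), rules)
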