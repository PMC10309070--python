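"""Design-matrix encoding for EMR covariates and tumor volume.

Categorical variables are fully one-hot encoded with an explicit
missing-value level (e.g. "Not tested" for HPV status); continuous
variables are standardized by train-set statistics; tumor volume is
log-transformed before standardization.  The schema is fitted on the
training cohort only and then applied unchanged to any evaluation cohort,
so train and test matrices always share the same columns in the same order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["EncodingSchema", "FeatureMatrix", "fit_schema", "encode",
           "SchemaError"]

#: explicit missing level appended to every categorical variable
DEFAULT_MISSING_TOKENS = {"hpv_status": "Not tested"}
GENERIC_MISSING_TOKEN = "Missing"


class SchemaError(ValueError):
    pass


@dataclass
class EncodingSchema:
    """Fitted encoding: level lists, train statistics, transform flags."""

    categorical_levels: dict[str, list[str]]
    continuous_stats: dict[str, tuple[float, float]]  # name -> (mean, sd)
    log_transform: tuple[str, ...] = ()
    missing_levels: dict[str, str] = field(default_factory=dict)
    variable_order: tuple[str, ...] = ()

    def __post_init__(self):
        for var, levels in self.categorical_levels.items():
            if len(levels) == 0 or len(set(levels)) != len(levels):
                raise SchemaError(f"levels for {var!r} empty or duplicated")
        for var, (_, sd) in self.continuous_stats.items():
            if sd <= 0:
                raise SchemaError(f"SD for {var!r} must be > 0")

    @property
    def feature_names(self) -> list[str]:
        names = []
        for var in self.variable_order:
            if var in self.categorical_levels:
                names.extend(f"{var}={lvl}"
                             for lvl in self.categorical_levels[var])
            else:
                names.append(var)
        return names

    def to_json(self, path) -> None:
        payload = {
            "categorical_levels": self.categorical_levels,
            "continuous_stats": {k: list(v)
                                 for k, v in self.continuous_stats.items()},
            "log_transform": list(self.log_transform),
            "missing_levels": self.missing_levels,
            "variable_order": list(self.variable_order),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EncodingSchema":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            categorical_levels=payload["categorical_levels"],
            continuous_stats={k: tuple(v) for k, v in
                              payload["continuous_stats"].items()},
            log_transform=tuple(payload["log_transform"]),
            missing_levels=payload["missing_levels"],
            variable_order=tuple(payload["variable_order"]),
        )


@dataclass
class FeatureMatrix:
    """Numeric design matrix with named columns."""

    values: np.ndarray
    feature_names: list[str]
    schema: EncodingSchema | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)

    def hstack(self, other: "FeatureMatrix") -> "FeatureMatrix":
        return FeatureMatrix(np.hstack([self.values, other.values]),
                             self.feature_names + other.feature_names)


def fit_schema(train_cohort: pd.DataFrame, variables: Sequence[str],
               log_transform: Sequence[str] = ("volume_cc",),
               missing_tokens: dict[str, str] | None = None
               ) -> EncodingSchema:
    """Collect categorical levels and continuous statistics from train data.

    Every categorical variable gets an explicit missing level: the
    variable-specific token if configured ("Not tested" for HPV status),
    otherwise "Missing", appended when not already observed in training.
    """
    tokens = dict(DEFAULT_MISSING_TOKENS)
    if missing_tokens:
        tokens.update(missing_tokens)
    categorical_levels: dict[str, list[str]] = {}
    continuous_stats: dict[str, tuple[float, float]] = {}
    log_vars = tuple(v for v in log_transform if v in variables)

    for var in variables:
        if var not in train_cohort.columns:
            raise SchemaError(f"variable {var!r} not in cohort")
        col = train_cohort[var]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            missing = tokens.get(var, GENERIC_MISSING_TOKEN)
            if missing not in levels:
                levels.append(missing)
            categorical_levels[var] = levels
        else:
            x = col.to_numpy(float)
            if var in log_vars:
                x = np.log(x)
            mean, sd = float(x.mean()), float(x.std())
            if sd == 0:
                raise SchemaError(f"continuous variable {var!r} is constant "
                                  "in the training cohort")
            continuous_stats[var] = (mean, sd)

    missing_levels = {var: tokens.get(var, GENERIC_MISSING_TOKEN)
                      for var in categorical_levels}
    return EncodingSchema(
        categorical_levels=categorical_levels,
        continuous_stats=continuous_stats,
        log_transform=log_vars,
        missing_levels=missing_levels,
        variable_order=tuple(variables),
    )


def encode(cohort: pd.DataFrame, schema: EncodingSchema) -> FeatureMatrix:
    """Apply a fitted schema; unseen categorical levels map to the missing
    column, mirroring the missing-value-category mechanism."""
    blocks = []
    for var in schema.variable_order:
        if var in schema.categorical_levels:
            levels = schema.categorical_levels[var]
            index = {lvl: i for i, lvl in enumerate(levels)}
            missing_idx = index[schema.missing_levels[var]]
            codes = cohort[var].astype(str).map(
                lambda v: index.get(v, missing_idx)).to_numpy()
            block = np.zeros((len(cohort), len(levels)))
            block[np.arange(len(cohort)), codes] = 1.0
            blocks.append(block)
        else:
            x = cohort[var].to_numpy(float)
            if var in schema.log_transform:
                x = np.log(x)
            mean, sd = schema.continuous_stats[var]
            blocks.append(((x - mean) / sd)[:, None])
    return FeatureMatrix(np.hstack(blocks), schema.feature_names, schema)
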