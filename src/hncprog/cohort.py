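"""Synthetic head-and-neck cancer cohorts with known ground-truth hazards.

The generator emulates the tabular structure of a radiotherapy EMR cohort:
demographics (age, sex), clinical stage (T/N/overall), disease site,
performance status, HPV status (with an explicit "Not tested" level),
treatment variables (radiation dose in Gy, systemic-therapy flag), primary
tumor volume in cc, and right-censored overall-survival outcomes.  Survival
times are drawn from a discrete-time (monthly) proportional-hazard model

    h_k(x) = baseline_hazard[k] * exp(beta . x_encoded),   truncated at 1,

so every downstream model can be validated against a known risk ordering.
Censoring is administrative: a configurable fraction of patients receive a
censoring time drawn uniformly on [24, 84] months, which enforces the
cohort inclusion rule that censored patients have at least 2 years of
follow-up.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortConfig",
    "default_config",
    "generate_cohort",
    "apply_shift",
    "generate_feature_block",
    "split_by_date",
    "binarize_outcome",
    "true_linear_predictor",
    "write_cohort_csv",
    "read_cohort_csv",
    "config_from_yaml",
    "config_to_yaml",
    "CATEGORICAL_VARIABLES",
    "CONTINUOUS_VARIABLES",
    "EMR_VARIABLES",
]

#: categorical EMR variables and their order in the cohort table
CATEGORICAL_VARIABLES = (
    "sex",
    "t_stage",
    "n_stage",
    "overall_stage",
    "disease_site",
    "performance_status",
    "hpv_status",
)
CONTINUOUS_VARIABLES = ("age", "dose_gy", "chemotherapy")
EMR_VARIABLES = CATEGORICAL_VARIABLES + CONTINUOUS_VARIABLES

COHORT_COLUMNS = [
    "patient_id", "age", "sex", "t_stage", "n_stage", "overall_stage",
    "disease_site", "performance_status", "hpv_status", "dose_gy",
    "chemotherapy", "volume_cc", "time_months", "event", "diagnosis_index",
    "cohort_label",
]


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


def _default_covariate_specs() -> dict:
    # Mix chosen to resemble a definitive-radiotherapy HNC population:
    # male-dominated, mostly oropharynx, high stage-IV share, substantial
    # untested-HPV fraction.
    return {
        "age": {"kind": "normal", "mean": 62.0, "sd": 11.0},
        "sex": {"kind": "categorical",
                "probs": {"Male": 0.76, "Female": 0.24}},
        "t_stage": {"kind": "categorical",
                    "probs": {"T1": 0.17, "T2": 0.32, "T3": 0.31, "T4": 0.20}},
        "n_stage": {"kind": "categorical",
                    "probs": {"N0": 0.33, "N1": 0.12, "N2": 0.47, "N3": 0.08}},
        "overall_stage": {"kind": "categorical",
                          "probs": {"I": 0.12, "II": 0.15, "III": 0.23,
                                    "IV": 0.50}},
        "disease_site": {"kind": "categorical",
                         "probs": {"Oropharynx": 0.50, "Larynx": 0.20,
                                   "Nasopharynx": 0.12, "Hypopharynx": 0.05,
                                   "Oral cavity": 0.08, "Other": 0.05}},
        "performance_status": {"kind": "categorical",
                               "probs": {"ECOG 0": 0.45, "ECOG 1": 0.40,
                                         "ECOG 2": 0.10, "ECOG 3": 0.05}},
        "hpv_status": {"kind": "categorical",
                       "probs": {"Positive": 0.45, "Negative": 0.25,
                                 "Not tested": 0.30}},
        "dose_gy": {"kind": "normal", "mean": 66.0, "sd": 6.0},
        "chemotherapy": {"kind": "bernoulli", "p": 0.55},
    }


def _default_true_coefficients() -> dict:
    # Ground-truth log-hazard effects on the encoded scale (continuous
    # variables standardized by the config anchors, categoricals one-hot).
    # Signs follow established HNC prognostic factors: higher stage, worse
    # performance status and larger tumors are harmful; HPV positivity,
    # higher dose and systemic therapy are protective.
    return {
        "age": 0.35,
        "dose_gy": -0.20,
        "chemotherapy": -0.20,
        "log_volume": 0.50,
        "sex=Male": 0.10, "sex=Female": 0.0,
        "t_stage=T1": 0.0, "t_stage=T2": 0.20, "t_stage=T3": 0.45,
        "t_stage=T4": 0.75,
        "n_stage=N0": 0.0, "n_stage=N1": 0.10, "n_stage=N2": 0.30,
        "n_stage=N3": 0.60,
        "overall_stage=I": 0.0, "overall_stage=II": 0.10,
        "overall_stage=III": 0.25, "overall_stage=IV": 0.50,
        "disease_site=Oropharynx": 0.0, "disease_site=Larynx": 0.20,
        "disease_site=Nasopharynx": -0.20, "disease_site=Hypopharynx": 0.50,
        "disease_site=Oral cavity": 0.40, "disease_site=Other": 0.30,
        "performance_status=ECOG 0": 0.0, "performance_status=ECOG 1": 0.30,
        "performance_status=ECOG 2": 0.60, "performance_status=ECOG 3": 0.90,
        "hpv_status=Positive": -0.80, "hpv_status=Negative": 0.0,
        "hpv_status=Not tested": -0.10,
    }


@dataclass
class CohortConfig:
    """Full description of the simulated cohort's generating process.

    ``covariate_specs`` maps variable name to a distribution descriptor
    (``normal``/``categorical``/``bernoulli``); ``true_coefficients`` maps
    encoded feature names to log-hazard effects; ``standardization_anchors``
    holds the (mean, sd) pairs that define the encoded scale for continuous
    variables and are intentionally immune to distribution shifts, so that a
    shifted cohort shares the identical ground-truth model.
    """

    n_patients: int = 2552
    covariate_specs: dict = field(default_factory=_default_covariate_specs)
    volume_logmean: float = 3.0  # log cc; median tumor volume ~20 cc
    volume_logsd: float = 1.0
    true_coefficients: dict = field(default_factory=_default_true_coefficients)
    baseline_hazard: np.ndarray = field(
        default_factory=lambda: np.full(120, 0.004))
    censoring_rate: float = 0.55
    seed: int = 0
    cohort_label: str = "simulated"
    standardization_anchors: dict = field(default_factory=dict)

    def __post_init__(self):
        self.baseline_hazard = np.asarray(self.baseline_hazard, dtype=float)
        if not self.standardization_anchors:
            self.standardization_anchors = {
                "age": (self.covariate_specs["age"]["mean"],
                        self.covariate_specs["age"]["sd"]),
                "dose_gy": (self.covariate_specs["dose_gy"]["mean"],
                            self.covariate_specs["dose_gy"]["sd"]),
                "log_volume": (self.volume_logmean, self.volume_logsd),
            }
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name, spec in self.covariate_specs.items():
            if spec["kind"] == "categorical":
                total = sum(spec["probs"].values())
                if abs(total - 1.0) > 1e-8 or min(spec["probs"].values()) < 0:
                    raise ConfigurationError(
                        f"category probabilities for {name!r} must be "
                        f"nonnegative and sum to 1 (got {total})")
            elif spec["kind"] == "bernoulli":
                if not 0 <= spec["p"] <= 1:
                    raise ConfigurationError(f"invalid probability for {name!r}")
            elif spec["kind"] == "normal":
                if spec["sd"] <= 0:
                    raise ConfigurationError(f"sd for {name!r} must be > 0")
            else:
                raise ConfigurationError(f"unknown kind for {name!r}")
        hz = self.baseline_hazard
        if hz.ndim != 1 or hz.size < 1 or np.any(hz < 0) or np.any(hz > 1):
            raise ConfigurationError("baseline_hazard entries must lie in [0,1]")
        if hz[-1] <= 0:
            raise ConfigurationError(
                "last baseline_hazard entry must be > 0 (tail hazard)")
        if not 0 <= self.censoring_rate <= 1:
            raise ConfigurationError("censoring_rate must lie in [0,1]")


def default_config(**overrides) -> CohortConfig:
    """Convenience constructor for the default RADCURE-like configuration."""
    return CohortConfig(**overrides)


def _draw_covariates(config: CohortConfig, rng: np.random.Generator
                     ) -> pd.DataFrame:
    n = config.n_patients
    cols = {}
    for name, spec in config.covariate_specs.items():
        if spec["kind"] == "normal":
            cols[name] = rng.normal(spec["mean"], spec["sd"], size=n)
        elif spec["kind"] == "bernoulli":
            cols[name] = (rng.random(n) < spec["p"]).astype(int)
        else:
            levels = list(spec["probs"])
            probs = np.array([spec["probs"][l] for l in levels], dtype=float)
            probs = probs / probs.sum()
            cols[name] = rng.choice(levels, size=n, p=probs)
    cols["volume_cc"] = np.exp(
        rng.normal(config.volume_logmean, config.volume_logsd, size=n))
    return pd.DataFrame(cols)


def true_linear_predictor(cohort: pd.DataFrame, config: CohortConfig
                          ) -> np.ndarray:
    """Ground-truth log-hazard linear predictor beta . x for each patient."""
    anchors = config.standardization_anchors
    eta = np.zeros(len(cohort))
    beta = config.true_coefficients
    for var in ("age", "dose_gy"):
        mean, sd = anchors[var]
        eta += beta.get(var, 0.0) * (cohort[var].to_numpy(float) - mean) / sd
    mean, sd = anchors["log_volume"]
    eta += beta.get("log_volume", 0.0) * (
        np.log(cohort["volume_cc"].to_numpy(float)) - mean) / sd
    eta += beta.get("chemotherapy", 0.0) * cohort["chemotherapy"].to_numpy(float)
    for var in CATEGORICAL_VARIABLES:
        values = cohort[var].astype(str)
        coef = values.map(
            lambda lvl, v=var: beta.get(f"{v}={lvl}", 0.0)).to_numpy(float)
        eta += coef
    return eta


def _draw_survival_times(eta: np.ndarray, baseline: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Continuous death times from the per-month discrete hazard model.

    Month k (1-based) has hazard ``min(baseline[k-1] * exp(eta), 1)``; beyond
    the hazard grid the last month's hazard repeats (geometric tail), so
    every patient eventually dies.  The death time is placed uniformly
    within the death month.
    """
    n = eta.size
    hazards = np.clip(baseline[None, :] * np.exp(eta)[:, None], 0.0, 1.0)
    log_surv = np.log1p(-np.minimum(hazards, 1 - 1e-15))
    cum_log_surv = np.cumsum(log_surv, axis=1)  # log S(k), k = 1..K
    log_u = np.log(rng.random(n))
    # death month: first k with log S(k) < log u
    month = 1 + (cum_log_surv >= log_u[:, None]).sum(axis=1)
    beyond = month > baseline.size
    if np.any(beyond):
        tail_log = log_surv[beyond, -1]
        resid = log_u[beyond] - cum_log_surv[beyond, -1]
        extra = np.ceil(resid / tail_log).astype(int)
        month[beyond] = baseline.size + np.maximum(extra, 1)
    return month - rng.random(n)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a cohort as a tidy DataFrame, one row per patient.

    Deterministic for a fixed ``config.seed``: covariates, survival times,
    censoring and the diagnosis ordering each consume an independent stream
    spawned from the master seed.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    rng_cov, rng_surv, rng_cens, rng_date = (
        np.random.default_rng(s) for s in master.spawn(4))

    cov = _draw_covariates(config, rng_cov)
    eta = true_linear_predictor(cov, config)
    death_time = _draw_survival_times(eta, config.baseline_hazard, rng_surv)

    time = death_time.copy()
    event = np.ones(config.n_patients, dtype=int)
    gets_censor = rng_cens.random(config.n_patients) < config.censoring_rate
    censor_time = rng_cens.uniform(24.0, 84.0, size=config.n_patients)
    censored = gets_censor & (death_time > censor_time)
    time[censored] = censor_time[censored]
    event[censored] = 0

    n = config.n_patients
    cohort = pd.DataFrame({
        "patient_id": [f"PT{i:05d}" for i in range(1, n + 1)],
        **{c: cov[c] for c in EMR_VARIABLES if c in cov},
        "volume_cc": cov["volume_cc"],
        "time_months": time,
        "event": event,
        "diagnosis_index": rng_date.permutation(n) + 1,
        "cohort_label": config.cohort_label,
    })
    return cohort[COHORT_COLUMNS]


def apply_shift(config: CohortConfig, shift: Mapping[str, Mapping]
                ) -> CohortConfig:
    """Return a new config with replaced covariate distributions.

    ``shift`` maps variable names to replacement descriptor fields, e.g.
    ``{"hpv_status": {"probs": {"Positive": 0.2, ...}}}`` or
    ``{"age": {"mean": 58.0}}``.  Ground-truth coefficients, baseline hazard
    and standardization anchors are untouched, so the shifted cohort is
    governed by the same outcome model (pure covariate shift).
    """
    specs = {k: {**v, "probs": dict(v["probs"])} if "probs" in v else dict(v)
             for k, v in config.covariate_specs.items()}
    for name, replacement in shift.items():
        if name not in specs:
            raise KeyError(f"unknown covariate {name!r} in shift")
        updated = dict(specs[name])
        for field_name, value in replacement.items():
            updated[field_name] = dict(value) if isinstance(value, Mapping) else value
        specs[name] = updated
    return dataclasses.replace(
        config, covariate_specs=specs,
        standardization_anchors=dict(config.standardization_anchors))


def generate_feature_block(cohort: pd.DataFrame, p: int,
                           volume_coupling: float = 0.5,
                           noise_sd: float = 1.0, seed: int = 0):
    """Synthetic engineered-imaging features with tunable volume dependence.

    Each of the ``p`` features is ``volume_coupling * z + noise_sd * eps``
    where ``z`` is the within-cohort standardized log tumor volume and
    ``eps`` is independent standard normal noise.  This mimics the
    well-documented tendency of engineered radiomic signatures to correlate
    strongly with tumor volume: at ``volume_coupling = 1, noise_sd = 0``
    each feature is a monotone transform of volume (Spearman rho = 1).
    """
    from .preprocessing import FeatureMatrix  # deferred, avoids cycle

    if p < 1:
        raise ValueError("p must be >= 1")
    if not 0 <= volume_coupling <= 1:
        raise ValueError("volume_coupling must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    logv = np.log(cohort["volume_cc"].to_numpy(float))
    z = (logv - logv.mean()) / logv.std()
    values = (volume_coupling * z[:, None]
              + noise_sd * rng.standard_normal((len(cohort), p)))
    names = [f"radiomic_{j:03d}" for j in range(1, p + 1)]
    return FeatureMatrix(values=values, feature_names=names, schema=None)


def split_by_date(cohort: pd.DataFrame, train_fraction: float = 0.706
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Date-ordered split: earliest-diagnosed patients form the train set.

    ``train_fraction = 0.706`` on 2,552 patients reproduces the 1,802/750
    train/test sizes of the RADCURE challenge split.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(cohort)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    ordered = cohort.sort_values("diagnosis_index", kind="mergesort")
    train = ordered.iloc[:n_train].sort_index()
    test = ordered.iloc[n_train:].sort_index()
    return train, test


def binarize_outcome(cohort: pd.DataFrame, horizon_months: float = 24.0
                     ) -> np.ndarray:
    """Binary death-by-horizon labels (1 = died at or before the horizon).

    Requires every censored patient to have follow-up past the horizon —
    the cohort inclusion rule — so no label is ambiguous and no censoring
    correction is needed.  A death at exactly the horizon counts as an
    event (inclusive boundary).
    """
    time = cohort["time_months"].to_numpy(float)
    event = cohort["event"].to_numpy(int)
    bad = (event == 0) & (time < horizon_months)
    if np.any(bad):
        raise ValueError(
            f"{bad.sum()} censored patients have follow-up shorter than the "
            f"{horizon_months}-month horizon; their labels are ambiguous")
    return ((event == 1) & (time <= horizon_months)).astype(int)


# ---------------------------------------------------------------------------
# serialization

def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file lacks columns: {sorted(missing)}")
    return df[COHORT_COLUMNS]


def config_to_yaml(config: CohortConfig, path) -> None:
    payload = dataclasses.asdict(config)
    payload["baseline_hazard"] = [float(h) for h in config.baseline_hazard]
    payload["standardization_anchors"] = {
        k: [float(a), float(b)]
        for k, (a, b) in config.standardization_anchors.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def config_from_yaml(path) -> CohortConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if "baseline_hazard" in payload:
        payload["baseline_hazard"] = np.asarray(payload["baseline_hazard"])
    if "standardization_anchors" in payload:
        payload["standardization_anchors"] = {
            k: tuple(v) for k, v in payload["standardization_anchors"].items()}
    return CohortConfig(**payload)
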