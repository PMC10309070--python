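"""End-to-end simulated prognostic-modeling challenge.

Orchestrates the full benchmarking workflow: simulate a cohort with known
ground truth, split it by diagnosis date, fit the encoding schema on the
training portion only, train a roster of survival and binary models,
blind-evaluate them on the held-out test split, rank by AUROC with AP as
the tie-break, test each model against the best at 5% FDR, analyze volume
dependence and risk stratification, and validate the frozen models on
distribution-shifted external cohorts.

Blind-evaluation discipline is enforced structurally: test-set outcomes
live behind :class:`HeldOutOutcomes`, which refuses to reveal them until
every model's predictions have been frozen.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import baselines, evaluation
from .cohort import (CATEGORICAL_VARIABLES, EMR_VARIABLES, CohortConfig,
                     apply_shift, binarize_outcome, default_config,
                     generate_cohort, generate_feature_block, split_by_date)
from .mtlr import MTLR, MTLRResults
from .preprocessing import EncodingSchema, encode, fit_schema

logger = logging.getLogger("hncprog")

__all__ = ["ChallengeConfig", "ChallengeResult", "HeldOutOutcomes",
           "run_challenge", "run_external_validation", "report",
           "render_report", "load_report", "DEFAULT_ROSTER",
           "default_shift_presets", "BlindEvaluationError",
           "save_models", "load_models"]

DEFAULT_ROSTER = ("deep_mtlr", "linear_mtlr", "logistic_emr", "cox_emr",
                  "volume_only", "clinical_baseline", "mrmr_feature_model")

CLINICAL_VARIABLES = ("age", "sex", "t_stage", "n_stage", "hpv_status")


def default_shift_presets() -> dict:
    """Three qualitative external-cohort presets: a site-mix shift, an
    outcome-prevalence shift via stage mix, and an HPV-mix shift with a
    disproportionately HPV-negative population.  Magnitudes are
    illustrative, not estimates of any real cohort."""
    return {
        "site_shift": {
            "disease_site": {"probs": {
                "Oropharynx": 0.55, "Larynx": 0.40, "Nasopharynx": 0.01,
                "Hypopharynx": 0.02, "Oral cavity": 0.01, "Other": 0.01}},
        },
        "prevalence_shift": {
            "overall_stage": {"probs": {
                "I": 0.03, "II": 0.07, "III": 0.25, "IV": 0.65}},
            "t_stage": {"probs": {
                "T1": 0.08, "T2": 0.25, "T3": 0.35, "T4": 0.32}},
        },
        "hpv_negative_shift": {
            "hpv_status": {"probs": {
                "Positive": 0.15, "Negative": 0.55, "Not tested": 0.30}},
            "disease_site": {"probs": {
                "Oropharynx": 0.35, "Larynx": 0.30, "Nasopharynx": 0.05,
                "Hypopharynx": 0.10, "Oral cavity": 0.12, "Other": 0.08}},
        },
    }


@dataclass
class ChallengeConfig:
    cohort: CohortConfig = field(default_factory=default_config)
    train_fraction: float = 0.706
    model_roster: tuple = DEFAULT_ROSTER
    shift_configs: dict = field(default_factory=default_shift_presets)
    horizon_months: float = 24.0
    n_boot: int = 1000
    n_perm: int = 1000
    ci_level: float = 0.95
    n_synthetic_features: int = 30
    volume_coupling: float = 0.6
    feature_noise_sd: float = 1.0
    mrmr_m: int = 10
    deep_hidden_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if len(self.model_roster) == 0:
            raise ValueError("model roster must be nonempty")
        if self.horizon_months > self.cohort.baseline_hazard.size:
            raise ValueError("horizon extends beyond the hazard grid")

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload["cohort"]["baseline_hazard"] = [
            float(h) for h in self.cohort.baseline_hazard]
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class BlindEvaluationError(RuntimeError):
    """Raised when test outcomes are requested before predictions freeze."""


class HeldOutOutcomes:
    """Guard around test-set outcomes enforcing challenge-style blinding.

    Outcome columns are only revealed after :meth:`freeze_predictions` has
    registered the final prediction set for every expected model.
    """

    def __init__(self, test_cohort: pd.DataFrame, expected_models):
        self._outcomes = test_cohort[["time_months", "event"]].copy()
        self._expected = set(expected_models)
        self._frozen = None

    def freeze_predictions(self, predictions: dict) -> None:
        missing = self._expected - set(predictions)
        if missing:
            raise BlindEvaluationError(
                f"cannot freeze: missing predictions for {sorted(missing)}")
        self._frozen = {k: {kk: np.asarray(vv) for kk, vv in v.items()}
                        for k, v in predictions.items()}

    @property
    def frozen_predictions(self) -> dict:
        if self._frozen is None:
            raise BlindEvaluationError("predictions have not been frozen")
        return self._frozen

    def reveal(self) -> tuple[np.ndarray, np.ndarray]:
        if self._frozen is None:
            raise BlindEvaluationError(
                "test outcomes are sealed until predictions are frozen")
        return (self._outcomes["time_months"].to_numpy(float),
                self._outcomes["event"].to_numpy(int))


# ---------------------------------------------------------------------------
# model roster

def _platt_calibrate(train_risk, y_train):
    """Map an uncalibrated risk score to [0, 1] via 1-d logistic fit."""
    x = np.asarray(train_risk, dtype=float)[:, None]
    return baselines.fit_logistic(x, y_train, l2_strength=1e-4,
                                  feature_names=["risk"])


class _FittedModel:
    """Uniform wrapper around a serialized model: predict -> probabilities
    and risk scores from the appropriate design matrix."""

    def __init__(self, name, serial):
        self.name = name
        self.kind = serial["kind"]
        self.columns = serial["columns"]
        self.serial = serial  # JSON-serializable parameters
        self._predict_fn = _predictor_from_serial(serial)

    def predict(self, matrices: dict) -> dict:
        event_prob, risk = self._predict_fn(matrices)
        return {"event_prob": np.asarray(event_prob, dtype=float),
                "risk_score": np.asarray(risk, dtype=float)}


def _predictor_from_serial(serial: dict):
    """Build the prediction closure from serialized parameters, so that a
    model reloaded from JSON predicts identically to the freshly fitted
    one (the external-validation hand-off contract)."""
    kind, cols = serial["kind"], list(serial["columns"])
    if kind == "mtlr":
        res = MTLRResults.from_dict(serial["mtlr"])

        def predict(mats):
            ps = res.predict(mats["emr_volume"][:, cols])
            return ps.event_prob, ps.risk_score
    elif kind in ("logistic", "logistic_features"):
        lm = baselines.LinearModel.from_dict(serial["model"])
        key = "features" if kind == "logistic_features" else "emr_volume"

        def predict(mats):
            p = lm.predict_prob(mats[key][:, cols])
            return p, p
    elif kind == "cox":
        lm = baselines.LinearModel.from_dict(serial["model"])
        calib = baselines.LinearModel.from_dict(serial["calibration"])

        def predict(mats):
            risk = lm.risk_score(mats["emr_volume"][:, cols])
            return calib.predict_prob(risk[:, None]), risk
    else:
        raise ValueError(f"unknown serialized model kind {kind!r}")
    return predict


def _column_indices(schema_names, variables, include_volume):
    idx = []
    for j, name in enumerate(schema_names):
        var = name.split("=")[0]
        if var == "volume_cc":
            if include_volume:
                idx.append(j)
        elif var in variables:
            idx.append(j)
    return idx


def _build_model(name, config, train, X_train, feat_train, y_train, seeds):
    """Fit one roster model on training data only."""
    names = X_train.feature_names
    t = train["time_months"].to_numpy(float)
    e = train["event"].to_numpy(int)

    def mtlr_model(hidden):
        cols = _column_indices(names, EMR_VARIABLES, include_volume=True)
        model = MTLR(X_train.values[:, cols], t, e, hidden_size=hidden,
                     feature_names=[names[j] for j in cols])
        res = model.fit(seed=int(seeds[name]))
        return _FittedModel(name, {"kind": "mtlr", "columns": cols,
                                   "mtlr": res.to_dict()})

    def logistic_model(variables, include_volume, model_name):
        cols = _column_indices(names, variables, include_volume)
        lm = baselines.fit_logistic(X_train.values[:, cols], y_train,
                                    l2_strength=1.0,
                                    feature_names=[names[j] for j in cols])
        return _FittedModel(model_name, {"kind": "logistic", "columns": cols,
                                         "model": lm.to_dict()})

    if name == "deep_mtlr":
        return mtlr_model(config.deep_hidden_size)
    if name == "linear_mtlr":
        return mtlr_model(None)
    if name == "logistic_emr":
        return logistic_model(EMR_VARIABLES, False, name)
    if name == "volume_only":
        return logistic_model((), True, name)
    if name == "clinical_baseline":
        return logistic_model(CLINICAL_VARIABLES, False, name)
    if name == "cox_emr":
        cols = _column_indices(names, EMR_VARIABLES, include_volume=False)
        lm = baselines.fit_cox(X_train.values[:, cols], t, e,
                               l2_strength=0.1,
                               feature_names=[names[j] for j in cols])
        calib = _platt_calibrate(lm.risk_score(X_train.values[:, cols]),
                                 y_train)
        return _FittedModel(name, {"kind": "cox", "columns": cols,
                                   "model": lm.to_dict(),
                                   "calibration": calib.to_dict()})
    if name == "mrmr_feature_model":
        m = min(config.mrmr_m, feat_train.n_features)
        sel = baselines.mrmr_select(feat_train.values, y_train, m)
        cols = sel.selected_indices
        lm = baselines.fit_logistic(feat_train.values[:, cols], y_train,
                                    l2_strength=1.0,
                                    feature_names=[feat_train.feature_names[j]
                                                   for j in cols])
        return _FittedModel(name, {"kind": "logistic_features",
                                   "columns": cols, "model": lm.to_dict()})
    raise ValueError(f"unknown roster model {name!r}")


def save_models(models: dict, outdir) -> None:
    """Serialize every fitted roster model to ``<outdir>/<name>.json``."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, model in models.items():
        with open(outdir / f"{name}.json", "w") as fh:
            json.dump(model.serial, fh)


def load_models(model_dir) -> dict:
    """Reload serialized models; predictions match the original fits."""
    from pathlib import Path
    models = {}
    for path in sorted(Path(model_dir).glob("*.json")):
        with open(path) as fh:
            models[path.stem] = _FittedModel(path.stem, json.load(fh))
    return models


# ---------------------------------------------------------------------------
# challenge run

@dataclass
class ChallengeResult:
    config: ChallengeConfig
    cohort: pd.DataFrame
    train: pd.DataFrame
    test: pd.DataFrame
    schema: EncodingSchema
    models: dict
    predictions: dict
    metrics: pd.DataFrame
    ranking: pd.DataFrame
    volume_dependence: pd.DataFrame
    stratification: evaluation.StratificationResult | None
    failures: dict
    seeds: dict


def _evaluate_predictions(predictions, y_test, t_test, e_test, volume_test,
                          config, eval_seed):
    """Point estimates, stratified-bootstrap CIs and permutation p-values
    for every model on the frozen test predictions."""
    rows = []
    for i, (name, pred) in enumerate(sorted(predictions.items())):
        seed = int(eval_seed + i)
        res_auroc = evaluation.stratified_bootstrap_ci(
            evaluation.auroc, pred["event_prob"], y_test,
            n_boot=config.n_boot, level=config.ci_level, seed=seed,
            name="auroc")
        res_ap = evaluation.stratified_bootstrap_ci(
            evaluation.average_precision, pred["event_prob"], y_test,
            n_boot=config.n_boot, level=config.ci_level, seed=seed,
            name="ap")
        res_c = evaluation.stratified_bootstrap_ci(
            evaluation.c_index, pred["risk_score"], t_test, e_test,
            strata=e_test, n_boot=config.n_boot, level=config.ci_level,
            seed=seed, name="c_index")
        p_perm = evaluation.permutation_test(
            evaluation.auroc, pred["event_prob"], y_test,
            n_perm=config.n_perm, seed=seed)
        rows.append({
            "model": name,
            "auroc": res_auroc.estimate, "auroc_lo": res_auroc.ci_low,
            "auroc_hi": res_auroc.ci_high,
            "ap": res_ap.estimate, "ap_lo": res_ap.ci_low,
            "ap_hi": res_ap.ci_high,
            "c_index": res_c.estimate, "c_index_lo": res_c.ci_low,
            "c_index_hi": res_c.ci_high,
            "p_vs_random": p_perm,
        })
    return pd.DataFrame(rows)


def _rank_models(metrics: pd.DataFrame, predictions, y_test, config,
                 eval_seed) -> pd.DataFrame:
    """Rank by AUROC (AP breaks ties) and test every model against the
    best with a one-sided paired bootstrap t test at BH-FDR 5%."""
    ranking = metrics.sort_values(["auroc", "ap"],
                                  ascending=False, kind="mergesort")
    ranking = ranking.reset_index(drop=True)
    ranking.insert(0, "rank", np.arange(1, len(ranking) + 1))
    best = ranking.iloc[0]["model"]
    p_values, others = [], []
    for name in ranking["model"]:
        if name == best:
            continue
        others.append(name)
        p_values.append(evaluation.compare_models(
            predictions[best]["event_prob"], predictions[name]["event_prob"],
            y_test, n_boot=config.n_boot, seed=int(eval_seed)))
    if others:
        reject, p_adj = evaluation.fdr_adjust(p_values)
        flags = dict(zip(others, zip(p_values, p_adj, reject)))
    else:
        flags = {}
    ranking["p_vs_best"] = [
        np.nan if m == best else flags[m][0] for m in ranking["model"]]
    ranking["p_vs_best_adj"] = [
        np.nan if m == best else flags[m][1] for m in ranking["model"]]
    ranking["worse_than_best_fdr5"] = [
        False if m == best else bool(flags[m][2]) for m in ranking["model"]]
    return ranking


def run_challenge(config: ChallengeConfig | None = None) -> ChallengeResult:
    """Simulate, split, train the roster, blind-evaluate and rank."""
    config = config or ChallengeConfig()
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(4)
    seeds = {
        "cohort": int(children[0].generate_state(1)[0] % 2**31),
        "features": int(children[1].generate_state(1)[0] % 2**31),
        "evaluation": int(children[2].generate_state(1)[0] % 2**31),
    }
    model_seed_root = children[3].generate_state(len(config.model_roster))
    seeds.update({name: int(s % 2**31) for name, s in
                  zip(config.model_roster, model_seed_root)})

    cohort_config = dataclasses.replace(
        config.cohort, seed=seeds["cohort"],
        standardization_anchors=dict(config.cohort.standardization_anchors))
    cohort = generate_cohort(cohort_config)
    features = generate_feature_block(
        cohort, config.n_synthetic_features, config.volume_coupling,
        config.feature_noise_sd, seed=seeds["features"])
    train, test = split_by_date(cohort, config.train_fraction)
    train_mask = cohort.index.isin(train.index)

    schema = fit_schema(train, list(EMR_VARIABLES) + ["volume_cc"])
    X_train, X_test = encode(train, schema), encode(test, schema)
    from .preprocessing import FeatureMatrix
    feat_train = FeatureMatrix(features.values[train_mask],
                               features.feature_names)
    feat_test = FeatureMatrix(features.values[~train_mask],
                              features.feature_names)
    y_train = binarize_outcome(train, config.horizon_months)

    models, predictions, failures = {}, {}, {}
    test_matrices = {"emr_volume": X_test.values, "features": feat_test.values}
    for name in config.model_roster:
        try:
            fitted = _build_model(name, config, train, X_train, feat_train,
                                  y_train, seeds)
            models[name] = fitted
            predictions[name] = fitted.predict(test_matrices)
        except Exception as exc:  # challenge framing: rank what completes
            logger.warning("model %s failed: %s", name, exc)
            failures[name] = repr(exc)
    if not predictions:
        raise RuntimeError("every roster model failed")
    holdout = HeldOutOutcomes(test, predictions.keys())
    holdout.freeze_predictions(predictions)
    t_test, e_test = holdout.reveal()
    y_test = binarize_outcome(test, config.horizon_months)

    metrics = _evaluate_predictions(predictions, y_test, t_test, e_test,
                                    test["volume_cc"].to_numpy(float),
                                    config, seeds["evaluation"])
    ranking = _rank_models(metrics, predictions, y_test, config,
                           seeds["evaluation"])

    vol_dep = evaluation.volume_dependence(
        {m: p["event_prob"] for m, p in predictions.items()},
        test["volume_cc"].to_numpy(float))
    vol_dep = vol_dep.merge(metrics[["model", "auroc", "c_index"]],
                            on="model")

    best = ranking.iloc[0]["model"]
    try:
        strat = evaluation.km_stratify(predictions[best]["event_prob"],
                                       t_test, e_test)
    except ValueError as exc:
        logger.warning("stratification unavailable: %s", exc)
        strat = None

    return ChallengeResult(
        config=config, cohort=cohort, train=train, test=test, schema=schema,
        models=models, predictions=predictions, metrics=metrics,
        ranking=ranking, volume_dependence=vol_dep, stratification=strat,
        failures=failures, seeds=seeds)


# ---------------------------------------------------------------------------
# external validation

def run_external_validation(result: ChallengeResult, shift_names=None,
                            n_external: int = 750) -> dict:
    """Evaluate the frozen models on distribution-shifted cohorts.

    Each named shift replaces covariate distributions (ground-truth
    coefficients unchanged), a fresh cohort is generated, the *frozen*
    train-set schema and models are applied unchanged, and the covariate
    distributions are compared to the internal test set with pairwise
    chi-squared tests at 5% FDR.
    """
    config = result.config
    names = list(shift_names) if shift_names is not None \
        else list(config.shift_configs)
    out = {}
    for i, shift_name in enumerate(names):
        shift = config.shift_configs[shift_name]
        base = dataclasses.replace(
            result.config.cohort,
            standardization_anchors=dict(
                result.config.cohort.standardization_anchors))
        ext_config = apply_shift(base, shift)
        ext_config = dataclasses.replace(
            ext_config, n_patients=n_external,
            seed=int((result.seeds["cohort"] + 1000 + i) % 2**31),
            cohort_label=shift_name,
            standardization_anchors=dict(ext_config.standardization_anchors))
        ext = generate_cohort(ext_config)
        X_ext = encode(ext, result.schema)
        feat_ext = generate_feature_block(
            ext, config.n_synthetic_features, config.volume_coupling,
            config.feature_noise_sd,
            seed=int((result.seeds["features"] + 1000 + i) % 2**31))
        matrices = {"emr_volume": X_ext.values, "features": feat_ext.values}
        predictions = {name: model.predict(matrices)
                       for name, model in result.models.items()}
        y_ext = binarize_outcome(ext, config.horizon_months)
        metrics = _evaluate_predictions(
            predictions, y_ext, ext["time_months"].to_numpy(float),
            ext["event"].to_numpy(int), ext["volume_cc"].to_numpy(float),
            config, result.seeds["evaluation"] + 500 + i)
        ranking = _rank_models(metrics, predictions, y_ext, config,
                               result.seeds["evaluation"] + 500 + i)
        shift_table = evaluation.cohort_shift_test(
            result.test, ext,
            list(CATEGORICAL_VARIABLES) + ["age", "volume_cc"])
        out[shift_name] = {"cohort": ext, "metrics": metrics,
                           "ranking": ranking, "shift_table": shift_table,
                           "prevalence": float(y_ext.mean())}
    return out


# ---------------------------------------------------------------------------
# reporting

def _result_payload(result: ChallengeResult, external: dict | None) -> dict:
    payload = {
        "config_digest": result.config.digest(),
        "seed": result.config.seed,
        "seeds": result.seeds,
        "n_train": len(result.train),
        "n_test": len(result.test),
        "test_prevalence": float(
            binarize_outcome(result.test,
                             result.config.horizon_months).mean()),
        "ranking": result.ranking.to_dict(orient="records"),
        "volume_dependence": result.volume_dependence.to_dict(
            orient="records"),
        "failures": result.failures,
    }
    if result.stratification is not None:
        s = result.stratification
        payload["stratification"] = {
            "threshold": s.threshold,
            "hazard_ratio": s.hazard_ratio,
            "hr_ci": list(s.hr_ci),
            "logrank_p": s.logrank_p,
            "n_high_risk": int(s.group_assignment.sum()),
            "n_low_risk": int((1 - s.group_assignment).sum()),
        }
    if external:
        payload["external"] = {
            name: {"ranking": ext["ranking"].to_dict(orient="records"),
                   "shift_table": ext["shift_table"].to_dict(
                       orient="records"),
                   "prevalence": ext["prevalence"]}
            for name, ext in external.items()}
    return payload


def render_report(payload: dict) -> str:
    """Human-readable summary from the machine-readable report payload."""
    lines = [
        "Simulated prognostic-modeling challenge report",
        "=" * 60,
        f"config digest: {payload['config_digest']}   "
        f"master seed: {payload['seed']}",
        f"train / test: {payload['n_train']} / {payload['n_test']}   "
        f"test 2-year event prevalence: {payload['test_prevalence']:.3f}",
        "",
        "Ranking (AUROC primary, AP tie-break)",
        "-" * 60,
    ]
    for row in payload["ranking"]:
        flag = " *worse than best (FDR<5%)" if row["worse_than_best_fdr5"] \
            else ""
        lines.append(
            f"{row['rank']:>2}. {row['model']:<20} "
            f"AUROC {row['auroc']:.3f} [{row['auroc_lo']:.3f}-"
            f"{row['auroc_hi']:.3f}]  AP {row['ap']:.3f}  "
            f"C {row['c_index']:.3f}{flag}")
    lines += ["", "Volume dependence (Spearman rho of predictions vs volume)",
              "-" * 60]
    for row in payload["volume_dependence"]:
        lines.append(f"{row['model']:<20} rho = {row['spearman_rho']:+.3f}  "
                     f"(AUROC {row['auroc']:.3f})")
    if "stratification" in payload:
        s = payload["stratification"]
        lines += ["", "Risk stratification of best model "
                  f"(threshold {s['threshold']:.2f})",
                  "-" * 60,
                  f"high/low risk: {s['n_high_risk']}/{s['n_low_risk']}  "
                  f"HR = {s['hazard_ratio']:.2f} "
                  f"[{s['hr_ci'][0]:.2f}-{s['hr_ci'][1]:.2f}]  "
                  f"log-rank p = {s['logrank_p']:.2e}"]
    for name, ext in payload.get("external", {}).items():
        lines += ["", f"External validation: {name} "
                  f"(prevalence {ext['prevalence']:.3f})", "-" * 60]
        for row in ext["ranking"]:
            lines.append(f"{row['rank']:>2}. {row['model']:<20} "
                         f"AUROC {row['auroc']:.3f}  AP {row['ap']:.3f}")
        shifted = [r["variable"] for r in ext["shift_table"] if r["shifted"]]
        lines.append("shifted variables (chi2, FDR<5%): "
                     + (", ".join(shifted) if shifted else "none"))
    if payload.get("failures"):
        lines += ["", "Model failures: "
                  + "; ".join(f"{k}: {v}"
                              for k, v in payload["failures"].items())]
    return "\n".join(lines) + "\n"


def report(result: ChallengeResult, outdir, external: dict | None = None
           ) -> dict:
    """Write machine-readable (CSV/JSON) and human-readable outputs."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = _result_payload(result, external)
    result.ranking.to_csv(outdir / "ranking.csv", index=False)
    result.metrics.to_csv(outdir / "metrics.csv", index=False)
    result.volume_dependence.to_csv(outdir / "volume_dependence.csv",
                                    index=False)
    if external:
        for name, ext in external.items():
            ext["ranking"].to_csv(outdir / f"external_{name}_ranking.csv",
                                  index=False)
            ext["shift_table"].to_csv(outdir / f"external_{name}_shift.csv",
                                      index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(render_report(payload))
    return payload


def load_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
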