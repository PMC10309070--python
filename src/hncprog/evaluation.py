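"""Metrics, uncertainty and significance framework for model benchmarking.

The binary 2-year endpoint is scored with AUROC (primary ranking metric)
and average precision (AP, the precision-recall step sum
``sum_n (R_n - R_{n-1}) P_n``; used to break ranking ties because of its
sensitivity to class imbalance).  Lifetime-risk predictions are scored
with Harrell's concordance index over comparable censored pairs.  No
censoring correction is applied to the binary metrics: the cohort
inclusion rule guarantees at least two years of follow-up for censored
patients, so 2-year labels are unambiguous.

Uncertainty is quantified with stratified bootstrap percentile intervals
(resampling within outcome strata); significance against random guessing
with permutation tests (add-one smoothed p-values); model-vs-model
comparisons with a paired one-sided t test on shared bootstrap
replicates; and multiplicity with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MetricResult", "StratificationResult", "auroc", "average_precision",
    "c_index", "stratified_bootstrap_ci", "permutation_test",
    "compare_models", "fdr_adjust", "km_stratify", "volume_dependence",
    "cohort_shift_test", "metric_agreement",
]


@dataclass
class MetricResult:
    name: str
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    p_value: float | None = None

    def __post_init__(self):
        if self.ci_low is not None and not (
                self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12):
            raise ValueError("estimate must lie inside its CI")

    def __str__(self):
        out = f"{self.name} = {self.estimate:.3f}"
        if self.ci_low is not None:
            out += f" [{self.ci_low:.3f}-{self.ci_high:.3f}]"
        return out


# ---------------------------------------------------------------------------
# point metrics

def auroc(scores, labels) -> float:
    """Area under the ROC curve = P(score_pos > score_neg) + 0.5 P(tie).

    Computed as the normalized Mann-Whitney rank sum (midranks handle
    score ties), which is cheap enough to sit inside bootstrap and
    permutation loops.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: single-class labels")
    ranks = stats.rankdata(scores)
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def average_precision(scores, labels) -> float:
    """AP = sum_n (R_n - R_{n-1}) P_n over decreasing score thresholds,
    tied scores grouped at a single threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AP undefined: no positive labels")
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, len(y) + 1)
    recall = tp / n_pos
    last_of_threshold = np.r_[s[1:] != s[:-1], True]  # tie groups collapse
    p = precision[last_of_threshold]
    r = recall[last_of_threshold]
    return float(np.sum(np.diff(np.r_[0.0, r]) * p))


def c_index(risk_scores, time_months, event) -> float:
    """Harrell's concordance index over comparable pairs.

    A pair (i, j) with t_i < t_j and event_i = 1 is comparable; credit 1
    if r_i > r_j, 1/2 on risk ties; pairs with equal times where the
    ordering is ambiguous are excluded.
    """
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("C-index undefined: no comparable pairs")
    try:
        return float(concordance_index(
            np.asarray(time_months, dtype=float),
            -np.asarray(risk_scores, dtype=float), event))
    except ZeroDivisionError as exc:
        raise ValueError("C-index undefined: no comparable pairs") from exc


# ---------------------------------------------------------------------------
# resampling inference

def _stratum_indices(strata: np.ndarray) -> list[np.ndarray]:
    groups = [np.where(strata == g)[0] for g in np.unique(strata)]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty stratum")
    return groups


def _stratified_resample(groups, rng) -> np.ndarray:
    return np.concatenate([g[rng.integers(0, len(g), len(g))]
                           for g in groups])


def stratified_bootstrap_ci(metric_fn, scores, *outcome_arrays,
                            strata=None, n_boot: int = 10000,
                            level: float = 0.95, seed: int = 0,
                            name: str = "metric") -> MetricResult:
    """Percentile bootstrap CI resampling within outcome strata.

    ``metric_fn(scores, *outcome_arrays)`` is recomputed on each
    replicate; ``strata`` defaults to the last outcome array (binary
    labels, or the event indicator for the C-index), preserving class /
    event balance in every replicate.
    """
    scores = np.asarray(scores, dtype=float)
    arrays = [np.asarray(a) for a in outcome_arrays]
    strata = np.asarray(arrays[-1] if strata is None else strata)
    estimate = metric_fn(scores, *arrays)
    groups = _stratum_indices(strata)
    rng = np.random.default_rng(seed)
    replicates = np.empty(n_boot)
    for b in range(n_boot):
        idx = _stratified_resample(groups, rng)
        replicates[b] = metric_fn(scores[idx], *(a[idx] for a in arrays))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(replicates, [alpha, 1.0 - alpha])
    return MetricResult(name=name, estimate=float(estimate),
                        ci_low=float(min(lo, estimate)),
                        ci_high=float(max(hi, estimate)), n_boot=n_boot)


def permutation_test(metric_fn, scores, *outcome_arrays, n_perm: int = 1000,
                     alternative: str = "greater", seed: int = 0) -> float:
    """Permutation p-value for association between scores and outcome.

    Outcomes are jointly permuted against the scores; the add-one-smoothed
    p-value (1 + #extreme) / (n_perm + 1) can never be exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scores = np.asarray(scores, dtype=float)
    arrays = [np.asarray(a) for a in outcome_arrays]
    observed = metric_fn(scores, *arrays)
    rng = np.random.default_rng(seed)
    n = len(scores)
    extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        value = metric_fn(scores, *(a[perm] for a in arrays))
        if alternative == "greater":
            extreme += value >= observed
        elif alternative == "less":
            extreme += value <= observed
        else:
            raise ValueError("alternative must be 'greater' or 'less'")
    return (1 + extreme) / (n_perm + 1)


def compare_models(scores_best, scores_other, labels, n_boot: int = 1000,
                   seed: int = 0) -> float:
    """One-sided paired test that the best model's AUROC exceeds another's.

    Both models are evaluated on the same stratified bootstrap replicates;
    the test statistic is the mean per-replicate AUROC difference divided
    by the replicate standard deviation (the bootstrap estimate of the
    difference's standard error), referred to a t distribution with
    n_boot - 1 degrees of freedom (H1: mean difference > 0).  Identical
    score vectors give p = 1 by convention (no evidence of superiority).
    """
    scores_best = np.asarray(scores_best, dtype=float)
    scores_other = np.asarray(scores_other, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_best.shape != scores_other.shape or len(labels) != len(
            scores_best):
        raise ValueError("score vectors must cover the same patients")
    groups = _stratum_indices(labels)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = _stratified_resample(groups, rng)
        diffs[b] = (auroc(scores_best[idx], labels[idx])
                    - auroc(scores_other[idx], labels[idx]))
    if np.allclose(diffs, 0.0):
        return 1.0
    t_stat = diffs.mean() / diffs.std(ddof=1)
    return float(stats.t.sf(t_stat, df=n_boot - 1))


def fdr_adjust(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# survival-specific analyses

@dataclass
class StratificationResult:
    group_assignment: np.ndarray  # 1 = high risk
    km_curves: dict  # group -> DataFrame(time, survival)
    hazard_ratio: float
    hr_ci: tuple
    logrank_p: float
    threshold: float = 0.5

    def __post_init__(self):
        counts = np.bincount(self.group_assignment.astype(int), minlength=2)
        if counts.min() == 0:
            raise ValueError("both risk groups must be nonempty")


def km_stratify(event_prob, time_months, event, threshold: float = 0.5
                ) -> StratificationResult:
    """Two-group risk stratification at a predicted-probability threshold.

    Patients with 2-year event probability >= threshold form the high-risk
    group; Kaplan-Meier curves are estimated per group, the hazard ratio
    comes from a univariate Cox model on the group indicator, and the
    log-rank test compares the two survival distributions.
    """
    event_prob = np.asarray(event_prob, dtype=float)
    time_months = np.asarray(time_months, dtype=float)
    event = np.asarray(event, dtype=int)
    high = (event_prob >= threshold).astype(int)
    if high.min() == high.max():
        raise ValueError("threshold produces an empty risk group")
    curves = {}
    for g, label in ((0, "low_risk"), (1, "high_risk")):
        kmf = KaplanMeierFitter()
        kmf.fit(time_months[high == g], event[high == g])
        curves[label] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy()})
    df = pd.DataFrame({"high": high, "_time": time_months, "_event": event})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    hr = float(np.exp(cph.params_["high"]))
    ci = cph.confidence_intervals_
    hr_ci = (float(np.exp(ci.iloc[0, 0])), float(np.exp(ci.iloc[0, 1])))
    lr = logrank_test(time_months[high == 1], time_months[high == 0],
                      event[high == 1], event[high == 0])
    return StratificationResult(group_assignment=high, km_curves=curves,
                                hazard_ratio=hr, hr_ci=hr_ci,
                                logrank_p=float(lr.p_value),
                                threshold=threshold)


def volume_dependence(predictions_by_model: dict, volume_cc) -> pd.DataFrame:
    """Spearman rank correlation of each model's 2-year event probabilities
    with tumor volume (the volume-dependence axis of the rho-vs-AUROC
    analysis)."""
    volume = np.asarray(volume_cc, dtype=float)
    if len(volume) < 3:
        raise ValueError("need at least 3 patients")
    rows = []
    for model, preds in predictions_by_model.items():
        preds = np.asarray(preds, dtype=float)
        if np.ptp(preds) == 0:
            raise ValueError(f"constant predictions for {model!r}: "
                             "Spearman correlation undefined")
        rho = stats.spearmanr(preds, volume).statistic
        rows.append({"model": model, "spearman_rho": float(rho)})
    return pd.DataFrame(rows)


def _bin_continuous(a: np.ndarray, b: np.ndarray, n_bins: int = 4):
    pooled = np.concatenate([a, b])
    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.digitize(a, edges), np.digitize(b, edges)


def cohort_shift_test(cohort_a: pd.DataFrame, cohort_b: pd.DataFrame,
                      variables, q: float = 0.05) -> pd.DataFrame:
    """Pairwise chi-squared tests of covariate-distribution equality.

    One contingency-table chi-squared statistic per variable (no
    continuity correction, matching the plain sum (O-E)^2 / E), with
    Benjamini-Hochberg FDR control across variables.  Continuous
    variables are quartile-binned on the pooled sample; expected counts
    below 5 trigger a warning rather than an exact test.
    """
    rows = []
    for var in variables:
        a, b = cohort_a[var], cohort_b[var]
        if a.dtype == object or isinstance(a.dtype, pd.CategoricalDtype):
            a_codes, b_codes = a.astype(str), b.astype(str)
        else:
            a_codes, b_codes = _bin_continuous(a.to_numpy(float),
                                               b.to_numpy(float))
        table = pd.crosstab(
            np.concatenate([np.asarray(a_codes, dtype=object),
                            np.asarray(b_codes, dtype=object)]),
            np.repeat(["a", "b"], [len(a), len(b)]))
        chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(),
                                                        correction=False)
        if expected.min() < 5:
            warnings.warn(f"variable {var!r}: expected cell count below 5; "
                          "chi-squared approximation may be poor")
        rows.append({"variable": var, "chi2": float(chi2), "dof": int(dof),
                     "p_value": float(p)})
    out = pd.DataFrame(rows)
    reject, p_adj = fdr_adjust(out["p_value"].to_numpy(), q=q)
    out["p_adjusted"] = p_adj
    out["shifted"] = reject
    return out


def metric_agreement(metric_table: pd.DataFrame,
                     pairs=(("auroc", "ap"), ("auroc", "c_index"))
                     ) -> dict[tuple, float]:
    """Pearson correlation between metric columns across models."""
    if len(metric_table) < 3:
        raise ValueError("need at least 3 models")
    out = {}
    for a, b in pairs:
        cols = metric_table[[a, b]].dropna()
        if cols[a].std() == 0 or cols[b].std() == 0:
            raise ValueError(f"constant metric column in pair ({a}, {b})")
        out[(a, b)] = float(stats.pearsonr(cols[a], cols[b]).statistic)
    return out
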