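"""Multitask logistic regression (MTLR) for discrete-time survival.

MTLR discretizes the time axis into K intervals (by default 24 monthly
intervals covering the first two years) and fits a sequence of dependent
logistic scores, one per interval, jointly over all intervals.  A patient's
outcome is represented as a monotone binary sequence (alive ... alive,
dead ... dead); the unnormalized log-score of the sequence that dies in
interval k is

    s_k = sum_{j=k}^{K} (w_j . z + b_j),        s_{K+1} = 0 (survives all),

and sequence probabilities are softmax over the K+1 admissible sequences.
Uncensored patients contribute the log-probability of their death interval;
a patient censored inside interval k contributes the log of the summed
probability of all sequences with death strictly after interval k.  Because
no parametric form is imposed on the survival function, the model can
express time-varying, non-proportional covariate effects while still
producing a full survival curve per patient.

The representation ``z`` is either the raw feature vector (linear MTLR — a
concave maximum-likelihood problem solved with full-batch L-BFGS) or a
single hidden layer with exponential-linear-unit activation, ``z =
ELU(W_h x + c_h)`` (deep MTLR — trained with seeded minibatch Adam and
early stopping on a held-out split).  Two smoothness/shrinkage penalties
regularize the per-interval weights:

    (lambda_smooth / 2) * sum_k ||w_{k+1} - w_k||^2
  + (lambda_ridge  / 2) * sum_k ||w_k||^2            (+ encoder ridge).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["TimeGrid", "MTLR", "MTLRResults", "PredictionSet",
           "monthly_grid", "elu"]


def elu(a: np.ndarray) -> np.ndarray:
    """Exponential linear unit: a for a > 0, exp(a) - 1 otherwise."""
    return np.where(a > 0, a, np.expm1(np.minimum(a, 0.0)))


def _elu_grad(a: np.ndarray) -> np.ndarray:
    return np.where(a > 0, 1.0, np.exp(np.minimum(a, 0.0)))


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing interval boundaries tau_1 < ... < tau_K (months).

    Interval k covers (tau_{k-1}, tau_k] with tau_0 = 0; interval K+1 is
    "survives the whole grid".  A time falling exactly on a boundary
    belongs to the earlier interval (inclusive right endpoint).
    """

    boundaries: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 1 or b[0] <= 0 or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing and > 0")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_intervals(self) -> int:
        return self.boundaries.size

    def interval_of(self, times: np.ndarray) -> np.ndarray:
        """1-based interval index per time; K+1 for times beyond the grid."""
        t = np.asarray(times, dtype=float)
        if np.any(t <= 0):
            raise ValueError("times must be positive")
        return np.searchsorted(self.boundaries, t, side="left") + 1


def monthly_grid(n_intervals: int = 24) -> TimeGrid:
    """Monthly grid: boundaries at 1, 2, ..., n_intervals months."""
    return TimeGrid(np.arange(1, n_intervals + 1, dtype=float))


@dataclass
class PredictionSet:
    """Per-patient survival curve, horizon event probability and risk score.

    ``risk_score`` for MTLR is the discrete expected number of intervals
    spent dead, sum_k (1 - S(tau_k)) — strictly increasing in every
    interval's death probability, hence a valid lifetime-risk ranking.
    For binary-only baseline models the curve is absent and the predicted
    event probability doubles as the risk score.
    """

    event_prob: np.ndarray
    risk_score: np.ndarray
    survival_curve: np.ndarray | None = None
    grid: TimeGrid | None = None

    def __post_init__(self):
        self.event_prob = np.asarray(self.event_prob, dtype=float)
        self.risk_score = np.asarray(self.risk_score, dtype=float)
        if np.any((self.event_prob < -1e-9) | (self.event_prob > 1 + 1e-9)):
            raise ValueError("event probabilities must lie in [0, 1]")
        if self.survival_curve is not None:
            curve = np.asarray(self.survival_curve, dtype=float)
            if np.any((curve < -1e-9) | (curve > 1 + 1e-9)):
                raise ValueError("survival curve values must lie in [0, 1]")
            if np.any(np.diff(curve, axis=1) > 1e-9):
                raise ValueError("survival curves must be non-increasing")
            self.survival_curve = curve


class MTLR:
    """MTLR survival model bound to a training sample (statsmodels-style).

    Parameters
    ----------
    X : (n, d) array
        Encoded feature matrix.
    time_months, event : (n,) arrays
        Follow-up time (months, > 0) and event indicator (1 = death).
    time_grid : TimeGrid, optional
        Defaults to 24 monthly intervals.
    hidden_size : int or None
        None fits the linear variant; an integer fits the deep variant
        with one ELU hidden layer of that width.
    lambda_smooth, lambda_ridge : float
        Regularization strengths (defaults from a 5-fold CV grid search on
        the default simulated cohort; see the methods note).
    """

    def __init__(self, X, time_months, event, *, time_grid: TimeGrid | None
                 = None, hidden_size: int | None = None,
                 lambda_smooth: float = 10.0, lambda_ridge: float = 1.0,
                 feature_names=None):
        self.X = np.ascontiguousarray(X, dtype=float)
        self.time = np.asarray(time_months, dtype=float)
        self.event = np.asarray(event, dtype=int)
        if self.X.ndim != 2 or len(self.time) != len(self.X):
            raise ValueError("X and outcomes must have matching length")
        if np.any(self.time <= 0):
            raise ValueError("times must be positive")
        if lambda_smooth < 0 or lambda_ridge < 0:
            raise ValueError("regularization strengths must be >= 0")
        self.grid = time_grid or monthly_grid()
        self.hidden_size = hidden_size
        self.lambda_smooth = float(lambda_smooth)
        self.lambda_ridge = float(lambda_ridge)
        self.feature_names = list(feature_names) if feature_names is not None \
            else [f"x{j}" for j in range(self.X.shape[1])]
        self.n_obs, self.n_features = self.X.shape
        self._interval = self.grid.interval_of(self.time)  # 1..K+1

    @classmethod
    def from_dataframe(cls, df, feature_cols, duration_col="time_months",
                       event_col="event", **kwargs) -> "MTLR":
        return cls(df[list(feature_cols)].to_numpy(float),
                   df[duration_col].to_numpy(float),
                   df[event_col].to_numpy(int),
                   feature_names=list(feature_cols), **kwargs)

    # -- parameter packing ---------------------------------------------------

    @property
    def _dz(self) -> int:
        return self.hidden_size if self.hidden_size else self.n_features

    def _n_params(self) -> int:
        K, d, h = self.grid.n_intervals, self.n_features, self.hidden_size
        n = K * self._dz + K
        if h:
            n += h * d + h
        return n

    def _unpack(self, params):
        K, d, h = self.grid.n_intervals, self.n_features, self.hidden_size
        dz = self._dz
        W = params[:K * dz].reshape(K, dz)
        b = params[K * dz:K * dz + K]
        if h:
            off = K * dz + K
            Wh = params[off:off + h * d].reshape(h, d)
            ch = params[off + h * d:off + h * d + h]
            return W, b, Wh, ch
        return W, b, None, None

    def _pack(self, W, b, Wh=None, ch=None):
        parts = [W.ravel(), b]
        if Wh is not None:
            parts += [Wh.ravel(), ch]
        return np.concatenate(parts)

    # -- forward computations ------------------------------------------------

    def encode_hidden(self, params, X=None):
        """Representation z: ELU(W_h x + c_h) for the deep variant, x itself
        for the linear variant."""
        X = self.X if X is None else np.asarray(X, dtype=float)
        _, _, Wh, ch = self._unpack(np.asarray(params, dtype=float))
        if Wh is None:
            return X
        return elu(X @ Wh.T + ch)

    def sequence_logits(self, params, X=None) -> np.ndarray:
        """(n, K+1) unnormalized log-scores of the death-in-interval-k
        sequences; the last column (survive-all) is identically 0."""
        params = np.asarray(params, dtype=float)
        X = self.X if X is None else np.asarray(X, dtype=float)
        W, b, _, _ = self._unpack(params)
        Z = self.encode_hidden(params, X)
        U = Z @ W.T + b  # (n, K): per-interval logits
        s = np.cumsum(U[:, ::-1], axis=1)[:, ::-1]
        return np.hstack([s, np.zeros((len(s), 1))])

    def sequence_probs(self, params, X=None) -> np.ndarray:
        s = self.sequence_logits(params, X)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)

    # -- likelihood and gradient ---------------------------------------------

    def _penalty(self, W, Wh):
        pen = 0.5 * self.lambda_ridge * np.sum(W * W)
        if self.grid.n_intervals > 1:
            diff = np.diff(W, axis=0)
            pen += 0.5 * self.lambda_smooth * np.sum(diff * diff)
        if Wh is not None:
            pen += 0.5 * self.lambda_ridge * np.sum(Wh * Wh)
        return pen

    def loglike(self, params, subset=None) -> float:
        """Penalized log-likelihood at ``params`` (sum over patients).

        A patient censored inside interval k contributes the log summed
        probability of death strictly after k (sequence columns k..K, i.e.
        intervals k+1..K+1); censored or dead beyond the grid maps to the
        survive-all column K.
        """
        params = np.asarray(params, dtype=float)
        idx = slice(None) if subset is None else subset
        X, interval, event = self.X[idx], self._interval[idx], self.event[idx]
        K = self.grid.n_intervals
        s = self.sequence_logits(params, X)
        # tail[:, k] = logsumexp(s[:, k:])
        tail = np.logaddexp.accumulate(s[:, ::-1], axis=1)[:, ::-1]
        logZ = tail[:, 0]
        rows = np.arange(len(s))
        death_col = np.minimum(interval, K + 1) - 1
        cens_col = np.minimum(interval, K)
        ll = np.where(event == 1, s[rows, death_col],
                      tail[rows, cens_col]) - logZ
        W, _, Wh, _ = self._unpack(params)
        return float(ll.sum() - self._penalty(W, Wh))

    def score(self, params, subset=None) -> np.ndarray:
        """Gradient of the penalized log-likelihood (analytic backprop)."""
        params = np.asarray(params, dtype=float)
        idx = slice(None) if subset is None else subset
        X, interval, event = self.X[idx], self._interval[idx], self.event[idx]
        K = self.grid.n_intervals
        W, b, Wh, ch = self._unpack(params)
        Z = self.encode_hidden(params, X)
        s = self.sequence_logits(params, X)
        smax = s.max(axis=1, keepdims=True)
        e = np.exp(s - smax)
        p = e / e.sum(axis=1, keepdims=True)  # (n, K+1)
        tail = np.logaddexp.accumulate(s[:, ::-1], axis=1)[:, ::-1]
        # posterior over sequences consistent with the observation
        q = np.zeros_like(p)
        rows = np.arange(len(s))
        unc = event == 1
        q[rows[unc], np.minimum(interval[unc], K + 1) - 1] = 1.0
        if np.any(~unc):
            cen = ~unc
            start = np.minimum(interval[cen], K)
            cols = np.arange(K + 1)
            mask = cols[None, :] >= start[:, None]
            q[cen] = mask * np.exp(s[cen] - tail[cen, start][:, None])
        r = q - p  # d loglik / d s, (n, K+1); last column unused downstream
        g_u = np.cumsum(r[:, :K], axis=1)  # d loglik / d U_j
        gW = g_u.T @ Z
        gb = g_u.sum(axis=0)
        # penalties
        gW -= self.lambda_ridge * W
        if K > 1:
            diff = np.diff(W, axis=0)
            gW[:-1] += self.lambda_smooth * diff
            gW[1:] -= self.lambda_smooth * diff
        if Wh is None:
            return self._pack(gW, gb)
        A = X @ Wh.T + ch
        gZ = g_u @ W  # (n, h)
        dA = gZ * _elu_grad(A)
        gWh = dA.T @ X - self.lambda_ridge * Wh
        gch = dA.sum(axis=0)
        return self._pack(gW, gb, gWh, gch)

    # -- fitting -------------------------------------------------------------

    def fit(self, *, seed: int = 0, maxiter: int = 2000,
            epochs: int = 300, batch_size: int = 128, lr: float = 1e-3,
            val_fraction: float = 0.1, patience: int = 20,
            start_params=None) -> "MTLRResults":
        """Maximize the penalized likelihood.

        Linear variant: full-batch L-BFGS from zero (the problem is
        concave, so the optimum is unique up to numerical tolerance).
        Deep variant: seeded He-initialized minibatch Adam with early
        stopping on a held-out validation split (the problem is
        non-convex; the seed is recorded for reproducibility).
        """
        if self.event.sum() == 0:
            raise ValueError("no events in the training data; "
                             "the likelihood is degenerate")
        if self.n_obs < 2:
            raise ValueError("need at least 2 observations")
        if self.hidden_size is None:
            x0 = np.zeros(self._n_params()) if start_params is None \
                else np.asarray(start_params, dtype=float)
            n = self.n_obs  # per-observation scaling conditions the problem
            res = minimize(lambda p: -self.loglike(p) / n, x0,
                           jac=lambda p: -self.score(p) / n,
                           method="L-BFGS-B",
                           options={"maxiter": maxiter, "ftol": 1e-10,
                                    "gtol": 1e-5})
            return MTLRResults(self, res.x, converged=bool(res.success),
                               loglike_value=self.loglike(res.x), seed=seed,
                               n_iter=int(res.nit))
        return self._fit_deep(seed=seed, epochs=epochs, batch_size=batch_size,
                              lr=lr, val_fraction=val_fraction,
                              patience=patience)

    def _fit_deep(self, *, seed, epochs, batch_size, lr, val_fraction,
                  patience):
        rng = np.random.default_rng(seed)
        K, d, h = self.grid.n_intervals, self.n_features, self.hidden_size
        Wh = rng.normal(0.0, np.sqrt(2.0 / d), size=(h, d))
        ch = np.zeros(h)
        W = rng.normal(0.0, 0.01, size=(K, h))
        b = np.zeros(K)
        params = self._pack(W, b, Wh, ch)

        n = self.n_obs
        n_val = max(int(round(val_fraction * n)), 1) if n >= 20 else 0
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if n_val and self.event[train_idx].sum() == 0:
            val_idx, train_idx = np.array([], dtype=int), perm  # degenerate
            n_val = 0

        m = np.zeros_like(params)
        v = np.zeros_like(params)
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best = (params.copy(), -np.inf)
        stall = 0
        for epoch in range(epochs):
            order = rng.permutation(train_idx)
            for start in range(0, len(order), batch_size):
                batch = order[start:start + batch_size]
                if len(batch) == 0:
                    continue
                # scale batch gradient to full-sample likelihood scale
                g = self.score(params, subset=batch) * (len(train_idx)
                                                        / len(batch))
                t += 1
                m = beta1 * m + (1 - beta1) * g
                v = beta2 * v + (1 - beta2) * g * g
                mhat = m / (1 - beta1 ** t)
                vhat = v / (1 - beta2 ** t)
                params = params + lr * mhat / (np.sqrt(vhat) + eps)
            monitor = self.loglike(params, subset=val_idx) if n_val \
                else self.loglike(params)
            if monitor > best[1] + 1e-9:
                best = (params.copy(), monitor)
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break
        params = best[0]
        return MTLRResults(self, params, converged=True,
                           loglike_value=self.loglike(params), seed=seed,
                           n_iter=epoch + 1)


class MTLRResults:
    """Fitted MTLR: parameter access, prediction, summary, serialization."""

    def __init__(self, model: MTLR, params, *, converged: bool,
                 loglike_value: float, seed: int, n_iter: int):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.converged = converged
        self.loglike_value = loglike_value
        self.seed = seed
        self.n_iter = n_iter

    @property
    def weights(self):
        return self.model._unpack(self.params)[0]

    @property
    def biases(self):
        return self.model._unpack(self.params)[1]

    def predict(self, X=None) -> PredictionSet:
        """Survival curve S(tau_1..tau_K), event probability by tau_K, and
        expected-dead-time risk score for each patient."""
        p = self.model.sequence_probs(self.params, X)
        K = self.model.grid.n_intervals
        surv = 1.0 - np.cumsum(p[:, :K], axis=1)
        surv = np.clip(surv, 0.0, 1.0)
        event_prob = 1.0 - surv[:, -1]
        risk = np.sum(1.0 - surv, axis=1)
        return PredictionSet(event_prob=event_prob, risk_score=risk,
                             survival_curve=surv, grid=self.model.grid)

    def summary(self) -> str:
        m = self.model
        kind = (f"deep (hidden={m.hidden_size}, ELU)" if m.hidden_size
                else "linear")
        lines = [
            "Multitask logistic regression (discrete-time survival)",
            "=" * 58,
            f"variant:           {kind}",
            f"observations:      {m.n_obs}  (events: {int(m.event.sum())})",
            f"features:          {m.n_features}",
            f"time intervals:    {m.grid.n_intervals} "
            f"(up to {m.grid.boundaries[-1]:g} months)",
            f"lambda_smooth:     {m.lambda_smooth:g}",
            f"lambda_ridge:      {m.lambda_ridge:g}",
            f"penalized loglik:  {self.loglike_value:.4f}",
            f"converged:         {self.converged}  "
            f"(iterations: {self.n_iter}, seed: {self.seed})",
        ]
        return "\n".join(lines)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        m = self.model
        W, b, Wh, ch = m._unpack(self.params)
        return {
            "grid": m.grid.boundaries.tolist(),
            "hidden_size": m.hidden_size,
            "lambda_smooth": m.lambda_smooth,
            "lambda_ridge": m.lambda_ridge,
            "feature_names": m.feature_names,
            "weights": W.tolist(),
            "biases": b.tolist(),
            "encoder_weights": Wh.tolist() if Wh is not None else None,
            "encoder_biases": ch.tolist() if ch is not None else None,
            "seed": self.seed,
            "converged": self.converged,
            "loglike": self.loglike_value,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, payload: dict) -> "MTLRResults":
        grid = TimeGrid(np.asarray(payload["grid"]))
        d = len(payload["feature_names"])
        # bind to a 2-row placeholder sample; prediction only needs X
        dummy_X = np.zeros((2, d))
        model = MTLR(dummy_X, np.ones(2), np.ones(2, dtype=int),
                     time_grid=grid, hidden_size=payload["hidden_size"],
                     lambda_smooth=payload["lambda_smooth"],
                     lambda_ridge=payload["lambda_ridge"],
                     feature_names=payload["feature_names"])
        W = np.asarray(payload["weights"])
        b = np.asarray(payload["biases"])
        if payload["encoder_weights"] is not None:
            params = model._pack(W, b, np.asarray(payload["encoder_weights"]),
                                 np.asarray(payload["encoder_biases"]))
        else:
            params = model._pack(W, b)
        return cls(model, params, converged=payload["converged"],
                   loglike_value=payload["loglike"], seed=payload["seed"],
                   n_iter=0)

    @classmethod
    def from_json(cls, path) -> "MTLRResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
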