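"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: metrics are
computed by exhaustive pair/threshold enumeration and MTLR sequence
probabilities by direct enumeration of all monotone death sequences.
"""

import numpy as np


def auroc_oracle(scores, labels):
    """All-pairs Mann-Whitney counting."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def ap_oracle(scores, labels):
    """Direct threshold enumeration of the precision-recall step sum."""
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    thresholds = np.unique(s)[::-1]
    n_pos = y.sum()
    ap, prev_recall = 0.0, 0.0
    for thr in thresholds:
        kept = s >= thr
        tp = y[kept].sum()
        ap += (tp / n_pos - prev_recall) * (tp / kept.sum())
        prev_recall = tp / n_pos
    return ap


def c_index_oracle(risk, time, event):
    """Exhaustive comparable-pair enumeration, Harrell's convention."""
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


def mtlr_sequence_probs_oracle(W, b, z):
    """Enumerate all K+1 monotone death sequences directly."""
    K = W.shape[0]
    s = np.array([sum(W[j] @ z + b[j] for j in range(k, K))
                  for k in range(K)] + [0.0])
    e = np.exp(s)
    return e / e.sum()


def mtlr_loglik_oracle(model, W, b):
    """Independent penalized likelihood via enumerated sequence sums."""
    K = model.grid.n_intervals
    ll = 0.0
    for i in range(model.n_obs):
        p = mtlr_sequence_probs_oracle(W, b, model.X[i])
        k = int(np.searchsorted(model.grid.boundaries, model.time[i],
                                side="left")) + 1
        if model.event[i] == 1:
            ll += np.log(p[min(k, K + 1) - 1])
        else:
            ll += np.log(p[min(k, K):].sum())
    pen = (0.5 * model.lambda_ridge * np.sum(W * W)
           + 0.5 * model.lambda_smooth * np.sum(np.diff(W, axis=0) ** 2))
    return ll - pen
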