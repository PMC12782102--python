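"""Independent reference implementations used to check the package.

Everything here is deliberately naive — explicit loops, exhaustive sweeps,
pair counting — and shares no code with the implementation it verifies.
"""

from __future__ import annotations

import numpy as np


def loop_enhanced_attention(X, WQ, WK, WV, WO, gain, bias, variant):
    """Triple-loop reference for the enhanced single-head attention block."""
    L, D = X.shape
    Q = X @ WQ
    K = X @ WK
    V = X @ WV
    if variant == "matmul":
        out = np.zeros((L, D))
        for i in range(L):
            scores = np.array([Q[i] @ K[j] for j in range(L)]) / np.sqrt(D)
            e = np.exp(scores - scores.max())
            w = e / e.sum()
            for j in range(L):
                out[i] += w[j] * V[j]
    else:
        S = np.zeros((L, D))
        for i in range(L):
            for d in range(D):
                S[i, d] = Q[i, d] * K[i, d] / np.sqrt(D)
        out = np.zeros((L, D))
        for d in range(D):
            col = S[:, d]
            e = np.exp(col - col.max())
            w = e / e.sum()
            for i in range(L):
                out[i, d] = w[i] * V[i, d]
    proj = out @ WO
    R = X + proj
    Y = np.zeros_like(R)
    for i in range(L):
        mu = R[i].mean()
        var = R[i].var()
        Y[i] = gain * (R[i] - mu) / np.sqrt(var + 1e-5) + bias
    return Y


def loop_multihead(X, WQ, WK, WV, WO, gain, bias, heads):
    """Per-head loop reference for multi-head fusion attention (no mask)."""
    L, D = X.shape
    hd = D // heads
    Q = X @ WQ
    K = X @ WK
    V = X @ WV
    O = np.zeros((L, D))
    for h in range(heads):
        sl = slice(h * hd, (h + 1) * hd)
        for i in range(L):
            scores = np.array([Q[i, sl] @ K[j, sl] for j in range(L)]) / np.sqrt(hd)
            e = np.exp(scores - scores.max())
            w = e / e.sum()
            for j in range(L):
                O[i, sl] += w[j] * V[j, sl]
    R = X + O @ WO
    Y = np.zeros_like(R)
    for i in range(L):
        mu = R[i].mean()
        var = R[i].var()
        Y[i] = gain * (R[i] - mu) / np.sqrt(var + 1e-5) + bias
    return Y


def mann_whitney_auc(scores, labels):
    """AUC as the normalized pair statistic (ties count one half)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def sweep_confusion(scores, labels, t):
    """Count TP/FP/TN/FN by explicit iteration (predict positive iff >= t)."""
    tp = fp = tn = fn = 0
    for s, y in zip(scores, labels):
        if s >= t:
            if y == 1:
                tp += 1
            else:
                fp += 1
        else:
            if y == 1:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn


def step_average_precision(scores, labels):
    """AP as the step-wise sum over the descending-score ranking."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    y = np.asarray(labels)[order]
    n_pos = int(y.sum())
    ap = 0.0
    tp = 0
    # group tied scores at a single threshold
    s_sorted = np.asarray(scores, dtype=float)[order]
    i = 0
    prev_recall = 0.0
    while i < len(y):
        j = i
        while j < len(y) and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(y[i:j].sum())
        recall = tp / n_pos
        precision = tp / j
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def double_loop_window_mean(x, N, passes):
    """Reference truncated-window smoother for a 1-D signal."""
    x = list(map(float, x))
    half = (N - 1) // 2
    for _ in range(passes):
        out = []
        for i in range(len(x)):
            lo = max(0, i - half)
            hi = min(len(x), i + half + 1)
            out.append(sum(x[lo:hi]) / (hi - lo))
        x = out
    return x
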