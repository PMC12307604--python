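"""Independent reference implementations used only to check the package.

These are deliberately naive (loops, explicit formulas) and share no code
with the package: a Newton-Raphson Cox partial-likelihood solver, a
pairwise-comparison AUC, confusion-matrix metrics from first principles, and
a hand product-limit estimator.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def cox_newton(X, time, event, max_iter=200, tol=1e-12):
    """Cox PH fit by Newton-Raphson on the Breslow partial likelihood.

    Valid as an Efron-equivalent reference only when event times are unique.
    Returns (beta, se, z, p) arrays.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        grad = np.zeros(k)
        hess = np.zeros((k, k))
        eta = X @ beta
        w = np.exp(eta)
        for i in range(n):
            if d[i] != 1:
                continue
            risk = t >= t[i]
            wr = w[risk]
            xr = X[risk]
            s0 = wr.sum()
            s1 = (wr[:, None] * xr).sum(axis=0)
            s2 = (wr[:, None, None] * xr[:, :, None] * xr[:, None, :]).sum(axis=0)
            grad += X[i] - s1 / s0
            hess += s2 / s0 - np.outer(s1, s1) / s0**2
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    # observed information at the optimum
    eta = X @ beta
    w = np.exp(eta)
    hess = np.zeros((k, k))
    for i in range(n):
        if d[i] != 1:
            continue
        risk = t >= t[i]
        wr = w[risk]
        xr = X[risk]
        s0 = wr.sum()
        s1 = (wr[:, None] * xr).sum(axis=0)
        s2 = (wr[:, None, None] * xr[:, :, None] * xr[:, None, :]).sum(axis=0)
        hess += s2 / s0 - np.outer(s1, s1) / s0**2
    se = np.sqrt(np.diag(np.linalg.inv(hess)))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return beta, se, z, p


def auc_pairs(outcome, score):
    """AUC by explicit comparison of all (positive, negative) pairs."""
    outcome = np.asarray(outcome, dtype=int)
    score = np.asarray(score, dtype=float)
    pos = score[outcome == 1]
    neg = score[outcome == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def metrics_from_confusion(cm):
    """Accuracy, weighted F1, Cohen's kappa from confusion counts (rows=truth)."""
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    acc = np.trace(cm) / n
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    p_o = acc
    p_e = (row * col).sum() / n**2
    kappa = (p_o - p_e) / (1.0 - p_e)
    f1s = []
    for i in range(cm.shape[0]):
        tp = cm[i, i]
        prec = tp / col[i] if col[i] > 0 else 0.0
        rec = tp / row[i] if row[i] > 0 else 0.0
        f1s.append(0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec))
    weighted_f1 = float((row / n * np.asarray(f1s)).sum())
    recalls = np.where(row > 0, np.diag(cm) / np.maximum(row, 1), np.nan)
    return {"accuracy": float(acc), "weighted_f1": weighted_f1,
            "cohens_kappa": float(kappa), "per_class_recall": recalls}


def km_by_hand(time, event):
    """Product-limit estimator as a dict {event_time: S(t)}."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    s = 1.0
    out = {}
    for t in sorted(set(time[event == 1])):
        at_risk = (time >= t).sum()
        deaths = ((time == t) & (event == 1)).sum()
        s *= 1.0 - deaths / at_risk
        out[t] = s
    return out


def logrank_by_hand(time, event, group):
    """Two-group log-rank chi-squared from observed-minus-expected sums."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    g0 = sorted(set(group))[0]
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n0 = (at_risk & (group == g0)).sum()
        d = ((time == t) & (event == 1)).sum()
        d0 = ((time == t) & (event == 1) & (group == g0)).sum()
        o_minus_e += d0 - d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    stat = o_minus_e**2 / var
    p = stats.chi2.sf(stat, df=1)
    return float(stat), float(p)
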