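"""Small dense SMO solver for linear C-SVC and epsilon-SVR.

The cross-validated pattern analyses in this package solve tens of thousands
of tiny SVM problems (n < 100 samples) inside permutation loops.  This module
implements the standard maximal-violating-pair SMO algorithm on a precomputed
kernel matrix, JIT-compiled with numba so a single fit costs microseconds.
The formulation (dual problem, stopping rule, tolerance 1e-3, intercept from
free support vectors) follows the reference libsvm algorithm, and the test
suite checks agreement with scikit-learn's libsvm bindings.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TOL = 1e-3
_MAX_ITER = 100_000


@njit(cache=True)
def _smo(Q, p, y, C, tol, max_iter):
    """Minimise 0.5*a'Qa + p'a  s.t.  y'a = 0,  0 <= a <= C.

    Q must already include the label signs (Q_ij = y_i y_j K_ij for C-SVC).
    Returns (alpha, b) where b is the intercept of the decision function.
    """
    n = Q.shape[0]
    alpha = np.zeros(n)
    G = p.copy()  # gradient of the objective: Q a + p
    Gmax = 0.0
    Gmin = 0.0
    for _ in range(max_iter):
        # maximal violating pair (first-order working set selection)
        Gmax = -1e300
        Gmin = 1e300
        i = -1
        j = -1
        for t in range(n):
            if (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0):
                v = -y[t] * G[t]
                if v > Gmax:
                    Gmax = v
                    i = t
            if (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < C):
                v = -y[t] * G[t]
                if v < Gmin:
                    Gmin = v
                    j = t
        if i < 0 or j < 0 or Gmax - Gmin < tol:
            break

        old_ai = alpha[i]
        old_aj = alpha[j]
        if y[i] != y[j]:
            quad = Q[i, i] + Q[j, j] + 2.0 * Q[i, j]
            if quad <= 0.0:
                quad = 1e-12
            delta = (-G[i] - G[j]) / quad
            diff = alpha[i] - alpha[j]
            alpha[i] += delta
            alpha[j] += delta
            if diff > 0.0:
                if alpha[j] < 0.0:
                    alpha[j] = 0.0
                    alpha[i] = diff
            else:
                if alpha[i] < 0.0:
                    alpha[i] = 0.0
                    alpha[j] = -diff
            if diff > 0.0:
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = C - diff
            else:
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = C + diff
        else:
            quad = Q[i, i] + Q[j, j] - 2.0 * Q[i, j]
            if quad <= 0.0:
                quad = 1e-12
            delta = (G[i] - G[j]) / quad
            s = alpha[i] + alpha[j]
            alpha[i] -= delta
            alpha[j] += delta
            if s > C:
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = s - C
            else:
                if alpha[j] < 0.0:
                    alpha[j] = 0.0
                    alpha[i] = s
            if s > C:
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = s - C
            else:
                if alpha[i] < 0.0:
                    alpha[i] = 0.0
                    alpha[j] = s

        dai = alpha[i] - old_ai
        daj = alpha[j] - old_aj
        for t in range(n):
            G[t] += Q[t, i] * dai + Q[t, j] * daj

    # intercept: average of -y_t G_t over free vectors, else the midpoint
    nfree = 0
    bsum = 0.0
    for t in range(n):
        if 0.0 < alpha[t] < C:
            bsum += -y[t] * G[t]
            nfree += 1
    if nfree > 0:
        b = bsum / nfree
    else:
        b = 0.5 * (Gmax + Gmin)
    return alpha, b


@njit(cache=True)
def svc_fit(K, y, C):
    """C-SVC on precomputed kernel K with labels y in {-1,+1}.

    Returns (coef, b) where coef_t = y_t * alpha_t, so the decision value for
    a new point x is  sum_t coef_t K(x_t, x) + b.
    """
    n = K.shape[0]
    Q = np.empty((n, n))
    for a in range(n):
        for c in range(n):
            Q[a, c] = y[a] * y[c] * K[a, c]
    p = -np.ones(n)
    alpha, b = _smo(Q, p, y, C, _TOL, _MAX_ITER)
    return alpha * y, b


@njit(cache=True)
def svr_fit(K, target, C, eps):
    """epsilon-SVR on precomputed kernel K.

    Solved by expanding beta = alpha - alpha* into 2n box variables, which
    reduces the problem to the same SMO form as classification.  Returns
    (beta, b); the prediction for x is  sum_t beta_t K(x_t, x) + b.
    """
    n = K.shape[0]
    m = 2 * n
    s = np.empty(m)
    p = np.empty(m)
    for t in range(n):
        s[t] = 1.0
        s[n + t] = -1.0
        p[t] = eps - target[t]
        p[n + t] = eps + target[t]
    Q = np.empty((m, m))
    for a in range(m):
        ia = a if a < n else a - n
        for c in range(m):
            ic = c if c < n else c - n
            Q[a, c] = s[a] * s[c] * K[ia, ic]
    z, b = _smo(Q, p, s, C, _TOL, _MAX_ITER)
    beta = np.empty(n)
    for t in range(n):
        beta[t] = z[t] - z[n + t]
    return beta, b


@njit(cache=True)
def loocv_decision_values(K, y, C):
    """Leave-one-out decision values for C-SVC on a precomputed kernel.

    y in {-1,+1}.  Fold i trains on all samples but i and returns the decision
    value for sample i; the caller thresholds at zero.
    """
    n = K.shape[0]
    dec = np.empty(n)
    idx = np.empty(n - 1, dtype=np.int64)
    for i in range(n):
        k = 0
        for t in range(n):
            if t != i:
                idx[k] = t
                k += 1
        Ksub = np.empty((n - 1, n - 1))
        ysub = np.empty(n - 1)
        for a in range(n - 1):
            ysub[a] = y[idx[a]]
            for c in range(n - 1):
                Ksub[a, c] = K[idx[a], idx[c]]
        coef, b = svc_fit(Ksub, ysub, C)
        v = b
        for a in range(n - 1):
            v += coef[a] * K[i, idx[a]]
        dec[i] = v
    return dec


@njit(cache=True)
def loocv_predictions_svr(K, target, C, eps):
    """Leave-one-out predicted values for epsilon-SVR on a precomputed kernel."""
    n = K.shape[0]
    pred = np.empty(n)
    idx = np.empty(n - 1, dtype=np.int64)
    for i in range(n):
        k = 0
        for t in range(n):
            if t != i:
                idx[k] = t
                k += 1
        Ksub = np.empty((n - 1, n - 1))
        tsub = np.empty(n - 1)
        for a in range(n - 1):
            tsub[a] = target[idx[a]]
            for c in range(n - 1):
                Ksub[a, c] = K[idx[a], idx[c]]
        beta, b = svr_fit(Ksub, tsub, C, eps)
        v = b
        for a in range(n - 1):
            v += beta[a] * K[i, idx[a]]
        pred[i] = v
    return pred


@njit(cache=True)
def permuted_loocv_accuracies(K, y_perms, C):
    """LOOCV accuracy (fraction correct) for each row of permuted labels."""
    n_perm = y_perms.shape[0]
    n = K.shape[0]
    out = np.empty(n_perm)
    for q in range(n_perm):
        y = y_perms[q]
        dec = loocv_decision_values(K, y, C)
        correct = 0
        for i in range(n):
            pred = 1.0 if dec[i] >= 0.0 else -1.0
            if pred == y[i]:
                correct += 1
        out[q] = correct / n
    return out


@njit(cache=True)
def permuted_loocv_pearson(K, target_perms, C, eps):
    """LOOCV Pearson r(prediction, target) for each row of permuted targets."""
    n_perm = target_perms.shape[0]
    n = K.shape[0]
    out = np.empty(n_perm)
    for q in range(n_perm):
        t = target_perms[q]
        pred = loocv_predictions_svr(K, t, C, eps)
        mp = pred.mean()
        mt = t.mean()
        num = 0.0
        dp = 0.0
        dt = 0.0
        for i in range(n):
            num += (pred[i] - mp) * (t[i] - mt)
            dp += (pred[i] - mp) ** 2
            dt += (t[i] - mt) ** 2
        denom = np.sqrt(dp * dt)
        out[q] = num / denom if denom > 0.0 else 0.0
    return out
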