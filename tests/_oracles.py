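"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: the ANOVA
oracle is a direct sums-of-squares computation, the lasso oracle is the
closed-form soft threshold on orthonormal designs, and the power oracle
is a dense scan of the noncentral-F power curve.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def mixed_anova_ss(Y: np.ndarray, groups: np.ndarray) -> dict:
    """Direct sums-of-squares two-way mixed ANOVA (balanced design).

    Y is subjects x within-levels; groups labels the between factor.
    """
    Y = np.asarray(Y, float)
    n, k = Y.shape
    glabels = np.unique(groups)
    G = len(glabels)
    m = Y.mean()

    ss_total = ((Y - m) ** 2).sum()
    subj_means = Y.mean(axis=1)
    ss_between_subj = k * ((subj_means - m) ** 2).sum()

    ss_group = 0.0
    for g in glabels:
        sel = groups == g
        ss_group += k * sel.sum() * (Y[sel].mean() - m) ** 2
    ss_subj_within = ss_between_subj - ss_group

    level_means = Y.mean(axis=0)
    ss_time = n * ((level_means - m) ** 2).sum()

    ss_cells = 0.0
    for g in glabels:
        sel = groups == g
        cell = Y[sel].mean(axis=0)
        ss_cells += sel.sum() * ((cell - m) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_time
    ss_err = ss_total - ss_cells - ss_subj_within

    df_g, df_s = G - 1, n - G
    df_t, df_i, df_e = k - 1, (G - 1) * (k - 1), (n - G) * (k - 1)
    f_group = (ss_group / df_g) / (ss_subj_within / df_s)
    f_time = (ss_time / df_t) / (ss_err / df_e)
    f_inter = (ss_inter / df_i) / (ss_err / df_e)
    return {
        "between": (f_group, df_g, df_s),
        "within": (f_time, df_t, df_e),
        "interaction": (f_inter, df_i, df_e),
    }


def gg_epsilon(Y: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centered covariance."""
    Y = np.asarray(Y, float)
    k = Y.shape[1]
    S = np.cov(Y, rowvar=False)
    J = np.eye(k) - 1.0 / k
    Sd = J @ S @ J
    lam = np.linalg.eigvalsh(Sd)
    lam = np.clip(lam, 0, None)
    return float(lam.sum() ** 2 / ((k - 1) * (lam**2).sum()))


def holm_by_hand(pvals):
    """Step-down Holm adjustment, written out longhand."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = (m - rank) * p[idx]
        running = max(running, val)
        adj[idx] = min(1.0, running)
    return adj


def soft_threshold(b, lam):
    return np.sign(b) * np.maximum(np.abs(b) - lam, 0.0)


def pooled_t_by_hand(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


def power_scan(n_predictors: int, f2: float, alpha: float, target: float) -> int:
    """Dense scan of the noncentral-F power curve for the smallest N."""
    for n in range(n_predictors + 2, 2000):
        df2 = n - n_predictors - 1
        fcrit = sps.f.isf(alpha, n_predictors, df2)
        if sps.ncf.sf(fcrit, n_predictors, df2, f2 * n) >= target:
            return n
    raise RuntimeError("not attainable")


def streaming_mean(values):
    """Welford-style running mean, independent of numpy reductions."""
    m, n = 0.0, 0
    for v in values:
        n += 1
        m += (v - m) / n
    return m
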