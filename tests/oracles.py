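"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by direct enumeration or by the naive
definition, sharing no code with the package implementation it checks.
"""

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata


def freezing_labels_bruteforce(values, threshold, min_run):
    """O(n*w) window scan: frame i freezes iff some window of min_run
    consecutive strictly-sub-threshold frames covers it."""
    n = len(values)
    below = [v < threshold for v in values]
    labels = [False] * n
    for start in range(n - min_run + 1):
        if all(below[start:start + min_run]):
            for i in range(start, start + min_run):
                labels[i] = True
    return np.array(labels)


def gaussian_smooth_dense(values, sigma, radius):
    """Dense-matrix Gaussian convolution with edge replication."""
    n = len(values)
    ks = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (ks / sigma) ** 2)
    kernel /= kernel.sum()
    out = np.zeros(n)
    for i in range(n):
        for k, w in zip(ks, kernel):
            j = min(max(i + k, 0), n - 1)
            out[i] += w * values[j]
    return out


def mannwhitney_exact_enum(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all assignments of the
    pooled sample to groups (no ties).  Returns (U_min, p)."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    n1, n2 = len(x), len(y)

    def u_min(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n1 + n2) if i not in idx]
        u1 = sum(1 for a in xs for b in ys if a > b)
        return min(u1, n1 * n2 - u1)

    u_obs = min(sum(1 for a in x for b in y if a > b),
                sum(1 for b in y for a in x if b > a))
    count = sum(1 for idx in combinations(range(n1 + n2), n1)
                if u_min(set(idx)) <= u_obs)
    return u_obs, count / comb(n1 + n2, n1)


def fisher_exact_enum(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with the observed
    margins and summing hypergeometric probabilities <= the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k):
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(a)
    eps = 1e-10 * p_obs
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs + eps)


def srh_oracle(values, fa, fb):
    """Scheirer-Ray-Hare H statistics via a rank two-way ANOVA computed with
    an independent OLS route (statsmodels anova_lm on the ranks)."""
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"r": rankdata(values), "A": fa, "B": fb})
    fit = ols("r ~ C(A) + C(B) + C(A):C(B)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    n = len(df)
    ss_total = np.sum((df["r"] - df["r"].mean()) ** 2)
    ms_total = ss_total / (n - 1)
    return {
        "A": tab.loc["C(A)", "sum_sq"] / ms_total,
        "B": tab.loc["C(B)", "sum_sq"] / ms_total,
        "interaction": tab.loc["C(A):C(B)", "sum_sq"] / ms_total,
    }


def holm_stepdown(p_values):
    """Brute-force Holm step-down adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def welch_savgol_pointwise(y, window=11, order=2):
    """Per-point weighted local polynomial regression via lstsq with
    sqrt-weight scaling (independent of the normal-equations route)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    half = (window - 1) // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        ks = np.arange(lo - i, hi - i, dtype=float)
        w = 1.0 - (ks / ((window + 1) / 2.0)) ** 2
        X = np.vander(ks, order + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y[lo:hi] * sw, rcond=None)
        out[i] = beta[0]
    return out
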