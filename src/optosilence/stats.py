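"""Statistical tests used throughout the silencing analyses.

Every procedure returns a :class:`TestResult` so downstream code (and the
CLI) can treat heterogeneous tests uniformly.  Standard tests are thin
wrappers around :mod:`scipy.stats` / :mod:`statsmodels` with the degenerate
cases (zero-variance paired differences, zero contingency cells) handled
explicitly; the Scheirer-Ray-Hare rank two-way ANOVA and the one-way
within-subject F are implemented here because no mainstream library ships
them in the form needed.

Conventions
-----------
* All tests are two-sided by default at alpha = 0.05; one-sided variants are
  opt-in via ``sidedness``.
* Ties are handled by mean ranks everywhere.
* The 2x2 chi-square uses the Pearson statistic *without* Yates continuity
  correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    """Outcome of a hypothesis test.

    Attributes
    ----------
    statistic : float
        The test statistic (chi2, U, H, t, F, or odds ratio).
    p_value : float
        p in [0, 1].
    df : float or tuple or None
        Degrees of freedom; a pair for F tests.
    sidedness : str
        'two-sided', 'greater' or 'less'.
    method : str
        Identifier of the procedure.
    notes : dict
        Ties, corrections, degeneracy flags.
    """

    statistic: float
    p_value: float
    df: object = None
    sidedness: str = "two-sided"
    method: str = ""
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0,1]: {self.p_value}")


def chi2_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    The table is ``[[a, b], [c, d]]``.  All cells must be positive; tables
    with a zero cell must go through :func:`fisher_exact_2x2` instead.
    """
    cells = np.array([[a, b], [c, d]], dtype=float)
    if np.any(cells <= 0):
        raise ValueError(
            "chi2_2x2 requires all cells > 0; use fisher_exact_2x2 for "
            "tables containing zeros"
        )
    chi2, p, dof, _ = _sps.chi2_contingency(cells, correction=False)
    return TestResult(statistic=float(chi2), p_value=float(p), df=dof,
                      method="chi2_2x2")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Fisher's exact test on a 2x2 table, two-sided.

    Two-sided p sums the hypergeometric probabilities of all tables (with
    the observed margins) no more probable than the observed one.  The
    statistic is the sample odds ratio (may be inf).
    """
    cells = np.array([[a, b], [c, d]])
    if np.any(cells < 0):
        raise ValueError("counts must be non-negative")
    odds, p = _sps.fisher_exact(cells, alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=float(p),
                      method="fisher_exact_2x2")


def mann_whitney_u(x, y, sidedness: str = "two-sided",
                   mode: str = "exact") -> TestResult:
    """Mann-Whitney U test.

    Parameters
    ----------
    mode : {'exact', 'normal_cc'}
        'exact' enumerates the null distribution of U (valid without ties;
        falls back to the normal approximation when ties are present, with a
        note).  'normal_cc' uses the normal approximation with continuity
        correction and tie-corrected variance.

    The reported statistic is ``U = min(U1, U2)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    notes = {}
    if mode == "exact":
        if has_ties:
            notes["ties"] = "ties present; exact enumeration invalid, used normal_cc"
            method_scipy = "asymptotic"
            use_cc = True
        else:
            method_scipy = "exact"
            use_cc = False
    elif mode == "normal_cc":
        method_scipy = "asymptotic"
        use_cc = True
        if has_ties:
            notes["ties"] = "tie-corrected variance"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = _sps.mannwhitneyu(x, y, alternative=sidedness,
                            method=method_scipy, use_continuity=use_cc)
    u1 = float(res.statistic)
    u2 = x.size * y.size - u1
    return TestResult(statistic=min(u1, u2), p_value=float(res.pvalue),
                      sidedness=sidedness, method=f"mann_whitney_u[{mode}]",
                      notes=notes)


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square reference, df=k-1)."""
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and \
            not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=0.0, p_value=1.0, df=len(arrays) - 1,
                          method="kruskal_wallis",
                          notes={"degenerate": "all values identical"})
    h, p = _sps.kruskal(*arrays)
    return TestResult(statistic=float(h), p_value=float(p),
                      df=len(arrays) - 1, method="kruskal_wallis")


def scheirer_ray_hare(values, factor_a, factor_b) -> dict:
    """Scheirer-Ray-Hare rank-based two-way ANOVA.

    All observations are ranked jointly (mean ranks for ties); ordinary
    two-way ANOVA sums of squares are computed on the ranks, and each effect
    statistic is ``H = SS_effect / MS_total`` with
    ``MS_total = SS_total / (N - 1)``, referred to a chi-square distribution
    with the effect's degrees of freedom.

    Returns a dict with keys ``'A'``, ``'B'``, ``'interaction'`` mapping to
    :class:`TestResult`.  The design must be crossed with every (A, B) cell
    non-empty; it need not be balanced (cell-mean sums of squares are used,
    which reduce to the classical ones in the balanced case).
    """
    v = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (v.size == fa.size == fb.size):
        raise ValueError("values and factor labels must have equal length")
    n = v.size
    ranks = _sps.rankdata(v)
    a_levels = np.unique(fa)
    b_levels = np.unique(fb)
    grand = ranks.mean()
    ss_total = np.sum((ranks - grand) ** 2)
    ms_total = ss_total / (n - 1)

    # cell means; reject empty cells
    cell_mean = {}
    cell_n = {}
    for ai in a_levels:
        for bi in b_levels:
            m = (fa == ai) & (fb == bi)
            if not m.any():
                raise ValueError(f"empty cell ({ai!r}, {bi!r})")
            cell_mean[(ai, bi)] = ranks[m].mean()
            cell_n[(ai, bi)] = int(m.sum())

    ss_a = sum(ranks[fa == ai].size * (ranks[fa == ai].mean() - grand) ** 2
               for ai in a_levels)
    ss_b = sum(ranks[fb == bi].size * (ranks[fb == bi].mean() - grand) ** 2
               for bi in b_levels)
    ss_cells = sum(cell_n[k] * (cell_mean[k] - grand) ** 2 for k in cell_mean)
    ss_ab = ss_cells - ss_a - ss_b

    df_a = a_levels.size - 1
    df_b = b_levels.size - 1
    df_ab = df_a * df_b

    out = {}
    for key, ss, df in (("A", ss_a, df_a), ("B", ss_b, df_b),
                        ("interaction", ss_ab, df_ab)):
        h = ss / ms_total if ms_total > 0 else 0.0
        h = max(h, 0.0)  # interaction SS can be slightly negative (unbalanced rounding)
        p = float(_sps.chi2.sf(h, df)) if df > 0 else 1.0
        out[key] = TestResult(statistic=float(h), p_value=p, df=df,
                              method="scheirer_ray_hare")
    return out


def paired_t(x, y, sidedness: str = "two-sided") -> TestResult:
    """Paired-sample Student's t-test on x - y.

    Degenerate variance is handled rather than raised: all-zero differences
    give p = 1 (no evidence of any effect); zero-variance differences with a
    nonzero mean give p = 0 flagged degenerate (the effect is deterministic
    at the observed resolution).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return TestResult(statistic=0.0, p_value=1.0, df=x.size - 1,
                              sidedness=sidedness, method="paired_t",
                              notes={"degenerate": "all differences zero"})
        sign = math.copysign(1.0, d.mean())
        return TestResult(statistic=sign * math.inf, p_value=0.0,
                          df=x.size - 1, sidedness=sidedness,
                          method="paired_t",
                          notes={"degenerate": "zero-variance nonzero-mean differences"})
    res = _sps.ttest_rel(x, y, alternative=sidedness)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      df=x.size - 1, sidedness=sidedness, method="paired_t")


def rm_anova_oneway(data) -> TestResult:
    """One-way repeated-measures ANOVA.

    Parameters
    ----------
    data : (n_subjects, k_conditions) array
        Complete matrix, one row per subject.

    F = MS_condition / MS_error with df = (k-1, (k-1)(n-1)); the
    subject-by-condition interaction is the error term.
    """
    m = np.asarray(data, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a subjects x conditions matrix")
    if np.any(~np.isfinite(m)):
        raise ValueError("missing cells are not allowed")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = m.mean()
    ss_cond = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_err = ss_err / df_err
    if ms_err <= 0:
        return TestResult(statistic=0.0, p_value=1.0, df=(df_cond, df_err),
                          method="rm_anova_oneway",
                          notes={"degenerate": "zero error variance"})
    f = (ss_cond / df_cond) / ms_err
    p = float(_sps.f.sf(f, df_cond, df_err))
    return TestResult(statistic=float(f), p_value=p, df=(df_cond, df_err),
                      method="rm_anova_oneway")


def holm_bonferroni(p_values, alpha: float = 0.05):
    """Holm-Bonferroni step-down adjustment.

    Returns ``(adjusted_p, reject)`` arrays in the input order; adjusted
    p-values are monotone in the input ranks and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, reject
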