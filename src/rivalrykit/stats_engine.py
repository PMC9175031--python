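"""Mixed-design statistical battery for rivalry metrics tables.

Implements the split-plot (mixed factorial) ANOVA with Type-III sums of
squares under sum-to-zero coding, Greenhouse-Geisser sphericity correction,
partial eta-squared effect sizes, an optional between-subject covariate,
pairwise follow-ups (Bonferroni or LSD), classical t-tests with Cohen's d,
the Mann-Whitney U test, and Pearson correlation.

The within-subject machinery uses the orthonormal-contrast formulation: for a
within effect with q contrast degrees of freedom, each subject's cell vector
is projected onto an orthonormal contrast basis M (one basis per effect; for
two within factors the bases are Kronecker products), and the transformed
scores Z = Y M are analyzed in a between-subjects linear model X (intercept,
sum-to-zero group contrasts, and the centered covariate when supplied).  The
within main effect is the Type-III test of the intercept of Z, the
within-by-group interaction the test of the group columns, both against the
pooled residual of Z with q*(N - p) error degrees of freedom.  This is the
classical univariate repeated-measures decomposition, and it reproduces the
covariate-adjusted error degrees of freedom used by standard GLM software
(e.g. a 3-level within factor with 31 subjects, 2 groups and one covariate
tests within effects on (2, 56) df).

Greenhouse-Geisser epsilon is estimated per within effect from the pooled
residual covariance of the contrast scores; raw and corrected p-values are
both reported, with Mauchly's test as auxiliary output.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "partial_eta_squared",
    "cohens_d_from_t",
    "independent_t",
    "paired_t",
    "mann_whitney_u",
    "pearson_r",
    "gg_epsilon",
    "gg_epsilon_from_scores",
    "mauchly_test",
    "mixed_anova",
    "pairwise_comparisons",
    "TTestResult",
]


ANOVA_COLUMNS = [
    "Source", "SS", "df1", "df2", "MS", "SS_err", "F", "p", "np2",
    "eps", "df1_gg", "df2_gg", "p_gg", "mauchly_W", "mauchly_p",
]


# ---------------------------------------------------------------------------
# effect sizes and simple tests


def partial_eta_squared(F: float, df_num: float, df_den: float) -> float:
    """Partial eta-squared from an F statistic: F*df1 / (F*df1 + df2).

    Fractional (sphericity-corrected) degrees of freedom are allowed; the
    value is identical for raw and corrected dfs because the correction
    rescales numerator and denominator dfs by the same factor.
    """
    if F < 0 or df_num <= 0 or df_den <= 0:
        raise ValueError("F must be >= 0 and degrees of freedom positive")
    return F * df_num / (F * df_num + df_den)


def cohens_d_from_t(t: float, n1: int, n2: int) -> float:
    """Cohen's d for two independent groups recovered from the pooled t."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 observations")
    return t * math.sqrt(1.0 / n1 + 1.0 / n2)


class TTestResult:
    __slots__ = ("t", "df", "p", "d")

    def __init__(self, t: float, df: float, p: float, d: float):
        self.t, self.df, self.p, self.d = t, df, p, d

    def __iter__(self):
        return iter((self.t, self.df, self.p, self.d))

    def __repr__(self):
        return f"TTestResult(t={self.t:.4g}, df={self.df:g}, p={self.p:.4g}, d={self.d:.4g})"


def independent_t(x, y) -> TTestResult:
    """Classical pooled-variance independent-samples t-test (df = n1+n2-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least 2 observations")
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(float(t), n1 + n2 - 2, float(p),
                       cohens_d_from_t(float(t), n1, n2))


def paired_t(x, y) -> TTestResult:
    """Paired-samples t-test; d is the mean difference over the SD of
    differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    t, p = stats.ttest_rel(x, y)
    return TTestResult(float(t), len(x) - 1, float(p), float(diff.mean() / sd))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U, reported with the min-U convention.

    U counts the (x_i, y_j) pairs with x_i < y_j plus half the ties; the
    smaller of the two complementary statistics is returned.  The p-value is
    exact (two-sided) when the combined sample size is at most 20 and the
    data contain no ties, otherwise the normal approximation with tie
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u_greater = float(res.statistic)           # pairs with x > y (+ ties/2)
    u_less = len(x) * len(y) - u_greater       # pairs with x < y (+ ties/2)
    return min(u_less, u_greater), float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# sphericity


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser (Box) epsilon from the k x k covariance matrix of
    the within-cell scores; bounded in [1/(k-1), 1], exactly 1 at k = 2 and
    under compound symmetry."""
    S = np.asarray(cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1] or S.shape[0] < 2:
        raise ValueError("cov must be a square matrix with k >= 2")
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (
        np.sum(S ** 2) - 2 * k * np.sum(row_means ** 2) + k ** 2 * grand ** 2
    )
    if den <= 0:
        return 1.0
    eps = num / den
    return float(min(1.0, max(1.0 / (k - 1), eps)))


def gg_epsilon_from_scores(scores: np.ndarray) -> float:
    """Epsilon from an n x k matrix of within-cell scores (n >= 2 subjects)."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2:
        raise ValueError("need at least 2 subjects of within-cell scores")
    return gg_epsilon(np.cov(scores, rowvar=False))


def _eps_from_contrast_cov(S_z: np.ndarray) -> float:
    """Epsilon computed on the q x q covariance of orthonormal contrast
    scores: (tr S)^2 / (q * tr(S^2))."""
    q = S_z.shape[0]
    tr = float(np.trace(S_z))
    tr2 = float(np.sum(S_z * S_z))
    if tr2 <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / q, tr * tr / (q * tr2))))


def mauchly_test(S_z: np.ndarray, df_resid: int) -> tuple[float, float]:
    """Mauchly's sphericity W and its chi-square p (auxiliary diagnostic),
    computed on the covariance of orthonormal contrast scores."""
    q = S_z.shape[0]
    if q < 2:
        return 1.0, 1.0
    eigvals = np.linalg.eigvalsh(S_z)
    if np.any(eigvals <= 0):
        return 0.0, 0.0
    W = float(np.prod(eigvals) / (np.mean(eigvals) ** q))
    f = 1.0 - (2 * q * q + q + 2) / (6.0 * q * df_resid)
    chi2 = -f * df_resid * math.log(max(W, 1e-300))
    df = q * (q + 1) // 2 - 1
    return W, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# mixed factorial ANOVA


def _contrast_basis(k: int) -> np.ndarray:
    """Deterministic orthonormal contrast basis: k x (k-1) columns spanning
    the orthogonal complement of the unit vector."""
    A = np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]])
    Q, _ = np.linalg.qr(A)
    C = Q[:, 1:]
    # fix sign for determinism across BLAS implementations
    signs = np.sign(C[np.argmax(np.abs(C), axis=0), np.arange(k - 1)])
    return C * signs


def _rss(Z: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, Z, rcond=None)
    resid = Z - X @ beta
    return float(np.sum(resid * resid))


def _residuals(Z: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Z, rcond=None)
    return Z - X @ beta


def _partial_ss(Z: np.ndarray, X: np.ndarray, cols: Sequence[int]) -> float:
    """Type-III hypothesis SS for the given design columns."""
    keep = [j for j in range(X.shape[1]) if j not in set(cols)]
    return _rss(Z, X[:, keep]) - _rss(Z, X)


def _check_singular(ss_err: float, scale: float, what: str) -> None:
    if ss_err <= 1e-12 * max(scale, 1.0):
        raise ValueError(f"singular design: zero error variance for {what}")


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: str | Sequence[str],
    between: str,
    covariate: str | None = None,
) -> pd.DataFrame:
    """Split-plot ANOVA: one between-subject factor, one or two fully crossed
    within-subject factors, optional between-subject covariate.

    ``data`` is a long table with exactly one row per subject x within-cell.
    Returns one row per effect with sums of squares, F, p, partial
    eta-squared, and (for within effects) Greenhouse-Geisser epsilon with
    corrected dfs/p and Mauchly's test.
    """
    within_factors = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within_factors) <= 2:
        raise ValueError("one or two within factors are supported")

    levels = {f: list(pd.unique(data[f])) for f in within_factors}
    for f in within_factors:
        if len(levels[f]) < 2:
            raise ValueError(f"within factor {f!r} needs >= 2 levels")

    cols_arg = within_factors[0] if len(within_factors) == 1 else within_factors
    wide = data.pivot(index=subject, columns=cols_arg, values=dv)
    if len(within_factors) == 1:
        full_cols = pd.Index(levels[within_factors[0]], name=within_factors[0])
    else:
        full_cols = pd.MultiIndex.from_product(
            [levels[f] for f in within_factors], names=within_factors
        )
    wide = wide.reindex(columns=full_cols)
    if wide.isna().any().any():
        missing = [
            f"subject {idx!r} cell {col!r}"
            for idx, row in wide.iterrows()
            for col, v in row.items() if pd.isna(v)
        ]
        raise ValueError("missing within cells: " + "; ".join(missing[:10]))

    subj_info = data.drop_duplicates(subset=[subject]).set_index(subject)
    if (data.groupby(subject)[between].nunique() > 1).any():
        raise ValueError(f"between factor {between!r} varies within a subject")
    group_labels = subj_info.loc[wide.index, between]
    group_levels = list(pd.unique(group_labels))
    g = len(group_levels)
    if g < 2:
        raise ValueError("need at least 2 between-factor levels")
    counts = group_labels.value_counts()
    if (counts < 2).any():
        raise ValueError("each group needs at least 2 subjects")

    N = wide.shape[0]
    Y = wide.to_numpy(dtype=float)

    # design matrix: intercept | sum-to-zero group contrasts | centered covariate
    Xcols: list[np.ndarray] = [np.ones(N)]
    for lvl in group_levels[:-1]:
        col = np.where(group_labels.to_numpy() == lvl, 1.0, 0.0)
        col[group_labels.to_numpy() == group_levels[-1]] = -1.0
        Xcols.append(col)
    group_cols = list(range(1, g))
    cov_cols: list[int] = []
    if covariate is not None:
        z = subj_info.loc[wide.index, covariate].to_numpy(dtype=float)
        Xcols.append(z - z.mean())
        cov_cols = [len(Xcols) - 1]
    X = np.column_stack(Xcols)
    p = X.shape[1]
    if N <= p:
        raise ValueError("not enough subjects for the design")

    rows: list[dict] = []

    def _row(source, SS, df1, SS_err, df2, eps=np.nan, mauchly=(np.nan, np.nan)):
        MS = SS / df1
        F = MS / (SS_err / df2)
        p_raw = float(stats.f.sf(F, df1, df2))
        if not math.isnan(eps):
            df1_gg, df2_gg = eps * df1, eps * df2
            p_gg = float(stats.f.sf(F, df1_gg, df2_gg))
        else:
            df1_gg = df2_gg = p_gg = np.nan
        rows.append({
            "Source": source, "SS": SS, "df1": df1, "df2": df2, "MS": MS,
            "SS_err": SS_err, "F": F, "p": p_raw,
            "np2": SS / (SS + SS_err),
            "eps": eps, "df1_gg": df1_gg, "df2_gg": df2_gg, "p_gg": p_gg,
            "mauchly_W": mauchly[0], "mauchly_p": mauchly[1],
        })

    # ----- between-subjects stratum (subject means across all cells)
    u = Y.mean(axis=1, keepdims=True)
    ss_err_b = _rss(u, X)
    df_err_b = N - p
    scale = float(np.sum((Y - Y.mean()) ** 2))
    _check_singular(ss_err_b, scale, "the between-subjects test")
    _row(between, _partial_ss(u, X, group_cols), g - 1, ss_err_b, df_err_b)
    if covariate is not None:
        _row(covariate, _partial_ss(u, X, cov_cols), 1, ss_err_b, df_err_b)

    # ----- within-subject strata
    bases = {f: _contrast_basis(len(levels[f])) for f in within_factors}

    def _effect_matrix(active: tuple[str, ...]) -> np.ndarray:
        mats = []
        for f in within_factors:
            k = len(levels[f])
            mats.append(bases[f] if f in active else np.ones((k, 1)) / math.sqrt(k))
        M = mats[0]
        for m in mats[1:]:
            M = np.kron(M, m)
        return M

    effect_sets: list[tuple[str, tuple[str, ...]]] = [
        (f, (f,)) for f in within_factors
    ]
    if len(within_factors) == 2:
        effect_sets.append(
            (" * ".join(within_factors), tuple(within_factors))
        )

    for name, active in effect_sets:
        M = _effect_matrix(active)
        q = M.shape[1]
        Z = Y @ M
        R = _residuals(Z, X)
        ss_err_w = float(np.sum(R * R))
        df_err_w = q * (N - p)
        _check_singular(ss_err_w, scale, f"the within test of {name!r}")
        S_z = (R.T @ R) / (N - p)
        eps = _eps_from_contrast_cov(S_z)
        mau = mauchly_test(S_z, N - p)
        _row(name, _partial_ss(Z, X, [0]), q, ss_err_w, df_err_w,
             eps=eps, mauchly=mau)
        _row(f"{name} * {between}", _partial_ss(Z, X, group_cols),
             q * (g - 1), ss_err_w, df_err_w, eps=eps, mauchly=mau)

    return pd.DataFrame(rows, columns=ANOVA_COLUMNS)


def pairwise_comparisons(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    method: str = "bonferroni",
) -> pd.DataFrame:
    """All level pairs of a within-subject factor, paired t-tests, with
    Bonferroni (raw p times the number of comparisons, capped at 1) or LSD
    (no adjustment) control of the familywise error rate."""
    if method not in ("bonferroni", "lsd"):
        raise ValueError("method must be 'bonferroni' or 'lsd'")
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    levels = list(pd.unique(data[within]))
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        sub = wide[[a, b]].dropna()
        res = paired_t(sub[a].to_numpy(), sub[b].to_numpy())
        p_adj = res.p if method == "lsd" else min(1.0, res.p * m)
        rows.append({
            "level_a": a, "level_b": b,
            "mean_diff": float(sub[a].mean() - sub[b].mean()),
            "t": res.t, "df": res.df, "p_raw": res.p,
            "p_adj": p_adj, "method": method,
        })
    return pd.DataFrame(rows)
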