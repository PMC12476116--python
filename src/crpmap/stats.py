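"""Group statistics, correlation comparisons, and bootstrap mediation.

Covers the clinical-statistics layer of the pipeline: two-sample t-tests
(from raw vectors or printed summary statistics), Pearson chi-square for
2x2 tables (no continuity correction), partial correlation with BH-FDR over
a family, Fisher-z comparison of two independent correlations, and
covariate-adjusted simple mediation (X -> M -> Y) with a percentile
bootstrap confidence interval for the indirect effect a*b.

Mediation model (all paths are unstandardized OLS coefficients, covariates
included in every equation):

    M = i_M + a*X + f'C + e_M
    Y = i_Y + c'*X + b*M + g'C + e_Y
    Y = i_T + c*X + h'C + e_T        (total effect)

On any complete-case sample the OLS identity c = c' + a*b holds exactly.
A significant indirect effect is declared when the bootstrap 95% CI for
a*b excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupCompResult",
    "MediationResult",
    "two_sample_t",
    "two_sample_t_from_stats",
    "chi_square_2x2",
    "partial_correlation",
    "partial_correlation_family",
    "fisher_z_compare",
    "mediate",
]


@dataclass
class GroupCompResult:
    statistic: float
    df: float
    p: float
    kind: str
    summary: dict


@dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    se_a: float
    se_b: float
    n: int
    n_boot: int
    seed: int

    @property
    def significant(self) -> bool:
        return not (self.ci_low <= 0.0 <= self.ci_high)


def two_sample_t(x1, x2, variant: str = "pooled") -> GroupCompResult:
    """Two-sample t-test from raw vectors (pooled or Welch)."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    res = stats.ttest_ind(x1, x2, equal_var=(variant == "pooled"))
    df = res.df
    return GroupCompResult(float(res.statistic), float(df), float(res.pvalue),
                           "t", {"mean1": x1.mean(), "mean2": x2.mean(),
                                 "n1": len(x1), "n2": len(x2)})


def two_sample_t_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                            variant: str = "pooled") -> GroupCompResult:
    """Two-sample t-test from group summaries (as printed in a demographics
    table)."""
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return GroupCompResult(float(res.statistic), float(df), float(res.pvalue),
                           "t", {"mean1": mean1, "mean2": mean2,
                                 "n1": n1, "n2": n2})


def chi_square_2x2(counts) -> GroupCompResult:
    """Pearson chi-square for a 2x2 table, no continuity correction."""
    table = np.asarray(counts, float)
    if table.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return GroupCompResult(float(chi2), float(df), float(p), "chi2",
                           {"table": table.tolist()})


def partial_correlation(x, y, covariates=None):
    """Partial Pearson correlation of x and y given covariates.

    Residualizes both variables on [1, covariates] and correlates the
    residuals; p from the t distribution with df = n - 2 - k.
    Returns (r, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if covariates is None or (hasattr(covariates, "size")
                              and np.size(covariates) == 0):
        k = 0
        rx, ry = x - x.mean(), y - y.mean()
    else:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
        k = C.shape[1]
        Z = np.column_stack([np.ones(n), C])
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        raise ValueError("zero variance after removing covariates")
    r = float(np.clip((rx * ry).sum() / denom, -1, 1))
    df = n - 2 - k
    if df <= 0:
        raise ValueError("not enough observations for partial correlation")
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r ** 2))
    p = 2 * stats.t.sf(abs(t), df)
    return r, float(p)


def partial_correlation_family(df: pd.DataFrame, x: str, ys: list[str],
                               covariates: list[str]) -> pd.DataFrame:
    """Partial correlations of x with each y, BH-FDR over the family.

    Listwise deletion is applied per pair (x, y, covariates), so n may vary
    across rows as clinical variables have different missingness.
    """
    rows = []
    for yname in ys:
        sub = df[[x, yname] + covariates].dropna()
        r, p = partial_correlation(sub[x], sub[yname],
                                   sub[covariates] if covariates else None)
        rows.append({"y": yname, "n": len(sub), "r": r, "p": p})
    out = pd.DataFrame(rows)
    out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int):
    """Compare two independent correlations via the Fisher z transform.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided normal
    p.  Returns (z, p).
    """
    if min(n1, n2) <= 3:
        raise ValueError("need n > 3 in both groups")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def _ols(y: np.ndarray, X: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid ** 2).sum() / dof
    se = np.sqrt(np.diag(np.linalg.inv(X.T @ X)) * sigma2)
    return beta, se


def mediate(x, m, y, covariates=None, n_boot: int = 5000,
            seed: int = 0, ci_level: float = 0.95) -> MediationResult:
    """Simple mediation with percentile-bootstrap CI for the indirect effect.

    x, m, y : 1-D arrays (exposure, mediator, outcome); rows with any NaN
    are dropped listwise.  ``covariates`` (n, k) enter every equation.
    """
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    n0 = len(x)
    C = None
    if covariates is not None and np.size(covariates):
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n0:
            C = C.T
    keep = np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
    if C is not None:
        keep &= np.isfinite(C).all(1)
    x, m, y = x[keep], m[keep], y[keep]
    C = C[keep] if C is not None else None
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 complete cases")
    for name, v in (("x", x), ("m", m), ("y", y)):
        if v.std() == 0:
            raise ValueError(f"zero variance in {name}")

    ones = np.ones(n)
    base = [ones] if C is None else [ones, *C.T]
    Xm = np.column_stack(base + [x])
    Xy = np.column_stack(base + [x, m])
    Xt = np.column_stack(base + [x])

    bm, se_m = _ols(m, Xm)
    by, se_y = _ols(y, Xy)
    bt, _ = _ols(y, Xt)
    a, se_a = bm[-1], se_m[-1]
    c_prime, b = by[-2], by[-1]
    se_b = se_y[-1]
    c = bt[-1]

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    ab = np.empty(n_boot)
    for k in range(n_boot):
        i = idx[k]
        a_k = np.linalg.lstsq(Xm[i], m[i], rcond=None)[0][-1]
        b_k = np.linalg.lstsq(Xy[i], y[i], rcond=None)[0][-1]
        ab[k] = a_k * b_k
    alpha = (1 - ci_level) / 2
    lo, hi = np.quantile(ab, [alpha, 1 - alpha])
    return MediationResult(a=float(a), b=float(b), c=float(c),
                           c_prime=float(c_prime), indirect=float(a * b),
                           ci_low=float(lo), ci_high=float(hi),
                           se_a=float(se_a), se_b=float(se_b),
                           n=n, n_boot=n_boot, seed=seed)
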