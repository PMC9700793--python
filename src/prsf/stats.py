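"""Group-level inference.

- one-way ANCOVA: P-RSF scores compared between two groups (a "tandem")
  with MoCA and IFS as covariates; the group effect is tested with Type II
  sums of squares (full model vs the model without the group factor) and
  its size reported as partial eta squared;
- equal-expected chi-square goodness of fit, the form used to match the two
  reference stories on count variables (words, verbs, sentences, ...);
- exploratory correlations whose method (Pearson vs Spearman) follows a
  Shapiro-Wilk normality gate on each variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AncovaResult:
    F: float
    df_effect: int
    df_error: int
    p: float
    eta_p2: float
    ss_effect: float
    ss_error: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    method: str  # "pearson" | "spearman"
    n: int


def partial_eta_squared(F: float, df_effect: int, df_error: int) -> float:
    """eta_p^2 = F*df1 / (F*df1 + df2), the single-effect identity with the
    sums-of-squares definition SS_effect / (SS_effect + SS_error)."""
    if F < 0 or df_effect <= 0 or df_error <= 0:
        raise ValueError("F must be >= 0 and both dfs positive")
    return F * df_effect / (F * df_effect + df_error)


def _lstsq_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def ancova_one_way(
    y: Sequence[float],
    group: Sequence[str],
    covariates: np.ndarray | Sequence[Sequence[float]] | None,
    covariate_names: Sequence[str] | None = None,
) -> AncovaResult:
    """One-way ANCOVA: y ~ group + covariates, group tested by model comparison.

    Type II sums of squares: SS_group = RSS(intercept + covariates) -
    RSS(intercept + covariates + group); F = (SS_group/df1)/(SS_error/df2)
    with df1 = g-1 and df2 = n - g - c. Constant (zero-variance) covariates
    are dropped, which degrades gracefully to a one-way ANOVA; a rank-
    deficient design after that is an error naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    n = y.size
    if group.size != n:
        raise ValueError("y and group must have equal length")
    levels = sorted(set(group.tolist()))
    g = len(levels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
    if np.isnan(y).any() or np.isnan(C).any():
        raise ValueError("missing values in y or covariates")
    names = list(covariate_names or [f"cov{j}" for j in range(C.shape[1])])
    keep = [j for j in range(C.shape[1]) if np.ptp(C[:, j]) > 0]
    if len(keep) < C.shape[1]:
        dropped = [names[j] for j in range(C.shape[1]) if j not in keep]
        logger.warning("dropping constant covariates %s", dropped)
    C = C[:, keep]
    names = [names[j] for j in keep]
    c = C.shape[1]

    intercept = np.ones((n, 1))
    dummies = np.column_stack(
        [(group == lev).astype(float) for lev in levels[1:]]
    ) if g > 1 else np.empty((n, 0))
    X_full = np.hstack([intercept, C, dummies])
    X_red = np.hstack([intercept, C])

    df_error = n - g - c
    if df_error <= 0:
        raise ValueError(f"not enough observations: n={n}, groups={g}, covariates={c}")
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        # find which columns are redundant
        bad = []
        cols = ["intercept"] + names + [f"group[{lev}]" for lev in levels[1:]]
        for j in range(1, X_full.shape[1]):
            sub = X_full[:, : j + 1]
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                bad.append(cols[j])
        raise ValueError(f"singular design matrix; collinear columns: {bad}")

    rss_full = _lstsq_rss(X_full, y)
    rss_red = _lstsq_rss(X_red, y)
    ss_group = max(rss_red - rss_full, 0.0)
    df_effect = g - 1
    if rss_full <= 0:
        # perfect fit: conventionally infinite F unless the effect is also nil
        F = 0.0 if ss_group == 0 else float("inf")
    else:
        F = (ss_group / df_effect) / (rss_full / df_error)
    p = float(sps.f.sf(F, df_effect, df_error)) if np.isfinite(F) else 0.0
    eta = ss_group / (ss_group + rss_full) if (ss_group + rss_full) > 0 else 0.0
    return AncovaResult(
        F=float(F),
        df_effect=df_effect,
        df_error=df_error,
        p=p,
        eta_p2=float(eta),
        ss_effect=float(ss_group),
        ss_error=float(rss_full),
    )


def chisq_equal_expected(count_a: int, count_b: int) -> tuple[float, float]:
    """Goodness-of-fit chi-square against an equal split of the two counts.

    chi2 = (a-e)^2/e + (b-e)^2/e with e = (a+b)/2, df = 1 — the statistic
    that tests whether two matched texts differ on a count variable.
    """
    if count_a < 0 or count_b < 0 or int(count_a) != count_a or int(count_b) != count_b:
        raise ValueError("counts must be non-negative integers")
    if count_a + count_b == 0:
        raise ValueError("both counts are zero; chi-square undefined")
    chi2, p = sps.chisquare([count_a, count_b])
    return float(chi2), float(p)


def correlate(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> CorrelationResult:
    """Pearson's r if both variables pass Shapiro-Wilk normality at
    ``alpha``, else Spearman's rho; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    normal = (
        sps.shapiro(x).pvalue > alpha and sps.shapiro(y).pvalue > alpha
    )
    if normal:
        res = sps.pearsonr(x, y)
        return CorrelationResult(float(res.statistic), float(res.pvalue), "pearson", x.size)
    res = sps.spearmanr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), "spearman", x.size)
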