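"""Rank-based inference linking dynamics features to severity.

Spearman's rho is computed as the Pearson correlation of average-ranked
data; the two-tailed p-value uses the t approximation with n - 2 degrees of
freedom and the 95% CI uses the Fisher z transform with standard error
1/sqrt(n - 3). The partial Spearman correlation rank-transforms every
variable and then residualizes both focal variables on the controls by least
squares (partial Pearson on ranks), losing one degree of freedom per
control. Mann-Whitney U uses exact enumeration for small untied samples and
otherwise a tie- and continuity-corrected normal approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

_TINY_P = 5e-324  # smallest positive float; keeps reported p in (0, 1]


@dataclass(frozen=True)
class AssociationResult:
    coefficient: float
    n: int
    df: int
    p_two_tailed: float
    ci_low: float
    ci_high: float
    controlled: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class GroupComparison:
    u_statistic: float
    n1: int
    n2: int
    p_two_tailed: float


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _t_pvalue(r: float, df: int) -> float:
    if df <= 0:
        return math.nan
    if abs(r) >= 1.0:
        return _TINY_P
    t = abs(r) * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(t, df)
    return float(min(1.0, max(p, _TINY_P)))


def _fisher_ci(r: float, n: int, k: int = 0, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z CI; one further df lost per control variable."""
    if n - 3 - k <= 0:
        return (math.nan, math.nan)
    r_c = min(1.0 - 1e-15, max(-1.0 + 1e-15, r))
    z = math.atanh(r_c)
    se = 1.0 / math.sqrt(n - 3 - k)
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    return (math.tanh(z - zcrit * se), math.tanh(z + zcrit * se))


def spearman(x, y, alpha: float = 0.05) -> AssociationResult:
    """Spearman rank correlation with t-approximation p and Fisher-z CI.

    Ties receive average ranks. Zero rank variance in either variable makes
    the coefficient undefined (NaN result, reported as missing).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 4:
        raise ValueError("spearman requires at least 4 paired observations")
    rx, ry = _rank(x), _rank(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return AssociationResult(math.nan, n, n - 2, math.nan, math.nan, math.nan)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    ci_low, ci_high = _fisher_ci(rho, n, k=0, alpha=alpha)
    return AssociationResult(
        coefficient=rho, n=n, df=n - 2, p_two_tailed=_t_pvalue(rho, n - 2),
        ci_low=ci_low, ci_high=ci_high,
    )


def partial_spearman(x, y, controls, control_names: Sequence[str] | None = None,
                     alpha: float = 0.05) -> AssociationResult:
    """Partial Spearman correlation of x and y given one or more controls.

    Every variable is rank-transformed (average ranks); x and y ranks are
    then residualized on the control ranks (with intercept) by least squares
    and the Pearson correlation of the residuals is returned, with
    df = n - 2 - (number of controls). With an empty control set this equals
    :func:`spearman` exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.atleast_2d(np.asarray(controls, dtype=float))
    if Z.size == 0:
        Z = np.empty((x.size, 0))
    elif Z.shape[0] != x.size:
        Z = Z.T
    if Z.shape[0] != x.size:
        raise ValueError("controls must have the same number of observations as x")
    k = Z.shape[1]
    if control_names is None:
        control_names = tuple(f"control_{i}" for i in range(k))
    n = x.size
    if n < 5 + k:
        raise ValueError(f"partial spearman with {k} controls requires n >= {5 + k}")
    rx, ry = _rank(x), _rank(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return AssociationResult(math.nan, n, n - 2 - k, math.nan, math.nan, math.nan,
                                 tuple(control_names))
    design = np.column_stack([np.ones(n), *(_rank(Z[:, j]) for j in range(k))])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "collinear controls (rank-deficient design): " + ", ".join(control_names)
        )
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    # controls explaining a focal variable exactly leave no association
    if np.std(ex) <= 1e-10 * np.std(rx) or np.std(ey) <= 1e-10 * np.std(ry):
        return AssociationResult(0.0, n, n - 2 - k, 1.0, math.nan, math.nan,
                                 tuple(control_names))
    r = float(np.corrcoef(ex, ey)[0, 1])
    ci_low, ci_high = _fisher_ci(r, n, k=k, alpha=alpha)
    return AssociationResult(
        coefficient=r, n=n, df=n - 2 - k, p_two_tailed=_t_pvalue(r, n - 2 - k),
        ci_low=ci_low, ci_high=ci_high, controlled=tuple(control_names),
    )


def _exact_mwu_p(ranks: np.ndarray, n1: int) -> float:
    """Two-tailed exact p by full enumeration of rank assignments (no ties)."""
    n = ranks.size
    all_idx = range(n)
    mu = n1 * (n - n1) / 2.0
    u_obs = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    dev_obs = abs(u_obs - mu)
    count = 0
    total = 0
    rank_values = np.sort(ranks)
    for combo in combinations(all_idx, n1):
        u = float(np.sum(rank_values[list(combo)]) - n1 * (n1 + 1) / 2.0)
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
    return count / total


def mann_whitney_u(a, b) -> GroupComparison:
    """Mann-Whitney U test for two independent samples.

    U is reported for the first sample (U1 = R1 - n1(n1+1)/2). The two-tailed
    p is exact (full enumeration) when n1 + n2 <= 12 with no ties, else a
    normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _rank(pooled)
    u1 = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))
    if n1 + n2 <= 12 and not has_ties:
        p = _exact_mwu_p(ranks, n1)
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
            p = float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
    return GroupComparison(u_statistic=u1, n1=n1, n2=n2, p_two_tailed=max(p, _TINY_P))


def association_table(
    features: pd.DataFrame,
    feature_list: Sequence[str],
    control_sets: Sequence[Sequence[str]] = ((),),
    severity_col: str = "severity",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Severity-feature correlations, one row per (feature, control set).

    Participants with a missing value in any variable of a given row are
    dropped pairwise for that row only; each row reports its own n.
    """
    rows = []
    for feature in feature_list:
        for controls in control_sets:
            controls = tuple(controls)
            cols = list(dict.fromkeys([feature, severity_col, *controls]))
            sub = features[cols].dropna()
            n = len(sub)
            row = {"feature": feature, "controls": "+".join(controls), "n": n}
            try:
                if controls:
                    res = partial_spearman(
                        sub[feature], sub[severity_col],
                        sub[list(controls)].to_numpy(),
                        control_names=controls, alpha=alpha,
                    )
                else:
                    res = spearman(sub[feature], sub[severity_col], alpha=alpha)
                row.update(
                    coefficient=res.coefficient, ci_low=res.ci_low,
                    ci_high=res.ci_high, df=res.df, p=res.p_two_tailed,
                )
            except ValueError as exc:
                row.update(coefficient=math.nan, ci_low=math.nan, ci_high=math.nan,
                           df=math.nan, p=math.nan, note=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)
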