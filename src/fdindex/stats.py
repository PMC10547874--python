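"""Rank-based group statistics for subject-level FDI values.

Implements the study-style statistical layer: Quade's rank ANCOVA for the
group comparison (controlling for age, sex and education), Spearman
correlations with Bonferroni correction between FDI and clinical scores,
Mann-Whitney U and chi-squared tests for demographics, and ROC/AUC
evaluation of FDI as a classifier feature with the fixed orientation "low
FDI predicts the patient class".
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io import CohortTable

__all__ = [
    "QuadeResult",
    "CorrelationResult",
    "RocResult",
    "quade_ancova",
    "spearman_bonferroni",
    "mann_whitney_u",
    "chi_squared",
    "roc_auc",
    "bonferroni",
]

#: Numeric coding of the ordinal covariates for rank regression.
EDUCATION_CODES = {"Primary": 1, "Secondary": 2, "High": 3}
SEX_CODES = {"M": 0, "F": 1}


@dataclasses.dataclass
class QuadeResult:
    """Quade rank-ANCOVA F test for a group difference in one region."""

    f_stat: float
    df: tuple[int, int]
    p_raw: float
    p_adj: float
    region: str = ""
    degenerate: bool = False


@dataclasses.dataclass
class CorrelationResult:
    """One Spearman correlation between an FDI region and a clinical score."""

    fdi_variable: str
    score_variable: str
    rho: float
    p_raw: float
    p_adj: float
    n: int
    method: str  # "exact" or "asymptotic"
    usable: bool = True


@dataclasses.dataclass
class RocResult:
    """ROC sweep of FDI cutoffs with the patient class at low FDI."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    orientation: str = "low FDI predicts SCZ"


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``min(1, m * p)``; ``m`` defaults to the family size."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


def quade_ancova(
    values: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    n_comparisons: int = 1,
    region: str = "",
) -> QuadeResult:
    """Quade's rank analysis of covariance.

    The response and every covariate are ranked across all subjects
    (average ranks for ties), the response ranks are regressed on the
    covariate ranks by ordinary least squares, and the residuals are
    compared between groups with a one-way ANOVA F test on
    ``(g - 1, n - g - c)`` degrees of freedom, where ``c`` is the effective
    (matrix-rank) number of covariates.  With no or constant covariates the
    residuals are the centred response ranks and the test reduces to a
    one-way ANOVA on ranks.
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n = y.size
    labels, g_idx = np.unique(groups, return_inverse=True)
    g = labels.size
    if g < 2:
        raise ValueError("need at least 2 groups")
    if np.min(np.bincount(g_idx)) < 3:
        raise ValueError("need at least 3 subjects per group")
    if np.all(y == y[0]):
        return QuadeResult(
            f_stat=0.0,
            df=(g - 1, n - g),
            p_raw=1.0,
            p_adj=1.0,
            region=region,
            degenerate=True,
        )
    ry = sps.rankdata(y)
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        rcov = np.apply_along_axis(sps.rankdata, 0, cov)
        rcov_c = rcov - rcov.mean(axis=0)
        c_eff = int(np.linalg.matrix_rank(rcov_c))
        design = np.column_stack([np.ones(n), rcov_c])
        beta, *_ = np.linalg.lstsq(design, ry, rcond=None)
        resid = ry - design @ beta
    else:
        c_eff = 0
        resid = ry - ry.mean()
    ss_total = float(resid @ resid)
    group_means = np.array([resid[g_idx == k].mean() for k in range(g)])
    counts = np.bincount(g_idx)
    ss_between = float(counts @ group_means**2)
    ss_within = ss_total - ss_between
    df1 = g - 1
    df2 = n - g - c_eff
    if df2 <= 0:
        raise ValueError("not enough subjects for the covariate count")
    if ss_within <= 0:
        f = math.inf
        p = 0.0
    else:
        f = (ss_between / df1) / (ss_within / df2)
        p = float(sps.f.sf(f, df1, df2))
    return QuadeResult(
        f_stat=float(f),
        df=(df1, df2),
        p_raw=p,
        p_adj=float(bonferroni(p, n_comparisons)[0]),
        region=region,
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p value for Spearman's rho (n <= 9)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    obs = abs(float(rx_c @ ry_c) / denom)
    n = len(x)
    perms = np.array(list(itertools.permutations(range(n))))
    rho_all = (ry_c[perms] @ rx_c) / denom
    return float(np.mean(np.abs(rho_all) >= obs - 1e-12))


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Spearman rho with an exact permutation p for n <= 9, t approx above."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho, p = sps.spearmanr(x, y)
    if len(x) <= 9:
        return float(rho), _exact_spearman_p(x, y), "exact"
    return float(rho), float(p), "asymptotic"


def spearman_bonferroni(
    cohort: CohortTable | pd.DataFrame,
    fdi_columns: list[str],
    score_columns: list[str],
    group: str | None = None,
) -> list[CorrelationResult]:
    """Spearman correlations for every (FDI, score) pair, Bonferroni-adjusted.

    The family size is the number of pairs actually tested.  Pairs with
    fewer than 4 complete observations are flagged unusable (rho and p are
    NaN) but still count toward the family, since they were tested.
    ``group`` restricts the rows (e.g. ``"SCZ"`` for PANSS correlations,
    which only patients have).
    """
    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    if group is not None:
        df = df[df["group"] == group]
    m = len(fdi_columns) * len(score_columns)
    results = []
    for fcol in fdi_columns:
        for scol in score_columns:
            sub = df[[fcol, scol]].dropna()
            if len(sub) < 4:
                results.append(
                    CorrelationResult(
                        fdi_variable=fcol,
                        score_variable=scol,
                        rho=float("nan"),
                        p_raw=float("nan"),
                        p_adj=float("nan"),
                        n=len(sub),
                        method="none",
                        usable=False,
                    )
                )
                continue
            rho, p, method = spearman(sub[fcol].to_numpy(), sub[scol].to_numpy())
            results.append(
                CorrelationResult(
                    fdi_variable=fcol,
                    score_variable=scol,
                    rho=rho,
                    p_raw=p,
                    p_adj=float(bonferroni(p, m)[0]),
                    n=len(sub),
                    method=method,
                )
            )
    return results


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U for the first sample with a two-sided p value.

    ``U`` counts the pairs where ``x > y`` plus half the ties.  The p value
    is exact (full enumeration) when ``n1 * n2 <= 400`` and the data are
    tie-free, and the tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_squared(table) -> tuple[float, float]:
    """Pearson chi-squared on an r x c contingency table (no continuity correction)."""
    res = sps.chi2_contingency(np.asarray(table), correction=False)
    return float(res.statistic), float(res.pvalue)


def roc_auc(fdi_values, groups) -> RocResult:
    """ROC analysis of FDI with patients predicted at low FDI.

    The score is ``-FDI`` with SCZ as the positive class, so the sweep
    enforces the orientation "FDI(SCZ) <= FDI(HC)".  The trapezoidal AUC is
    cross-checked against the Mann-Whitney identity
    ``AUC = U / (n1 * n2)`` with ``U`` counting (SCZ < HC) pairs plus half
    the ties.
    """
    fdi = np.asarray(fdi_values, dtype=float)
    groups = np.asarray(groups)
    is_scz = groups == "SCZ"
    if not is_scz.any() or is_scz.all():
        raise ValueError("both groups must be non-empty")
    scz = fdi[is_scz]
    hc = fdi[~is_scz]
    fpr, tpr, thr = _sk_roc_curve(is_scz.astype(int), -fdi)
    area = float(_sk_auc(fpr, tpr))
    u = float(
        (scz[:, None] < hc[None, :]).sum() + 0.5 * (scz[:, None] == hc[None, :]).sum()
    )
    u_auc = u / (len(scz) * len(hc))
    assert abs(area - u_auc) < 1e-9, "AUC / Mann-Whitney identity violated"
    return RocResult(thresholds=-thr, tpr=tpr, fpr=fpr, auc=area)
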