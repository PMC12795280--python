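"""Confounder-aware association screening.

Implements the screening layer between lifestyle exposures and omics
features: partial Spearman correlation (rank, residualise, correlate),
Cliff's delta with a consistent-variance normal CI, Benjamini-Hochberg FDR,
Type-III ANOVA with estimated marginal means and Tukey pairwise contrasts,
and a strict drug-deconfounding status machine in the spirit of post hoc
confounder filtering: a feature's exposure association survives only if the
exposure adds explanatory power on top of medication/clinical covariates
(likelihood-ratio test) and its effect-size CI excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "partial_spearman",
    "cliffs_delta",
    "cliffs_delta_ci",
    "bh_fdr",
    "deconfound",
    "anova_marginal_means",
    "MarginalMeansResult",
]


def _design(covariates: pd.DataFrame | None, index: pd.Index) -> np.ndarray:
    """Intercept + one-hot-coded covariate design matrix."""
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((len(index), 1))
    cov = covariates.loc[index]
    num = cov.select_dtypes(include=[np.number])
    cat = cov.drop(columns=num.columns)
    parts = [np.ones((len(index), 1)), num.to_numpy(dtype=float)]
    if cat.shape[1]:
        dummies = pd.get_dummies(cat.astype(str), drop_first=True)
        parts.append(dummies.to_numpy(dtype=float))
    return np.column_stack(parts)


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_spearman(
    x: pd.Series,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Partial Spearman correlation of ``x`` and ``y`` given covariates.

    Both variables are rank-transformed (average ranks), residualised on
    the covariates by OLS (categoricals one-hot coded), and the Pearson
    correlation of the residuals is returned with a t-test p-value on
    ``n - n_cov - 2`` degrees of freedom. With no covariates this reduces
    to the ordinary Spearman correlation.
    """
    df = pd.DataFrame({"x": x, "y": y}).dropna()
    n = len(df)
    X = _design(covariates, df.index)
    k = X.shape[1] - 1
    if n <= k + 2:
        raise ValueError("need n > #covariates + 2")
    rx = stats.rankdata(df["x"], method="average")
    ry = stats.rankdata(df["y"], method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("constant variable after ranking; correlation undefined")
        return (float("nan"), float("nan"))
    ex = _residualize(rx.astype(float), X)
    ey = _residualize(ry.astype(float), X)
    rho = float(np.dot(ex, ey) / np.sqrt(np.dot(ex, ex) * np.dot(ey, ey)))
    dof = n - k - 2
    rho_c = min(max(rho, -0.9999999999), 0.9999999999)
    t = rho_c * np.sqrt(dof / (1.0 - rho_c**2))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return rho, p


def cliffs_delta(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Cliff's delta: P(a > b) - P(a < b), positive when a stochastically
    dominates b.  Computed from joint ranks, O((n+m) log(n+m))."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ranks = stats.rankdata(np.concatenate([a, b]), method="average")
    ra = ranks[: a.size].sum()
    # Mann-Whitney U for group a, ties handled by midranks
    u_a = ra - a.size * (a.size + 1) / 2.0
    return float(2.0 * u_a / (a.size * b.size) - 1.0)


def cliffs_delta_ci(
    group_a: np.ndarray, group_b: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Cliff's delta with a consistent-variance normal-approximation CI.

    Returns ``(delta, lo, hi)``. The variance estimate combines the
    within-row, within-column and overall dominance variances (Cliff 1993).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    dom = np.sign(a[:, None] - b[None, :])
    delta = float(dom.mean())
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        return delta, -1.0, 1.0
    di = dom.mean(axis=1)
    dj = dom.mean(axis=0)
    s2 = (
        nb**2 * np.sum((di - delta) ** 2)
        + na**2 * np.sum((dj - delta) ** 2)
        - np.sum((dom - delta) ** 2)
    ) / (na * nb * (na - 1) * (nb - 1))
    s2 = max(s2, 0.0)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(s2)
    return delta, max(delta - half, -1.0), min(delta + half, 1.0)


def bh_fdr(p: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up q-values; NA p-values propagate."""
    arr = np.asarray(p, dtype=float)
    q = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    if ((arr[ok] < 0) | (arr[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        q[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(q, index=p.index, name="q")
    return q


# ---------------------------------------------------------------------------
# drug deconfounding
# ---------------------------------------------------------------------------

def _lrt_pvalue(y: np.ndarray, X0: np.ndarray, X1: np.ndarray) -> float:
    """LRT p-value for nested Gaussian OLS models (X0 nested in X1)."""
    n = len(y)
    r0 = _residualize(y, X0)
    r1 = _residualize(y, X1)
    rss0 = float(r0 @ r0)
    rss1 = float(r1 @ r1)
    if rss1 <= 0:
        return 0.0
    lr = n * np.log(rss0 / rss1)
    df = np.linalg.matrix_rank(X1) - np.linalg.matrix_rank(X0)
    if df <= 0:
        return 1.0
    return float(stats.chi2.sf(lr, df))


def deconfound(
    features: pd.DataFrame,
    exposure: pd.Series,
    covariates: pd.DataFrame,
    random_group: pd.Series | None = None,
    contrast: tuple[str, str] | None = None,
    fdr: float = 0.1,
    prevalence: float = 0.2,
    lrt_alpha: float = 0.05,
) -> pd.DataFrame:
    """Strict deconfounding of feature-exposure associations.

    ``exposure`` is a two-level contrast (e.g. high vs low QASD); rows with
    other labels are ignored. Features present in fewer than ``prevalence``
    of the samples are excluded. Stage 1 is a naive rank-sum test per
    feature with BH-FDR; stage 2 refits the rank-transformed feature on
    covariates (+ recruitment-center dummies) with and without the exposure
    and keeps the association only if the exposure adds explanatory power
    (LRT p < ``lrt_alpha``) and the Cliff's delta CI excludes zero.

    Status per feature: ``NS`` (naive test not significant), ``OK_nc``
    (significant, no covariate associated with the feature), ``OK_sd``
    (significant and strictly deconfounded), ``confounded`` otherwise.
    The contrast's first sorted level is treated as the reference "high"
    group for the sign of Cliff's delta, i.e. delta > 0 means higher values
    in the group passed as ``levels[0]``.
    """
    levels = sorted(pd.Series(exposure).dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"exposure must have exactly 2 levels, got {levels}")
    if contrast is not None:
        if sorted(contrast) != levels:
            raise ValueError(f"contrast {contrast} does not match {levels}")
        hi_level, lo_level = contrast
    else:
        hi_level, lo_level = levels  # first sorted level is the reference
    mask = exposure.isin(levels)
    feats = features.loc[features.index.intersection(exposure.index[mask])]
    expo = exposure.loc[feats.index]
    cov = covariates.loc[feats.index].copy()
    drop = [c for c in cov.columns if cov[c].nunique(dropna=True) < 2]
    if drop:
        warnings.warn(f"single-level covariates dropped: {drop}")
        cov = cov.drop(columns=drop)
    if random_group is not None:
        cov = cov.assign(_center=random_group.loc[feats.index].astype(str))

    prev = (feats > 0).mean(axis=0)
    kept = feats.columns[prev >= prevalence]
    x_hi = (expo == hi_level).to_numpy()  # contrast's "high" group
    records = []
    for name in kept:
        y = feats[name].to_numpy(dtype=float)
        a, b = y[x_hi], y[~x_hi]
        try:
            stat_p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        except ValueError:
            stat_p = 1.0
        delta, lo, hi = cliffs_delta_ci(a, b)
        records.append((name, float(stat_p), delta, lo, hi))
    table = pd.DataFrame(
        records, columns=["feature", "naive_p", "cliffs_delta", "ci_lo", "ci_hi"]
    ).set_index("feature")
    if table.empty:
        table["naive_q"] = []
        table["lrt_p"] = []
        table["status"] = []
        return table
    table["naive_q"] = bh_fdr(table["naive_p"])

    X0 = _design(cov, feats.index)
    x_num = x_hi.astype(float)
    X1 = np.column_stack([X0, x_num])
    lrt_p = np.full(len(table), np.nan)
    status = []
    for i, name in enumerate(table.index):
        y = feats[name].to_numpy(dtype=float)
        yr = stats.rankdata(y, method="average").astype(float)
        if table.loc[name, "naive_q"] >= fdr:
            status.append("NS")
            continue
        # is any covariate associated with this feature at all?
        cov_assoc = _lrt_pvalue(yr, np.ones((len(yr), 1)), X0) < lrt_alpha \
            if X0.shape[1] > 1 else False
        p1 = _lrt_pvalue(yr, X0, X1)
        lrt_p[i] = p1
        ci_excl0 = (table.loc[name, "ci_lo"] > 0) or (table.loc[name, "ci_hi"] < 0)
        if not cov_assoc:
            status.append("OK_nc")
        elif p1 < lrt_alpha and ci_excl0:
            status.append("OK_sd")
        else:
            status.append("confounded")
    table["lrt_p"] = lrt_p
    table["status"] = status
    table.attrs["contrast"] = f"{hi_level}-vs-{lo_level}"
    return table


# ---------------------------------------------------------------------------
# ANOVA with estimated marginal means
# ---------------------------------------------------------------------------

@dataclass
class MarginalMeansResult:
    """Type-III ANOVA of a factor plus covariate-adjusted level means."""

    f_value: float
    p_value: float
    means: pd.DataFrame       # level, mean, se, ci_lo, ci_hi
    tukey: pd.DataFrame       # level_a, level_b, diff, p_adj
    df_resid: int


def anova_marginal_means(
    y: pd.Series,
    factor: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> MarginalMeansResult:
    """Type-III F-test of ``factor`` in an OLS adjusting for covariates,
    with estimated marginal means (covariates held at their means) and
    Tukey-adjusted pairwise level contrasts."""
    import statsmodels.api as sm

    df = pd.DataFrame({"y": y, "f": factor.astype(str)}).dropna()
    levels = sorted(df["f"].unique())
    if len(levels) < 2:
        raise ValueError("factor needs >= 2 levels")
    Xcov = _design(covariates, df.index)
    # sum-to-zero coding for the factor so the Type-III test is sensible
    k = len(levels)
    F = np.zeros((len(df), k - 1))
    codes = pd.Categorical(df["f"], categories=levels).codes
    for j in range(k - 1):
        F[codes == j, j] = 1.0
        F[codes == k - 1, j] = -1.0
    X = np.column_stack([Xcov, F])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (aliased factor/covariates)")
    model = sm.OLS(df["y"].to_numpy(dtype=float), X).fit()
    ncov = Xcov.shape[1]
    R = np.zeros((k - 1, X.shape[1]))
    R[:, ncov:] = np.eye(k - 1)
    ftest = model.f_test(R)
    fval, pval = float(ftest.fvalue), float(ftest.pvalue)

    covm = Xcov.mean(axis=0)
    rows = []
    vecs = {}
    for j, lev in enumerate(levels):
        fx = np.zeros(k - 1)
        if j < k - 1:
            fx[j] = 1.0
        else:
            fx[:] = -1.0
        vec = np.concatenate([covm, fx])
        vecs[lev] = vec
        mean = float(vec @ model.params)
        se = float(np.sqrt(vec @ model.cov_params() @ vec))
        tcrit = stats.t.ppf(0.975, model.df_resid)
        rows.append((lev, mean, se, mean - tcrit * se, mean + tcrit * se))
    means = pd.DataFrame(
        rows, columns=["level", "mean", "se", "ci_lo", "ci_hi"]
    ).set_index("level")

    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            cvec = vecs[levels[i]] - vecs[levels[j]]
            diff = float(cvec @ model.params)
            se = float(np.sqrt(cvec @ model.cov_params() @ cvec))
            q = abs(diff) / se * np.sqrt(2.0)
            p_adj = float(stats.studentized_range.sf(q, k, model.df_resid))
            pairs.append((levels[i], levels[j], diff, p_adj))
    tukey = pd.DataFrame(pairs, columns=["level_a", "level_b", "diff", "p_adj"])
    return MarginalMeansResult(
        f_value=fval, p_value=pval, means=means, tukey=tukey,
        df_resid=int(model.df_resid),
    )
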