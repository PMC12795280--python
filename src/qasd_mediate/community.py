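"""Distance-matrix community analyses.

Bray-Curtis dissimilarity, principal coordinate analysis, sequential-term
PERMANOVA, a PERMANOVA-based mediation construction (joint significance of
the exposure->composition and composition->outcome|exposure terms),
distance-based redundancy analysis (univariate effect sizes, stepwise
forward selection with permutation stopping), environmental fitting of
covariates onto ordination axes, and the collinearity pre-filter for
candidate covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .association import _design

__all__ = [
    "bray_curtis",
    "OrdinationResult",
    "pcoa",
    "permanova",
    "permanova_mediation",
    "dbrda_univariate",
    "forward_select",
    "envfit",
    "redundancy_filter",
]


def bray_curtis(abundances: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity, ``sum|x_i - x_j| / sum(x_i + x_j)``."""
    A = abundances.to_numpy(dtype=float)
    if (A < 0).any():
        raise ValueError("abundances must be nonnegative")
    zero = A.sum(axis=1) == 0
    if zero.any():
        raise ValueError(
            f"all-zero abundance rows: {list(abundances.index[zero])[:5]}"
        )
    D = squareform(pdist(A, metric="braycurtis"))
    return pd.DataFrame(D, index=abundances.index, columns=abundances.index)


def _check_distance(d: pd.DataFrame) -> np.ndarray:
    D = np.asarray(d, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal must be zero")
    return D


@dataclass
class OrdinationResult:
    """Principal coordinates plus the eigenvalue spectrum."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray            # positive, descending
    relative_eigenvalues: np.ndarray   # fractions of positive inertia
    negative_eigenvalues: np.ndarray   # dropped axes, reported for diagnostics


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = len(A)
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def pcoa(d: pd.DataFrame, eps: float = 1e-10) -> OrdinationResult:
    """Classical principal coordinate analysis (metric MDS).

    Gower-centers ``-D^2/2`` and eigendecomposes; axes with negative
    eigenvalues (non-Euclidean distances) are dropped and reported.
    """
    D = _check_distance(d)
    G = _gower_center(D)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > eps * max(abs(vals[0]), 1.0)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    idx = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(len(D))
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=idx,
            columns=[f"PCo{i + 1}" for i in range(int(pos.sum()))],
        ),
        eigenvalues=vals[pos],
        relative_eigenvalues=vals[pos] / vals[pos].sum(),
        negative_eigenvalues=vals[vals < -eps * max(abs(vals[0]), 1.0)],
    )


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def _sequential_ss(G: np.ndarray, designs: list[np.ndarray]) -> np.ndarray:
    """Sequential (Type-I) sums of squares of distance inertia for nested
    design blocks, McArdle-Anderson style: SS(term) = tr(H_k G) - tr(H_{k-1} G)."""
    ss = []
    prev = 0.0
    for X in designs:
        cur = float(np.trace(_hat(X) @ G))
        ss.append(cur - prev)
        prev = cur
    return np.array(ss)


def _term_matrix(values: pd.Series) -> np.ndarray:
    v = pd.Series(values)
    if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype) \
            or v.dtype == bool:
        if v.nunique() < 2:
            raise ValueError(f"term {v.name!r} has a single level")
        return pd.get_dummies(v.astype(str), drop_first=True).to_numpy(float)
    if v.nunique() < 2:
        raise ValueError(f"term {v.name!r} is constant")
    return v.to_numpy(dtype=float).reshape(-1, 1)


def permanova(
    d: pd.DataFrame,
    design: pd.DataFrame,
    permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sequential-term PERMANOVA on a distance matrix.

    Terms enter in column order; pseudo-F per term uses the residual mean
    square of the full model. P-values come from free permutation of
    sample identities, recomputing the full sequential decomposition.
    Returns one row per term plus a residual row, with ``R2`` summing to 1.
    """
    D = _check_distance(d)
    n = len(D)
    if n < 5:
        raise ValueError("need >= 5 samples")
    G = _gower_center(D)
    terms = list(design.columns)
    blocks = [_term_matrix(design[t]) for t in terms]

    def decompose(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        designs = []
        X = np.ones((n, 1))
        for B in blocks:
            X = np.column_stack([X, B])
            designs.append(X.copy())
        ss_terms = _sequential_ss(Gm, designs)
        total = float(np.trace(Gm))
        ss_res = total - ss_terms.sum()
        return ss_terms, ss_res

    df_terms = np.array([
        np.linalg.matrix_rank(B) for B in blocks
    ])
    df_res = n - 1 - df_terms.sum()
    ss_terms, ss_res = decompose(G)
    ms_res = ss_res / df_res
    f_obs = (ss_terms / df_terms) / ms_res

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(permutations):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        ss_p, ss_rp = decompose(Gp)
        f_p = (ss_p / df_terms) / (ss_rp / df_res)
        exceed += f_p >= f_obs
    pvals = (1.0 + exceed) / (1.0 + permutations)

    total = float(np.trace(G))
    out = pd.DataFrame({
        "df": np.append(df_terms, df_res),
        "SS": np.append(ss_terms, ss_res),
        "F": np.append(f_obs, np.nan),
        "p": np.append(pvals, np.nan),
        "R2": np.append(ss_terms, ss_res) / total,
    }, index=terms + ["residual"])
    return out


def permanova_mediation(
    d: pd.DataFrame,
    exposure: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    permutations: int = 999,
    seed: int | None = None,
    n_axes: int = 10,
) -> dict:
    """PERMANOVA-based mediation of community composition.

    Joint-significance construction: component 1 tests whether the exposure
    shifts composition (sequential PERMANOVA F of the exposure term, after
    covariates); component 2 tests whether composition predicts the outcome
    conditional on the exposure (F of the leading ordination axes entering
    after exposure and covariates in an OLS on the outcome, permutation p
    by Freedman-Lane residual permutation). The mediation p-value is the
    maximum of the two component p-values.
    """
    rng = np.random.default_rng(seed)
    idx = exposure.dropna().index.intersection(outcome.dropna().index)
    if isinstance(d, pd.DataFrame):
        d = d.loc[idx, idx]
    design = pd.DataFrame(index=idx)
    if covariates is not None:
        design = covariates.loc[idx].copy()
    design["_exposure"] = exposure.loc[idx]
    res1 = permanova(d, design, permutations=permutations,
                     seed=int(rng.integers(2**31)))
    f1 = float(res1.loc["_exposure", "F"])
    p1 = float(res1.loc["_exposure", "p"])

    ord_res = pcoa(d)
    k = min(n_axes, ord_res.coordinates.shape[1])
    axes = ord_res.coordinates.iloc[:, :k].to_numpy()
    y = outcome.loc[idx].to_numpy(dtype=float)
    Xr = _design(covariates.loc[idx] if covariates is not None else None, idx)
    Xr = np.column_stack([
        Xr, _term_matrix(exposure.loc[idx].rename("_exposure"))
    ])
    Xf = np.column_stack([Xr, axes])

    def f_axes(yv: np.ndarray) -> float:
        rss_r = float(yv @ yv - yv @ _hat(Xr) @ yv)
        rss_f = float(yv @ yv - yv @ _hat(Xf) @ yv)
        df1 = k
        df2 = len(yv) - np.linalg.matrix_rank(Xf)
        if rss_f <= 0:
            return np.inf
        return ((rss_r - rss_f) / df1) / (rss_f / df2)

    f2 = f_axes(y)
    # Freedman-Lane: permute reduced-model residuals
    Hr = _hat(Xr)
    fitted = Hr @ y
    resid = y - fitted
    exceed = 0
    for _ in range(permutations):
        y_star = fitted + resid[rng.permutation(len(y))]
        if f_axes(y_star) >= f2:
            exceed += 1
    p2 = (1.0 + exceed) / (1.0 + permutations)
    return {
        "f_exposure_composition": f1,
        "p_exposure_composition": p1,
        "f_composition_outcome": f2,
        "p_composition_outcome": p2,
        "mediation_p": max(p1, p2),
    }


def _dbrda_r2(Y: np.ndarray, X: np.ndarray) -> float:
    """Fraction of positive ordination inertia explained by predictors."""
    H = _hat(X)
    return float(np.trace(Y.T @ H @ Y) / np.trace(Y.T @ Y))


def _ezekiel(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def dbrda_univariate(
    d: pd.DataFrame,
    covariate: pd.Series,
    permutations: int = 999,
    seed: int | None = None,
) -> dict:
    """Single-covariate distance-based redundancy analysis.

    PCoA coordinates on the positive axes are regressed on the covariate;
    R² is the constrained share of positive inertia, adjusted with the
    Ezekiel formula; the p-value permutes the covariate.
    """
    cov = pd.Series(covariate)
    if cov.nunique(dropna=True) < 2:
        raise ValueError("constant covariate")
    ord_res = pcoa(d)
    Y = ord_res.coordinates.to_numpy()
    n = len(Y)
    X = np.column_stack([np.ones(n), _term_matrix(cov)])
    p_pred = X.shape[1] - 1
    r2 = _dbrda_r2(Y, X)
    rng = np.random.default_rng(seed)
    exceed = 0
    xcol = X[:, 1:]
    for _ in range(permutations):
        Xp = np.column_stack([np.ones(n), xcol[rng.permutation(n)]])
        if _dbrda_r2(Y, Xp) >= r2:
            exceed += 1
    return {
        "r2": r2,
        "adj_r2": _ezekiel(r2, n, p_pred),
        "p": (1.0 + exceed) / (1.0 + permutations),
    }


def forward_select(
    d: pd.DataFrame,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Stepwise forward dbRDA model selection by permutation.

    Greedily adds the candidate with the largest adjusted-R² gain whose
    partial contribution is permutation-significant at ``alpha``; stops
    when no candidate qualifies. Returns the selection path with
    cumulative adjusted R².
    """
    ord_res = pcoa(d)
    Y = ord_res.coordinates.to_numpy()
    n = len(Y)
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    path = []
    remaining = list(candidates.columns)

    def model_adj_r2(cols: list[str]) -> float:
        if not cols:
            return 0.0
        X = np.column_stack(
            [np.ones(n)] + [_term_matrix(candidates[c]) for c in cols])
        return _ezekiel(_dbrda_r2(Y, X), n, X.shape[1] - 1)

    current = 0.0
    while remaining:
        gains = {}
        for c in remaining:
            try:
                gains[c] = model_adj_r2(selected + [c]) - current
            except ValueError:
                continue
        if not gains:
            break
        best = max(gains, key=gains.get)
        if gains[best] <= 0:
            break
        # permutation test of the partial contribution of `best`
        obs = gains[best]
        col = candidates[best]
        exceed = 0
        for _ in range(permutations):
            perm = col.iloc[rng.permutation(n)].reset_index(drop=True)
            perm.index = candidates.index
            tmp = candidates.assign(**{best: perm})
            X = np.column_stack(
                [np.ones(n)]
                + [_term_matrix(tmp[c]) for c in selected + [best]])
            g = _ezekiel(_dbrda_r2(Y, X), n, X.shape[1] - 1) - current
            if g >= obs:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + permutations)
        if p >= alpha:
            break
        selected.append(best)
        remaining.remove(best)
        current += obs
        path.append((best, obs, current, p))
    return pd.DataFrame(
        path, columns=["variable", "adj_r2_gain", "cum_adj_r2", "p"]
    )


def envfit(
    ordination: OrdinationResult,
    covariate: pd.Series,
    k: int = 2,
    permutations: int = 999,
    seed: int | None = None,
) -> dict:
    """Fit a covariate onto the first ``k`` ordination axes.

    OLS of the covariate on the axes; the arrow is the unit coefficient
    vector scaled by sqrt(R²); significance by permuting the covariate.
    """
    if k < 2:
        raise ValueError("need k >= 2 axes")
    cov = pd.Series(covariate).astype(float)
    if cov.nunique(dropna=True) < 2:
        raise ValueError("constant covariate")
    A = ordination.coordinates.iloc[:, :k].to_numpy()
    y = cov.to_numpy()
    X = np.column_stack([np.ones(len(A)), A])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(((y - fitted) ** 2).sum()) / ss_tot
    coef = beta[1:]
    norm = np.linalg.norm(coef)
    arrow = (coef / norm) * np.sqrt(max(r2, 0.0)) if norm > 0 else coef
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        yp = y[rng.permutation(len(y))]
        bp, *_ = np.linalg.lstsq(X, yp, rcond=None)
        r2p = 1.0 - float(((yp - X @ bp) ** 2).sum()) / ss_tot
        if r2p >= r2:
            exceed += 1
    return {
        "arrow": arrow,
        "r2": r2,
        "p": (1.0 + exceed) / (1.0 + permutations),
    }


def redundancy_filter(
    covariates: pd.DataFrame, threshold: float = 0.9
) -> list[str]:
    """Drop collinear covariates by pairwise Spearman correlation.

    While any pair exceeds ``|rho| > threshold``, the member with the
    larger mean absolute correlation to the remaining variables is removed.
    Returns the retained column names in original order.
    """
    if covariates.shape[1] == 0:
        raise ValueError("need at least one covariate")
    cols = list(covariates.columns)
    corr = covariates[cols].corr(method="spearman").abs()
    while True:
        sub = corr.loc[cols, cols].copy()
        np.fill_diagonal(sub.values, 0.0)
        i, j = np.unravel_index(np.argmax(sub.to_numpy()), sub.shape)
        if sub.iloc[i, j] <= threshold:
            break
        a, b = sub.index[i], sub.columns[j]
        drop = a if sub.loc[a].mean() >= sub.loc[b].mean() else b
        cols.remove(drop)
        if len(cols) == 1:
            break
    return [c for c in covariates.columns if c in cols]
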