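"""Linear causal mediation and bidirectional enumeration over feature pairs.

The core is the classic two-regression decomposition for a binary exposure
X, mediator M and outcome Y with covariates C:

    M = a·X + gamma'·C + e_m
    Y = c'·X + b·M + delta'·C + e_y

giving the average causal mediation effect ACME = a·b, the average direct
effect ADE = c', and total = ACME + ADE (an identity in the linear,
no-interaction case). Uncertainty comes from quasi-Bayesian simulation:
coefficients are drawn from the asymptotic normal sampling distributions of
the two fitted regressions and the effect products recomputed per draw;
percentile intervals and sign-based two-sided p-values are reported. The
proportion mediated is the point ratio ACME/total.

:class:`LinearMediation` / :class:`MediationResults` follow the
model-object convention: build the model from data, call ``fit``, read the
estimates off the results object (or print ``summary()``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import _design, bh_fdr

__all__ = [
    "LinearMediation",
    "MediationResults",
    "mediate_linear",
    "prefilter_pairs",
    "enumerate_bidirectional",
    "mediate_scalar_clinical",
    "filter_by_phenotype",
    "impact_tier",
]


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and their covariance matrix."""
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - np.linalg.matrix_rank(X)
    sigma2 = float(resid @ resid) / dof
    return beta, sigma2 * XtX_inv


class LinearMediation:
    """Linear mediation model for a binary exposure.

    Parameters
    ----------
    outcome, mediator : array-like
        The outcome Y and candidate mediator M.
    exposure : array-like
        Binary exposure X coded 1 for the treated/"healthier" level.
    covariates : DataFrame, optional
        Adjustment variables entering both component regressions
        (categoricals one-hot coded).
    """

    def __init__(self, outcome, mediator, exposure, covariates=None,
                 names: tuple[str, str, str] = ("y", "m", "x")):
        df = pd.DataFrame({
            "y": np.asarray(outcome, dtype=float),
            "m": np.asarray(mediator, dtype=float),
            "x": np.asarray(exposure, dtype=float),
        })
        if covariates is not None:
            covariates = pd.DataFrame(covariates).reset_index(drop=True)
        self._df = df
        keep = df.notna().all(axis=1)
        if covariates is not None:
            keep &= covariates.notna().all(axis=1)
        df = df[keep].reset_index(drop=True)
        if covariates is not None:
            covariates = covariates[keep.to_numpy()].reset_index(drop=True)
        levels = np.unique(df["x"])
        if len(levels) != 2:
            raise ValueError("exposure must take exactly two values")
        if np.allclose(df["m"], df["y"]):
            raise ValueError("mediator and outcome are identical series")
        self.names = names
        self.covariates = covariates
        X = _design(covariates, df.index)
        if len(df) <= X.shape[1] + 3:
            raise ValueError("too few observations for the adjustment set")
        x01 = (df["x"].to_numpy() == levels.max()).astype(float)
        self._x = x01
        self._m = df["m"].to_numpy()
        self._y = df["y"].to_numpy()
        self._C = X  # includes intercept
        self.nobs = len(df)

    def fit(self, draws: int = 1000, seed: int | None = None,
            method: Literal["quasi-bayesian", "bootstrap"] = "quasi-bayesian",
            ) -> "MediationResults":
        """Fit both component regressions and simulate effect uncertainty."""
        rng = np.random.default_rng(seed)
        Xm = np.column_stack([self._C, self._x])
        Xy = np.column_stack([self._C, self._x, self._m])
        beta_m, cov_m = _ols(self._m, Xm)
        beta_y, cov_y = _ols(self._y, Xy)
        a = beta_m[-1]
        c_prime = beta_y[-2]
        b = beta_y[-1]

        if method == "quasi-bayesian":
            draws_m = rng.multivariate_normal(beta_m, cov_m, size=draws,
                                              method="cholesky")
            draws_y = rng.multivariate_normal(beta_y, cov_y, size=draws,
                                              method="cholesky")
            a_s = draws_m[:, -1]
            c_s = draws_y[:, -2]
            b_s = draws_y[:, -1]
        elif method == "bootstrap":
            n = self.nobs
            a_s = np.empty(draws)
            b_s = np.empty(draws)
            c_s = np.empty(draws)
            for i in range(draws):
                idx = rng.integers(0, n, n)
                bm, _ = _ols(self._m[idx], Xm[idx])
                by, _ = _ols(self._y[idx], Xy[idx])
                a_s[i], c_s[i], b_s[i] = bm[-1], by[-2], by[-1]
        else:
            raise ValueError(f"unknown method {method!r}")

        sims = np.column_stack([a_s * b_s, c_s, a_s * b_s + c_s])
        point = np.array([a * b, c_prime, a * b + c_prime])
        ci = np.percentile(sims, [2.5, 97.5], axis=0).T
        p = np.array([
            min(1.0, 2.0 * min((s <= 0).mean(), (s >= 0).mean()))
            for s in sims.T
        ])
        return MediationResults(
            model=self, acme=point[0], ade=point[1], total=point[2],
            conf_int_arr=ci, pvalues_arr=p, draws=draws, method=method,
            coef_a=a, coef_b=b, coef_c_prime=c_prime, sims=sims,
        )


@dataclass
class MediationResults:
    """Estimates, simulation intervals and p-values from a fitted
    :class:`LinearMediation`."""

    model: LinearMediation
    acme: float
    ade: float
    total: float
    conf_int_arr: np.ndarray    # rows: acme, ade, total
    pvalues_arr: np.ndarray
    draws: int
    method: str
    coef_a: float
    coef_b: float
    coef_c_prime: float
    sims: np.ndarray = field(repr=False)

    @property
    def prop_mediated(self) -> float:
        """Point-estimate ratio ACME/total (can fall outside [0, 1] when
        the direct and indirect paths oppose)."""
        return self.acme / self.total if self.total != 0 else np.nan

    @property
    def total_significant(self) -> bool:
        lo, hi = self.conf_int_arr[2]
        return lo > 0 or hi < 0

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.conf_int_arr, index=["acme", "ade", "total"],
            columns=["ci_lo", "ci_hi"],
        )

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(self.pvalues_arr, index=["acme", "ade", "total"])

    @property
    def estimates(self) -> pd.Series:
        return pd.Series([self.acme, self.ade, self.total],
                         index=["acme", "ade", "total"])

    def summary(self) -> str:
        ci = self.conf_int_arr
        lines = [
            "Linear mediation (binary exposure)",
            f"n = {self.model.nobs}, {self.method}, {self.draws} draws",
            f"{'effect':<8}{'estimate':>10}{'2.5%':>10}{'97.5%':>10}{'p':>10}",
        ]
        for i, name in enumerate(["ACME", "ADE", "total"]):
            lines.append(
                f"{name:<8}{self.estimates.iloc[i]:>10.4f}"
                f"{ci[i, 0]:>10.4f}{ci[i, 1]:>10.4f}"
                f"{self.pvalues_arr[i]:>10.4g}"
            )
        pm = self.prop_mediated
        note = "" if self.total_significant else " (total CI includes 0)"
        lines.append(f"prop. mediated = {pm:.4f}{note}")
        return "\n".join(lines)


def impact_tier(prop_mediated: float) -> str:
    """Tier a mediation by the share of the total effect it carries:
    high > 20%, medium 10-20%, low < 10% (clipped to [0, 1] for tiering)."""
    p = min(max(prop_mediated, 0.0), 1.0)
    if p > 0.20:
        return "high"
    if p >= 0.10:
        return "medium"
    return "low"


def mediate_linear(
    x, m, y, covariates=None, draws: int = 1000, seed: int | None = None,
) -> MediationResults:
    """Convenience wrapper: build and fit a :class:`LinearMediation`."""
    return LinearMediation(y, m, x, covariates=covariates).fit(
        draws=draws, seed=seed
    )


# ---------------------------------------------------------------------------
# pipeline operations over feature panels
# ---------------------------------------------------------------------------

def prefilter_pairs(
    mgs: pd.DataFrame,
    metabolites: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Pairwise MGS-metabolite association screen.

    Each metabolite is regressed on each (rank-normal-transformed upstream)
    MGS with covariate adjustment; the slope test is computed via partial
    correlation of the covariate residuals. BH-FDR is applied across all
    pairs; only pairs with q < ``fdr`` are returned.
    """
    common = mgs.index.intersection(metabolites.index)
    A = mgs.loc[common].to_numpy(dtype=float)
    B = metabolites.loc[common].to_numpy(dtype=float)
    X = _design(covariates, common)
    k = X.shape[1] - 1
    n = len(common)
    Ra = A - X @ np.linalg.lstsq(X, A, rcond=None)[0]
    Rb = B - X @ np.linalg.lstsq(X, B, rcond=None)[0]
    sa = np.sqrt((Ra**2).sum(axis=0))
    sb = np.sqrt((Rb**2).sum(axis=0))
    sa[sa == 0] = np.nan
    sb[sb == 0] = np.nan
    corr = (Ra.T @ Rb) / np.outer(sa, sb)
    beta = (Ra.T @ Rb) / (sa**2)[:, None]
    dof = n - k - 2
    r = np.clip(corr, -0.9999999999, 0.9999999999)
    tstat = r * np.sqrt(dof / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    rows = pd.MultiIndex.from_product(
        [mgs.columns, metabolites.columns], names=["mediator", "outcome"]
    )
    table = pd.DataFrame({
        "beta": beta.ravel(), "p": p.ravel(),
    }, index=rows)
    table["q"] = bh_fdr(table["p"])
    return table[table["q"] < fdr]


def _run_both_directions(x, m_vec, y_vec, covariates, draws, rng):
    res = {}
    res[1] = LinearMediation(y_vec, m_vec, x, covariates).fit(
        draws=draws, seed=int(rng.integers(2**31)))
    res[2] = LinearMediation(m_vec, y_vec, x, covariates).fit(
        draws=draws, seed=int(rng.integers(2**31)))
    return res


def enumerate_bidirectional(
    pairs: pd.DataFrame,
    mgs: pd.DataFrame,
    metabolites: pd.DataFrame,
    qasd_group: pd.Series,
    covariates: pd.DataFrame | None = None,
    contrasts: Sequence[tuple[str, str]] = (("high", "low"),
                                            ("high", "medium"),
                                            ("medium", "low")),
    draws: int = 1000,
    seed: int | None = None,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Bidirectional mediation over prefiltered MGS-metabolite pairs.

    Direction 1 treats the MGS as mediator and the metabolite as outcome;
    direction 2 swaps the roles. BH-FDR runs separately per
    (direction, contrast, effect-type) family; a mediation is significant
    when all three effects pass ``fdr``. Each significant (pair, contrast)
    is classified shared (significant in both directions) or
    direction-specific, and tiered by its mediated proportion.
    Returns the result table plus a direction summary dictionary.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for hi, lo in contrasts:
        mask = qasd_group.isin([hi, lo])
        if qasd_group.eq(hi).sum() == 0 or qasd_group.eq(lo).sum() == 0:
            warnings.warn(f"contrast {hi}-vs-{lo} has an empty level; skipped")
            continue
        idx = qasd_group.index[mask]
        idx = idx.intersection(mgs.index).intersection(metabolites.index)
        x = (qasd_group.loc[idx] == hi).astype(float)
        cov = covariates.loc[idx] if covariates is not None else None
        for med_id, out_id in pairs.index:
            both = _run_both_directions(
                x.to_numpy(),
                mgs.loc[idx, med_id].to_numpy(),
                metabolites.loc[idx, out_id].to_numpy(),
                cov, draws, rng,
            )
            for direction, res in both.items():
                rows.append({
                    "contrast": f"{hi}-vs-{lo}",
                    "mgs": med_id, "metabolite": out_id,
                    "direction": direction,
                    "acme": res.acme, "ade": res.ade, "total": res.total,
                    "acme_p": res.pvalues_arr[0],
                    "ade_p": res.pvalues_arr[1],
                    "total_p": res.pvalues_arr[2],
                    "prop_mediated": res.prop_mediated,
                })
    table = pd.DataFrame(rows)
    if table.empty:
        return table, {"significant": 0, "shared": 0,
                       "direction_specific": {1: 0, 2: 0}, "tiers": {}}
    for eff in ("acme", "ade", "total"):
        table[f"{eff}_q"] = np.nan
        for (_, _), sub in table.groupby(["direction", "contrast"]):
            table.loc[sub.index, f"{eff}_q"] = bh_fdr(sub[f"{eff}_p"])
    table["significant"] = (
        (table["acme_q"] < fdr) & (table["ade_q"] < fdr)
        & (table["total_q"] < fdr)
    )
    table["tier"] = table["prop_mediated"].map(impact_tier)

    key = ["contrast", "mgs", "metabolite"]
    sig = table[table["significant"]]
    per_dir = {
        d: set(map(tuple, sig[sig["direction"] == d][key].to_numpy()))
        for d in (1, 2)
    }
    shared = per_dir[1] & per_dir[2]
    table["specificity"] = "ns"
    is_sig = table["significant"].to_numpy()
    keys = list(map(tuple, table[key].to_numpy()))
    spec = []
    for i, k in enumerate(keys):
        if not is_sig[i]:
            spec.append("ns")
        elif k in shared:
            spec.append("shared")
        else:
            spec.append("specific")
    table["specificity"] = spec
    tier_counts = (
        sig.groupby(["direction", "tier"]).size().to_dict() if len(sig) else {}
    )
    summary = {
        "significant": int(table["significant"].sum()),
        "shared": len(shared),
        "direction_specific": {
            d: len(per_dir[d] - shared) for d in (1, 2)
        },
        "tiers": {f"dir{d}_{t}": int(c) for (d, t), c in tier_counts.items()},
    }
    return table, summary


def mediate_scalar_clinical(
    qasd_group: pd.Series,
    gmgr: pd.Series,
    clinical: pd.Series,
    covariates: pd.DataFrame | None = None,
    contrast: tuple[str, str] = ("high", "low"),
    draws: int = 1000,
    seed: int | None = None,
) -> dict[int, MediationResults]:
    """Bidirectional mediation between QASD, gene richness and one clinical
    variable.

    Direction 1: QASD -> clinical (mediator) -> GMGR (outcome).
    Direction 2: QASD -> GMGR (mediator) -> clinical (outcome).
    """
    hi, lo = contrast
    mask = qasd_group.isin([hi, lo])
    idx = qasd_group.index[mask]
    idx = idx.intersection(gmgr.dropna().index).intersection(
        clinical.dropna().index)
    x = (qasd_group.loc[idx] == hi).astype(float).to_numpy()
    cov = covariates.loc[idx] if covariates is not None else None
    rng = np.random.default_rng(seed)
    g = gmgr.loc[idx].to_numpy()
    c = clinical.loc[idx].to_numpy()
    return {
        1: LinearMediation(g, c, x, cov).fit(
            draws=draws, seed=int(rng.integers(2**31))),
        2: LinearMediation(c, g, x, cov).fit(
            draws=draws, seed=int(rng.integers(2**31))),
    }


def filter_by_phenotype(
    results: pd.DataFrame,
    mgs: pd.DataFrame,
    metabolites: pd.DataFrame,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Keep mediation results whose MGS *and* metabolite are each associated
    with the phenotype (e.g. HOMA-IR) at FDR < ``fdr`` under the same
    adjustment framework."""
    if results.empty:
        return results
    idx = phenotype.dropna().index.intersection(mgs.index).intersection(
        metabolites.index)
    ph = phenotype.loc[idx].to_frame("ph")
    mgs_hits = prefilter_pairs(
        mgs.loc[idx], ph, covariates.loc[idx] if covariates is not None
        else None, fdr=fdr)
    met_hits = prefilter_pairs(
        metabolites.loc[idx], ph, covariates.loc[idx] if covariates is not None
        else None, fdr=fdr)
    ok_mgs = {m for m, _ in mgs_hits.index}
    ok_met = {m for m, _ in met_hits.index}
    keep = results["mgs"].isin(ok_mgs) & results["metabolite"].isin(ok_met)
    return results[keep]
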