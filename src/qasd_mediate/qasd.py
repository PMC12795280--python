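"""The QASD composite lifestyle score.

QASD sums tertile points for diet Quality (AHEI), physical Activity
(MET-h/week) and dietary Diversity (Simpson index of the diet without
beverages) — 0/1/2 points each — plus a binary Smoking point (1 for
non-smokers and former smokers, 0 for current smokers). The total ranges
0-7 and is additionally reported in a five-level grouping
("0-1-2", "3", "4", "5", "6-7") and a three-level grouping
("low" = 0-3, "medium" = 4, "high" = 5-7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TertileAssignment",
    "assign_tertiles",
    "recode_smoking",
    "build_qasd",
    "GROUP5_LABELS",
    "GROUP3_LABELS",
]

GROUP5_LABELS = ("0-1-2", "3", "4", "5", "6-7")
GROUP3_LABELS = ("low", "medium", "high")


@dataclass
class TertileAssignment:
    """Tertile cut points and per-participant labels for one variable."""

    variable: str
    cuts: tuple[float, float]
    tertile: pd.Series  # values in {"low","medium","high"} or NA
    points: pd.Series   # 0/1/2 or NA

    def __post_init__(self) -> None:
        if not self.cuts[0] <= self.cuts[1]:
            raise ValueError("tertile cut points must be ordered")


def _nearest_rank_cuts(values: np.ndarray) -> tuple[float, float]:
    # nearest-rank (inverted CDF) empirical 1/3 and 2/3 percentiles,
    # computed with integer arithmetic to dodge 2/3 rounding issues
    s = np.sort(values)
    n = len(s)
    k1 = -(-n // 3)       # ceil(n/3)
    k2 = -(-2 * n // 3)   # ceil(2n/3)
    return float(s[k1 - 1]), float(s[k2 - 1])


def assign_tertiles(
    values: pd.Series,
    variable: str | None = None,
    cuts: tuple[float, float] | None = None,
) -> TertileAssignment:
    """Split a variable into cohort tertiles worth 0/1/2 points.

    Cut points default to the nearest-rank empirical 33.33/66.67
    percentiles of the non-missing values; values tied with a cut point go
    to the lower tertile. External (reference-cohort) cut points may be
    supplied via ``cuts``, e.g. to calibrate score categories against a
    reference population. NA values stay NA.
    """
    v = pd.Series(values).astype(float)
    ok = v.notna()
    if cuts is None:
        if ok.sum() < 3:
            raise ValueError("need >= 3 non-missing values for tertiles")
        if v[ok].nunique() < 3:
            raise ValueError("need >= 3 distinct values; tertiles undefined")
        cuts = _nearest_rank_cuts(v[ok].to_numpy())
    pts = pd.Series(np.nan, index=v.index, dtype=float)
    pts[ok & (v <= cuts[0])] = 0
    pts[ok & (v > cuts[0]) & (v <= cuts[1])] = 1
    pts[ok & (v > cuts[1])] = 2
    labels = pts.map({0: "low", 1: "medium", 2: "high"})
    return TertileAssignment(
        variable=variable or (values.name or "value"),
        cuts=cuts, tertile=labels, points=pts,
    )


_SMOKING_POINTS = {
    "non-smoker": 1,
    "former": 1,
    # passive smokers are not active smokers under the binary
    # non-smoker/smoker recoding; configurable via the mapping argument
    "passive": 1,
    "current": 0,
}


def recode_smoking(
    status: pd.Series,
    points: dict[str, int] | None = None,
) -> pd.Series:
    """Binary smoking point: 0 for current smokers, 1 otherwise."""
    mapping = _SMOKING_POINTS if points is None else points
    s = pd.Series(status)
    unknown = set(s.dropna().unique()) - set(mapping)
    if unknown:
        raise ValueError(f"unknown smoking categories: {sorted(unknown)}")
    return s.map(mapping).astype(float)


def _group5(total: float) -> str:
    if total <= 2:
        return "0-1-2"
    if total >= 6:
        return "6-7"
    return str(int(total))


def _group3(total: float) -> str:
    if total <= 3:
        return "low"
    if total == 4:
        return "medium"
    return "high"


def build_qasd(
    ahei: pd.Series,
    diversity: pd.Series,
    activity_met: pd.Series,
    smoking: pd.Series,
    cuts: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Build the QASD profile table from its four components.

    Parameters
    ----------
    ahei, diversity, activity_met : Series
        Continuous components: AHEI diet quality, Simpson diversity of the
        diet without beverages, and total physical activity in MET-h/week.
        Each is converted to cohort tertile points (0/1/2).
    smoking : Series
        Smoking status categories (see :func:`recode_smoking`).
    cuts : dict, optional
        External cut points per component name
        ("quality", "diversity", "activity").

    Returns
    -------
    DataFrame with the component points, ``total`` (0-7), ``group5`` and
    ``group3`` labels, plus a ``cuts`` attribute in ``.attrs``. Any missing
    component makes the total NA.
    """
    cuts = cuts or {}
    comp = {}
    used_cuts = {}
    for name, vec in (
        ("quality", ahei), ("diversity", diversity), ("activity", activity_met)
    ):
        ta = assign_tertiles(vec, variable=name, cuts=cuts.get(name))
        comp[f"{name}_pts"] = ta.points
        used_cuts[name] = ta.cuts
    comp["smoking_pts"] = recode_smoking(smoking)
    out = pd.DataFrame(comp)
    out["total"] = out[["quality_pts", "diversity_pts",
                        "activity_pts", "smoking_pts"]].sum(axis=1, skipna=False)
    ok = out["total"].notna()
    out["group5"] = pd.Series(pd.NA, index=out.index, dtype="object")
    out["group3"] = pd.Series(pd.NA, index=out.index, dtype="object")
    out.loc[ok, "group5"] = out.loc[ok, "total"].map(_group5)
    out.loc[ok, "group3"] = out.loc[ok, "total"].map(_group3)
    out.attrs["cuts"] = used_cuts
    return out
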