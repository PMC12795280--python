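"""Dietary diversity, variety, quality and inflammatory-potential scoring.

Scores operate on a participant x food-item intake table (g/day) together
with a two-level item taxonomy (42 fine food groups refining 22 original
groups, with beverage/liquid flags). Implemented families:

* count-based diversity/variety — number of groups (or items) consumed;
* evenness-based (Berry/Simpson) diversity — ``1 - sum(p_i**2)`` over the
  intake shares of the groups in scope;
* healthy food diversity (HFD) — Simpson index times a health-value-weighted
  share sum, health values supplied by configuration;
* a normalised 0-100 composite combining group- and item-count scores;
* config-driven AHEI-style (0-10 linear) and DASH-style (quintile 1-5)
  component scorers;
* the energy-residual inflammatory index (aDII);
* Harris-Benedict basal metabolic rate and misreporter flagging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FoodIntakeTable",
    "ScoreSpec",
    "ComponentRule",
    "simpson_diversity",
    "count_score",
    "score_battery",
    "adii",
    "component_score",
    "diet_quality_index",
    "harris_benedict_bmr",
    "flag_misreporters",
]


@dataclass
class FoodIntakeTable:
    """Participant x item intake in g/day plus the item taxonomy.

    ``taxonomy`` is indexed by item with columns ``group42``, ``group22``,
    ``is_beverage`` and ``is_liquid``; every intake column must be mapped
    and the fine grouping must refine the coarse one.
    """

    grams: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.grams.columns) - set(self.taxonomy.index)
        if missing:
            raise ValueError(f"items missing from taxonomy: {sorted(missing)}")
        needed = {"group42", "group22", "is_beverage", "is_liquid"}
        if not needed <= set(self.taxonomy.columns):
            raise ValueError(f"taxonomy needs columns {sorted(needed)}")
        neg = self.grams.lt(0)
        if neg.to_numpy().any():
            r, c = np.argwhere(neg.to_numpy())[0]
            raise ValueError(
                "negative intake at participant "
                f"{self.grams.index[r]!r}, item {self.grams.columns[c]!r}"
            )
        # group42 must refine group22: each fine group maps to one coarse group
        n_parents = self.taxonomy.groupby("group42")["group22"].nunique()
        bad = n_parents[n_parents > 1]
        if len(bad):
            raise ValueError(
                f"group42 does not refine group22 for {list(bad.index)}"
            )

    @property
    def participants(self) -> pd.Index:
        return self.grams.index

    def items_in_scope(
        self,
        scope: str = "all",
        exclude: Literal["none", "beverages", "liquids"] = "none",
    ) -> pd.Index:
        """Items belonging to ``scope`` ('all' or a group42/group22 name)
        after dropping beverage (or, stricter, all liquid) items."""
        tax = self.taxonomy.loc[self.grams.columns]
        keep = pd.Series(True, index=tax.index)
        if scope != "all":
            keep &= (tax["group42"] == scope) | (tax["group22"] == scope)
            if not keep.any():
                raise KeyError(f"unknown food group {scope!r}")
        if exclude == "beverages":
            keep &= ~tax["is_beverage"].astype(bool)
        elif exclude == "liquids":
            keep &= ~(tax["is_beverage"].astype(bool)
                      | tax["is_liquid"].astype(bool))
        elif exclude != "none":
            raise ValueError(f"unknown exclusion {exclude!r}")
        return tax.index[keep]

    def group_totals(self, items: pd.Index) -> pd.DataFrame:
        """Participant x group42 total grams over the given items."""
        groups = self.taxonomy.loc[items, "group42"]
        return self.grams[items].T.groupby(groups).sum().T


def simpson_diversity(grams_in_scope: np.ndarray | pd.Series) -> float:
    """Berry/Simpson diversity ``1 - sum(p_i**2)`` of intake shares.

    ``grams_in_scope`` holds the per-group (or per-item) gram totals of one
    participant. Zero total intake is defined as minimal diversity (0.0),
    with a warning.
    """
    g = np.asarray(grams_in_scope, dtype=float)
    if g.ndim != 1 or g.size < 1:
        raise ValueError("expected a 1-d vector with at least one group")
    if (g < 0).any():
        raise ValueError("negative intake")
    total = g.sum()
    if total == 0:
        warnings.warn("zero total intake in scope; Simpson diversity set to 0")
        return 0.0
    p = g / total
    return float(1.0 - np.sum(p**2))


def count_score(grams_in_scope: np.ndarray | pd.Series) -> int:
    """Number of units (groups or items) with positive consumption."""
    g = np.asarray(grams_in_scope, dtype=float)
    if g.size < 1:
        raise ValueError("empty scope")
    if (g < 0).any():
        raise ValueError("negative intake")
    return int(np.count_nonzero(g > 0))


@dataclass(frozen=True)
class ScoreSpec:
    """Specification of one diversity/variety score column.

    ``kind='diversity'`` aggregates items to food groups before scoring;
    ``kind='variety'`` scores at the item level. ``estimator`` selects the
    count or Simpson form; ``scope`` is 'all' or a food-group name;
    ``exclude`` optionally drops beverages or all liquid foods.
    """

    name: str
    kind: Literal["diversity", "variety"] = "diversity"
    estimator: Literal["count", "simpson"] = "simpson"
    scope: str = "all"
    exclude: Literal["none", "beverages", "liquids"] = "none"


#: The score battery mirroring the published score families: total-diet
#: diversity and variety in count and Simpson forms, with and without
#: beverages/liquids.
DEFAULT_SCORE_SPECS: tuple[ScoreSpec, ...] = (
    ScoreSpec("diversity_count_all", "diversity", "count", "all", "none"),
    ScoreSpec("diversity_simpson_all", "diversity", "simpson", "all", "none"),
    ScoreSpec("diversity_count_no_beverages",
              "diversity", "count", "all", "beverages"),
    ScoreSpec("diversity_simpson_no_beverages",
              "diversity", "simpson", "all", "beverages"),
    ScoreSpec("diversity_simpson_no_liquids",
              "diversity", "simpson", "all", "liquids"),
    ScoreSpec("variety_count_all", "variety", "count", "all", "none"),
    ScoreSpec("variety_simpson_all", "variety", "simpson", "all", "none"),
)


def _score_one(spec: ScoreSpec, intake: FoodIntakeTable) -> pd.Series:
    items = intake.items_in_scope(spec.scope, spec.exclude)
    if spec.kind == "diversity":
        table = intake.group_totals(items)
    else:
        table = intake.grams[items]
    fn = simpson_diversity if spec.estimator == "simpson" else count_score
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vals = table.apply(lambda row: fn(row.to_numpy()), axis=1)
    if (table.sum(axis=1) == 0).any() and spec.estimator == "simpson":
        warnings.warn(
            f"score {spec.name!r}: participants with zero intake in scope "
            "scored 0 (minimal diversity)"
        )
    return vals.astype(float)


def score_battery(
    intake: FoodIntakeTable,
    specs: Sequence[ScoreSpec] = DEFAULT_SCORE_SPECS,
    hfd_health_values: Mapping[str, float] | None = None,
    composite: bool = True,
) -> pd.DataFrame:
    """Compute a battery of diversity/variety scores, one column per spec.

    When ``hfd_health_values`` (group42 -> health value in [0, 1]) is given,
    a healthy-food-diversity column ``hfd`` is added: Simpson (Berry) index
    of the full diet times the health-value-weighted share sum. With
    ``composite=True`` a 0-100 column combining the normalised group-count
    and item-count scores with equal weight is added.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate score spec names")
    out = pd.DataFrame(
        {s.name: _score_one(s, intake) for s in specs},
        index=intake.participants,
    )
    if hfd_health_values is not None:
        items = intake.items_in_scope("all", "none")
        groups = intake.group_totals(items)
        hv = pd.Series(hfd_health_values).reindex(groups.columns)
        if hv.isna().any():
            raise KeyError(
                f"health values missing for {list(hv.index[hv.isna()])}"
            )
        shares = groups.div(groups.sum(axis=1).replace(0, np.nan), axis=0)
        berry = 1.0 - (shares**2).sum(axis=1)
        out["hfd"] = (berry * (shares @ hv)).fillna(0.0)
    if composite:
        items = intake.items_in_scope("all", "none")
        groups = intake.group_totals(items)
        n_groups = groups.shape[1]
        n_items = len(items)
        gcount = groups.gt(0).sum(axis=1)
        icount = intake.grams[items].gt(0).sum(axis=1)
        out["composite_0_100"] = (
            50.0 * gcount / n_groups + 50.0 * icount / n_items
        )
    return out


def adii(
    intake: FoodIntakeTable,
    energy_kcal: pd.Series,
    weights: Mapping[str, float],
    misreporter: pd.Series | None = None,
) -> pd.Series:
    """Energy-residual inflammatory diet index.

    Per weighted item: regress intake on total energy across the cohort
    (Willett residual method), z-standardise the residuals, multiply by the
    literature pro/anti-inflammatory weight and sum over items. Higher
    values indicate a more pro-inflammatory diet. The residual regression
    and standardisation are fitted on non-misreporters only; flagged
    participants receive NA.
    """
    w = pd.Series(weights, dtype=float)
    if w.index.duplicated().any():
        raise ValueError("duplicate items in weight table")
    missing = set(w.index) - set(intake.grams.columns)
    if missing:
        raise KeyError(f"weighted items absent from intake: {sorted(missing)}")
    energy = energy_kcal.reindex(intake.participants).astype(float)
    if (energy <= 0).any():
        raise ValueError("energy must be positive for every participant")
    keep = pd.Series(True, index=intake.participants)
    if misreporter is not None:
        keep &= ~misreporter.reindex(intake.participants).fillna(False)
    if keep.sum() < 3:
        raise ValueError("need >= 3 non-misreporting participants")
    e = energy[keep].to_numpy()
    if np.ptp(e) == 0:
        raise ValueError("constant energy vector; residual method degenerate")
    X = np.column_stack([np.ones_like(e), e])
    Y = intake.grams.loc[keep, w.index].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sd = resid.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0  # constant-residual item contributes 0 everywhere
    z = (resid - resid.mean(axis=0)) / sd
    score = pd.Series(np.nan, index=intake.participants, name="adii")
    score[keep] = z @ w.to_numpy()
    return score


@dataclass(frozen=True)
class ComponentRule:
    """One diet-quality component.

    ``scoring='linear'`` interpolates from ``min_value`` (0 points) to
    ``max_value`` (10 points) AHEI-style; ``scoring='quintile'`` assigns the
    cohort consumption quintile 1-5 DASH-style. ``direction='adverse'``
    reverses the scale so lower consumption scores higher.
    """

    name: str
    variable: str
    direction: Literal["beneficial", "adverse"] = "beneficial"
    scoring: Literal["linear", "quintile"] = "linear"
    min_value: float = 0.0
    max_value: float = 1.0
    sex_max_value: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.scoring == "linear" and self.min_value == self.max_value:
            raise ValueError(f"component {self.name!r}: min == max")


def component_score(
    values: pd.Series,
    rule: ComponentRule,
    sex: pd.Series | None = None,
) -> pd.Series:
    """Score one component for every participant (0-10 linear or 1-5 quintile)."""
    v = values.astype(float)
    if rule.scoring == "linear":
        hi = pd.Series(rule.max_value, index=v.index, dtype=float)
        if rule.sex_max_value is not None:
            if sex is None:
                raise ValueError(f"{rule.name!r} needs a sex vector")
            hi = sex.map(rule.sex_max_value).astype(float)
        pts = 10.0 * (v - rule.min_value) / (hi - rule.min_value)
        pts = pts.clip(0.0, 10.0)
        if rule.direction == "adverse":
            pts = 10.0 - pts
        return pts
    # quintile scoring
    if v.nunique(dropna=True) == 1:
        warnings.warn(
            f"component {rule.name!r}: all values identical; "
            "quintile ranks degenerate"
        )
    ranks = v.rank(method="average", na_option="keep")
    q = np.ceil(5.0 * ranks / v.notna().sum()).clip(1, 5)
    if rule.direction == "adverse":
        q = 6.0 - q
    return q


def diet_quality_index(
    data: pd.DataFrame,
    rules: Sequence[ComponentRule],
    sex: pd.Series | None = None,
) -> pd.DataFrame:
    """Sum component scores into a diet-quality index (AHEI/DASH style).

    ``data`` holds one column per component input variable (food-group g/day
    or nutrient). Returns per-component columns plus a ``total`` column.
    """
    out = {}
    for rule in rules:
        if rule.variable not in data.columns:
            raise KeyError(f"component input {rule.variable!r} not in data")
        out[rule.name] = component_score(data[rule.variable], rule, sex=sex)
    table = pd.DataFrame(out, index=data.index)
    table["total"] = table.sum(axis=1)
    return table


#: Default 11-component AHEI-style rule set (0-10 linear points per
#: component). Thresholds are configuration, not published constants: the
#: published index is defined component-wise on portions, and users supply
#: their cohort's thresholds; these defaults target the g/day and mg/day
#: variables emitted by the synthetic cohort generator. Alcohol is scored
#: beneficial-linear up to a moderate ceiling rather than J-shaped.
DEFAULT_AHEI_RULES: tuple[ComponentRule, ...] = (
    ComponentRule("vegetables", "vegetables_g", "beneficial", "linear", 0, 400),
    ComponentRule("fruit", "fruit_g", "beneficial", "linear", 0, 300),
    ComponentRule("whole_grains", "whole_grains_g", "beneficial", "linear",
                  0, 150),
    ComponentRule("nuts_legumes", "nuts_legumes_g", "beneficial", "linear",
                  0, 60),
    ComponentRule("fish", "fish_g", "beneficial", "linear", 0, 80),
    ComponentRule("pufa", "pufa_g", "beneficial", "linear", 2, 25),
    ComponentRule("omega3", "omega3_mg", "beneficial", "linear", 0, 400),
    ComponentRule("red_meat", "red_meat_g", "adverse", "linear", 0, 150),
    ComponentRule("ssb", "ssb_g", "adverse", "linear", 0, 250),
    ComponentRule("trans_fat", "trans_fat_g", "adverse", "linear", 0.5, 4),
    ComponentRule("sodium", "sodium_mg", "adverse", "linear", 1500, 5000),
)

#: Default 8-component DASH-style rule set (consumption quintiles, 1-5).
DEFAULT_DASH_RULES: tuple[ComponentRule, ...] = (
    ComponentRule("fruit", "fruit_g", "beneficial", "quintile"),
    ComponentRule("vegetables", "vegetables_g", "beneficial", "quintile"),
    ComponentRule("nuts_legumes", "nuts_legumes_g", "beneficial", "quintile"),
    ComponentRule("whole_grains", "whole_grains_g", "beneficial", "quintile"),
    ComponentRule("dairy_lowfat", "dairy_lowfat_g", "beneficial", "quintile"),
    ComponentRule("sodium", "sodium_mg", "adverse", "quintile"),
    ComponentRule("red_meat", "red_meat_g", "adverse", "quintile"),
    ComponentRule("ssb", "ssb_g", "adverse", "quintile"),
)


_HB_MALE = (66.473, 13.7516, 5.0033, 6.755)
_HB_FEMALE = (655.0955, 9.5634, 1.8496, 4.6756)


def harris_benedict_bmr(
    sex: pd.Series | str,
    weight_kg: pd.Series | float,
    height_cm: pd.Series | float,
    age_yr: pd.Series | float,
) -> pd.Series | float:
    """Basal metabolic rate (kcal/day), classic Harris-Benedict equations.

    Men: 66.473 + 13.7516 W + 5.0033 H - 6.755 A;
    women: 655.0955 + 9.5634 W + 1.8496 H - 4.6756 A
    with W in kg, H in cm, A in years.
    """
    scalar = np.isscalar(sex) or isinstance(sex, str)
    s = pd.Series([sex]) if scalar else pd.Series(sex)
    w = pd.Series([weight_kg]) if scalar else pd.Series(weight_kg, index=s.index)
    h = pd.Series([height_cm]) if scalar else pd.Series(height_cm, index=s.index)
    a = pd.Series([age_yr]) if scalar else pd.Series(age_yr, index=s.index)
    if (w <= 0).any() or (h <= 0).any() or (a <= 0).any():
        raise ValueError("anthropometrics must be positive")
    known = s.isin(["male", "female", "M", "F"])
    if not known.all():
        raise ValueError(f"unknown sex codes: {sorted(s[~known].unique())}")
    male = s.isin(["male", "M"]).to_numpy()
    c = np.where(male[:, None], _HB_MALE, _HB_FEMALE)
    bmr = c[:, 0] + c[:, 1] * w.to_numpy() + c[:, 2] * h.to_numpy() - c[:, 3] * a.to_numpy()
    if scalar:
        return float(bmr[0])
    return pd.Series(bmr, index=s.index, name="bmr_kcal")


def flag_misreporters(
    energy_kcal: pd.Series,
    bmr_kcal: pd.Series,
    low: float = 0.5,
    high: float = 3.5,
) -> pd.Series:
    """Flag implausible energy reporters: energy < 0.5 BMR or > 3.5 BMR."""
    ratio = energy_kcal / bmr_kcal
    return (ratio < low) | (ratio > high)
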