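"""Synthetic cohorts with known ground truth.

Every analysis stage in this package is exercised on generated data whose
structural parameters are recorded: a latent "healthiness" score drives
diet quality, dietary diversity (through the concentration of the
per-participant intake distribution over food groups), physical activity,
smoking and — with slope ``richness_slope`` — the number of detected
catalog genes, while mediation panels plant exposure -> mediator -> outcome
coefficient chains (a, b, c') whose true mediated proportion is
``a*b / (a*b + c')``.

The generator draws every quantity from named RNG sub-streams derived from
one master seed, so cohorts are reproducible and adding a new component
does not shift existing draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd

from .diet import FoodIntakeTable
from .io import CohortBundle
from .metagenome import GeneAbundanceMatrix

__all__ = ["SyntheticTruth", "gen_cohort", "gen_mediation_panel",
           "gen_feature_panel", "FeaturePanel", "make_taxonomy"]


@dataclass
class SyntheticTruth:
    """Planted parameters of a generated cohort.

    ``a`` (exposure->mediator), ``b`` (mediator->outcome) and ``c_prime``
    (direct effect) define the mediation chain; the true ACME is ``a*b``,
    the true ADE ``c_prime`` and the mediated proportion
    ``a*b/(a*b + c_prime)``. ``richness_slope`` scales how strongly the
    latent healthiness shifts the number of detected genes;
    ``group_concentration`` is the Dirichlet concentration of intake over
    food groups (larger = more even diet).
    """

    n: int = 500
    seed: int = 0
    a: float = 0.556
    b: float = 0.5
    c_prime: float = 0.722
    sigma_m: float = 1.0
    sigma_y: float = 1.0
    richness_slope: float = 0.25
    group_concentration: float = 5.0
    n_species: int = 60
    genes_per_species: int = 40
    confound_beta: float = 0.2

    def __post_init__(self) -> None:
        if self.sigma_m <= 0 or self.sigma_y <= 0:
            raise ValueError("noise SDs must be positive")
        if self.n < 1:
            raise ValueError("n must be positive")

    @property
    def true_acme(self) -> float:
        return self.a * self.b

    @property
    def true_total(self) -> float:
        return self.a * self.b + self.c_prime

    @property
    def true_prop_mediated(self) -> float:
        if self.true_total == 0:
            return float("nan")
        return self.true_acme / self.true_total

    def manifest(self) -> dict:
        out = {k: getattr(self, k) for k in (
            "n", "seed", "a", "b", "c_prime", "sigma_m", "sigma_y",
            "richness_slope", "group_concentration", "n_species",
            "genes_per_species", "confound_beta")}
        out["true_acme"] = self.true_acme
        out["true_ade"] = self.c_prime
        out["true_prop_mediated"] = self.true_prop_mediated
        return out


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(name.encode())])
    )


# -- food taxonomy ----------------------------------------------------------

N_GROUPS42 = 42
N_GROUPS22 = 22
N_ITEMS = 160
_BEVERAGE_GROUPS = {"grp38", "grp39", "grp40", "grp41", "grp42"}
_LIQUID_GROUPS = _BEVERAGE_GROUPS | {"grp37"}  # milk counts as liquid


def make_taxonomy() -> pd.DataFrame:
    """A 160-item taxonomy with 42 fine groups refining 22 coarse groups,
    beverage groups at the tail and milk flagged liquid."""
    fine = [f"grp{i + 1:02d}" for i in range(N_GROUPS42)]
    # first 20 coarse groups hold 2 fine groups each, last 2 hold 1
    parents = {}
    for i, g in enumerate(fine):
        parents[g] = f"G{min(i // 2, N_GROUPS22 - 1) + 1:02d}"
    rows = []
    for j in range(N_ITEMS):
        g = fine[j % N_GROUPS42]
        rows.append({
            "item": f"item{j + 1:03d}",
            "group42": g,
            "group22": parents[g],
            "is_beverage": g in _BEVERAGE_GROUPS,
            "is_liquid": g in _LIQUID_GROUPS,
        })
    return pd.DataFrame(rows).set_index("item")


_NUTRIENT_PROFILE = {
    # column -> (base, spread, healthiness loading); adverse foods load
    # negatively so high-healthiness participants eat less of them
    "vegetables_g": (250.0, 80.0, 60.0),
    "fruit_g": (200.0, 70.0, 50.0),
    "whole_grains_g": (90.0, 40.0, 30.0),
    "nuts_legumes_g": (40.0, 20.0, 15.0),
    "fish_g": (40.0, 20.0, 12.0),
    "pufa_g": (15.0, 5.0, 3.0),
    "omega3_mg": (250.0, 100.0, 60.0),
    "red_meat_g": (90.0, 40.0, -25.0),
    "ssb_g": (150.0, 90.0, -60.0),
    "trans_fat_g": (2.0, 0.8, -0.5),
    "sodium_mg": (3200.0, 700.0, -350.0),
    "alcohol_g": (12.0, 8.0, 2.0),
    "dairy_lowfat_g": (120.0, 60.0, 25.0),
}


def gen_cohort(truth: SyntheticTruth) -> CohortBundle:
    """Generate a complete cohort bundle with the planted structure.

    Deterministic given ``truth.seed``. A latent healthiness score ``h``
    drives diet quality (through the nutrient columns scored by the
    default diet-quality rules), diet diversity (Dirichlet concentration
    over food groups scales with ``exp(h/2)``), physical activity, smoking
    status (assigned by healthiness quantile) and gene richness (fraction
    of species carried grows with ``richness_slope * h``).
    """
    n = truth.n
    seed = truth.seed
    pid = pd.Index([f"P{i + 1:04d}" for i in range(n)], name="participant")
    sid = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample")
    h = _rng(seed, "healthiness").standard_normal(n)

    # --- intake over the 42-group taxonomy --------------------------------
    tax = make_taxonomy()
    rng_int = _rng(seed, "intake")
    groups = tax["group42"].unique()
    base = rng_int.uniform(0.5, 1.5, size=len(groups))
    conc = truth.group_concentration * np.exp(
        0.5 * np.clip(h, -2.5, 2.5))  # diversity rises with healthiness
    grams = np.zeros((n, len(tax)))
    items_of = {g: np.flatnonzero(tax["group42"].to_numpy() == g)
                for g in groups}
    total_g = rng_int.normal(1900.0, 250.0, size=n).clip(800.0)
    for i in range(n):
        shares = rng_int.dirichlet(conc[i] * base)
        for g, share in zip(groups, shares):
            ids = items_of[g]
            within = rng_int.dirichlet(np.ones(len(ids)))
            grams[i, ids] = total_g[i] * share * within
    # sparsify: drop a healthiness-dependent share of items to vary counts
    drop_p = np.clip(0.35 - 0.1 * np.tanh(h), 0.05, 0.8)
    mask = rng_int.random(grams.shape) < drop_p[:, None]
    grams[mask] = 0.0
    intake = FoodIntakeTable(
        pd.DataFrame(grams, index=pid, columns=tax.index), tax)

    # --- nutrients --------------------------------------------------------
    rng_nut = _rng(seed, "nutrients")
    nut = {}
    for col, (base_v, sd, load) in _NUTRIENT_PROFILE.items():
        nut[col] = np.clip(
            base_v + load * h + sd * rng_nut.standard_normal(n), 0.0, None)
    energy = np.clip(2100.0 + 80.0 * rng_nut.standard_normal(n)
                     + 0.3 * (total_g - total_g.mean()), 900.0, None)
    nut["energy_kcal"] = energy
    nutrients = pd.DataFrame(nut, index=pid)

    # --- lifestyle --------------------------------------------------------
    rng_life = _rng(seed, "lifestyle")
    met = np.clip(
        42.0 + 16.0 * (0.7 * h + 0.7 * rng_life.standard_normal(n)), 0.5, None)
    q = pd.Series(h).rank(pct=True).to_numpy()
    smoking = np.where(
        q < 0.22, "current",
        np.where(q < 0.35, "former",
                 np.where(q < 0.42, "passive", "non-smoker")))
    lifestyle = pd.DataFrame(
        {"activity_met_h_week": met, "smoking": smoking}, index=pid)

    # --- clinical ---------------------------------------------------------
    rng_cl = _rng(seed, "clinical")
    age = rng_cl.uniform(28.0, 72.0, size=n)
    sex = rng_cl.choice(["male", "female"], size=n)
    center = rng_cl.choice(["FR", "DE", "DK"], size=n)
    bmi = 27.5 - 1.6 * h + 2.5 * rng_cl.standard_normal(n)
    hba1c = 5.9 - 0.35 * h + 0.4 * rng_cl.standard_normal(n)
    homa = np.exp(0.8 - 0.45 * h + 0.5 * rng_cl.standard_normal(n))
    p_drug = 1.0 / (1.0 + np.exp(1.2 + 0.5 * h))
    clinical = pd.DataFrame({
        "age": age, "sex": sex, "center": center,
        "bmi": bmi.clip(16.0), "hba1c": hba1c.clip(4.0),
        "homa_ir": homa,
        "metformin": (rng_cl.random(n) < p_drug).astype(int),
        "statin": (rng_cl.random(n) < p_drug).astype(int),
        "ppi": (rng_cl.random(n) < 0.15).astype(int),
        "antibiotics_courses": rng_cl.poisson(0.4, size=n),
    }, index=pid)

    # --- gene matrix ------------------------------------------------------
    rng_gen = _rng(seed, "genes")
    n_sp, gps = truth.n_species, truth.genes_per_species
    gene_ids = [f"sp{s + 1:03d}_g{g + 1:02d}"
                for s in range(n_sp) for g in range(gps)]
    # fixed per-species gene weight profiles
    gene_w = rng_gen.dirichlet(np.ones(gps) * 2.0, size=n_sp)
    depth = 20_000
    frac = np.clip(0.55 + truth.richness_slope * h
                   + 0.05 * rng_gen.standard_normal(n), 0.08, 1.0)
    counts = np.zeros((n, n_sp * gps), dtype=np.int64)
    sp_order = np.argsort(rng_gen.random((n, n_sp)), axis=1)
    for i in range(n):
        k = max(int(round(frac[i] * n_sp)), 3)
        present = sp_order[i, :k]
        ab = np.exp(rng_gen.normal(0.0, 1.0, size=k))
        ab /= ab.sum()
        for s, a_s in zip(present, ab):
            # expected reads at the nominal depth, floored at detection
            expected = depth * a_s * gene_w[s]
            counts[i, s * gps:(s + 1) * gps] = np.floor(expected).astype(
                np.int64)
    genes = GeneAbundanceMatrix(
        pd.DataFrame(counts, index=sid, columns=gene_ids),
        pd.Series(rng_gen.integers(600, 3000, size=len(gene_ids)),
                  index=gene_ids, dtype=float),
    )
    mgs_def = {
        f"mgs{s + 1:03d}": [f"sp{s + 1:03d}_g{g + 1:02d}"
                            for g in range(min(gps, 50))]
        for s in range(n_sp)
    }
    mgs_tax = {m: f"synthetic species {i + 1}"
               for i, m in enumerate(mgs_def)}

    # --- metabolites and cell counts --------------------------------------
    rng_met = _rng(seed, "metabolites")
    n_metab = 30
    metab = rng_met.standard_normal((n, n_metab))
    metab[:, 0] += 0.5 * h  # a couple of healthiness-linked features
    metab[:, 1] -= 0.5 * h
    metabolites = pd.DataFrame(
        metab, index=sid,
        columns=[f"metab{j + 1:03d}" for j in range(n_metab)])
    cell_counts = pd.Series(
        np.exp(rng_met.normal(25.0, 0.4, size=n)), index=sid,
        name="cell_count")
    sample_map = pd.Series(sid, index=pid, name="sample")

    bundle = CohortBundle(
        intake=intake, nutrients=nutrients, lifestyle=lifestyle,
        clinical=clinical, genes=genes, mgs_def=mgs_def,
        mgs_taxonomy=mgs_tax, metabolites=metabolites,
        sample_map=sample_map, cell_counts=cell_counts,
    )
    bundle.truth = truth  # attach planted parameters for test harnesses
    bundle.latent_healthiness = pd.Series(h, index=pid, name="healthiness")
    return bundle


def gen_mediation_panel(
    truth: SyntheticTruth,
    exposure_type: Literal["binary", "3-level"] = "binary",
) -> pd.DataFrame:
    """A single exposure/mediator/outcome panel with planted coefficients.

    ``mediator = a*X + beta*(c1+c2) + N(0, sigma_m)`` and
    ``outcome = b*M + c_prime*X + beta*(c1+c2) + N(0, sigma_y)`` with
    ``beta = truth.confound_beta`` and two standard-normal covariates that
    also tilt the exposure probability. The true ACME (``a*b``), ADE
    (``c_prime``) and mediated proportion are available from ``truth``.
    """
    n = truth.n
    rng = _rng(truth.seed, "mediation_panel")
    beta = truth.confound_beta
    c1 = rng.standard_normal(n)
    c2 = rng.standard_normal(n)
    p = 1.0 / (1.0 + np.exp(-beta * (c1 + c2)))
    if exposure_type == "binary":
        x = (rng.random(n) < p).astype(float)
    elif exposure_type == "3-level":
        u = rng.random(n) * 0.5 + 0.5 * p
        x = np.digitize(u, [1 / 3, 2 / 3]).astype(float)
    else:
        raise ValueError(f"unknown exposure_type {exposure_type!r}")
    m = truth.a * x + beta * (c1 + c2) \
        + truth.sigma_m * rng.standard_normal(n)
    y = truth.b * m + truth.c_prime * x + beta * (c1 + c2) \
        + truth.sigma_y * rng.standard_normal(n)
    out = pd.DataFrame({"x": x, "m": m, "y": y, "c1": c1, "c2": c2})
    out.attrs["truth"] = truth.manifest()
    return out


class FeaturePanel(NamedTuple):
    mgs: pd.DataFrame
    metabolites: pd.DataFrame
    exposure: pd.Series
    covariates: pd.DataFrame
    truth_pairs: list[dict]


def gen_feature_panel(
    truth: SyntheticTruth,
    n_mgs: int = 20,
    n_metab: int = 30,
    n_causal_pairs: int = 0,
) -> FeaturePanel:
    """MGS x metabolite panels with planted direction-1 causal pairs.

    For each planted pair the MGS depends on the exposure (coefficient
    ``a``) and the metabolite on the MGS (``b``) plus a direct exposure
    path (``c_prime``) — the direction-1 structure (exposure -> MGS ->
    metabolite). All remaining features are independent noise.
    """
    if n_causal_pairs > min(n_mgs, n_metab):
        raise ValueError("at most one planted pair per feature")
    n = truth.n
    rng = _rng(truth.seed, "feature_panel")
    x = (rng.random(n) < 0.5).astype(float)
    beta = truth.confound_beta
    cov = pd.DataFrame({
        "age": rng.standard_normal(n),
        "sex": (rng.random(n) < 0.5).astype(float),
    })
    mgs = rng.standard_normal((n, n_mgs))
    metab = rng.standard_normal((n, n_metab))
    pairs = []
    for k in range(n_causal_pairs):
        i, j = k, k  # planted pairs on the diagonal, deterministic
        mgs[:, i] = truth.a * x + beta * cov["age"] \
            + truth.sigma_m * rng.standard_normal(n)
        metab[:, j] = truth.b * mgs[:, i] + truth.c_prime * x \
            + beta * cov["age"] + truth.sigma_y * rng.standard_normal(n)
        pairs.append({
            "mgs": f"mgs{i + 1:03d}", "metabolite": f"metab{j + 1:03d}",
            "direction": 1, "a": truth.a, "b": truth.b,
            "c_prime": truth.c_prime,
        })
    idx = pd.RangeIndex(n, name="sample")
    return FeaturePanel(
        mgs=pd.DataFrame(mgs, index=idx,
                         columns=[f"mgs{i + 1:03d}" for i in range(n_mgs)]),
        metabolites=pd.DataFrame(
            metab, index=idx,
            columns=[f"metab{j + 1:03d}" for j in range(n_metab)]),
        exposure=pd.Series(x, index=idx, name="exposure"),
        covariates=cov.set_index(idx),
        truth_pairs=pairs,
    )
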