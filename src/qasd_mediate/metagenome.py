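"""Gene-count matrix processing: rarefied gene richness (GMGR), length/depth
normalisation, marker-gene MGS abundances, cell-count correction and the
rank-based inverse-normal transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneAbundanceMatrix",
    "rarefy_richness",
    "normalize_fpkm",
    "mgs_abundance",
    "cellcount_correct",
    "rank_inverse_normal",
]


@dataclass
class GeneAbundanceMatrix:
    """Sample x gene read counts with per-gene lengths (bp).

    ``depth`` (reads per sample) is the row sum of the counts.
    """

    counts: pd.DataFrame
    gene_length: pd.Series

    def __post_init__(self) -> None:
        self.gene_length = self.gene_length.reindex(self.counts.columns)
        if self.gene_length.isna().any():
            bad = list(self.gene_length.index[self.gene_length.isna()])
            raise ValueError(f"genes without length: {bad[:5]}")
        if (self.gene_length <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")

    @property
    def depth(self) -> pd.Series:
        return self.counts.sum(axis=1)


def _rng_for(seed: int, *keys: int) -> np.random.Generator:
    # independent sub-streams keyed by (sample, replicate) so results do
    # not depend on evaluation order or parallel scheduling
    return np.random.default_rng(np.random.SeedSequence([seed, *keys]))


def rarefy_richness(
    genes: GeneAbundanceMatrix,
    depth: int,
    replicates: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Gene richness after rarefaction to a fixed read depth (GMGR).

    Per replicate, ``depth`` reads are drawn per sample *without*
    replacement from the sample's gene-count vector (multivariate
    hypergeometric draw); richness is the number of genes hit at least
    once, and GMGR is the mean richness over replicates. Samples shallower
    than ``depth`` are returned as NA.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    if replicates < 1:
        raise ValueError("need >= 1 replicate")
    counts = genes.counts.to_numpy(dtype=np.int64)
    totals = counts.sum(axis=1)
    out = np.full(len(counts), np.nan)
    for i, row in enumerate(counts):
        if totals[i] < depth:
            continue
        if totals[i] == depth:
            out[i] = float(np.count_nonzero(row))
            continue
        rich = np.empty(replicates)
        for r in range(replicates):
            draw = _rng_for(seed, i, r).multivariate_hypergeometric(
                row, depth, method="marginals"
            )
            rich[r] = np.count_nonzero(draw)
        out[i] = rich.mean()
    if np.isnan(out).any():
        shallow = list(genes.counts.index[np.isnan(out)])
        warnings.warn(f"samples shallower than {depth} set to NA: {shallow[:5]}")
    return pd.Series(out, index=genes.counts.index, name="gmgr")


def normalize_fpkm(genes: GeneAbundanceMatrix) -> pd.DataFrame:
    """Length-normalised per-sample gene frequencies.

    Each count is divided by its gene length; rows are then scaled to sum
    to one, so values are frequencies comparable across samples and gene
    sizes. Zero-depth samples become all-NA rows with a warning.
    """
    rate = genes.counts.div(genes.gene_length, axis=1)
    totals = rate.sum(axis=1)
    if (totals == 0).any():
        warnings.warn(
            f"zero-depth samples set to NA: {list(totals.index[totals == 0])[:5]}"
        )
    return rate.div(totals.replace(0, np.nan), axis=0)


def mgs_abundance(
    freq: pd.DataFrame,
    marker_genes: Mapping[str, Sequence[str]],
    taxonomy: Mapping[str, str] | None = None,
    detection_fraction: float = 0.1,
) -> pd.DataFrame:
    """Metagenomic-species abundances from marker-gene frequencies.

    The abundance of an MGS in a sample is the mean frequency of its 50
    marker genes, provided strictly more than ``detection_fraction`` of the
    markers have a positive signal (frequency > 0); otherwise 0. Marker
    genes absent from the matrix count as zeros (warned); marker lists of a
    length other than 50 trigger a warning and the >10%-of-list rule.
    """
    cols = {}
    for mgs_id, markers in marker_genes.items():
        markers = list(markers)
        if len(markers) != 50:
            warnings.warn(
                f"{mgs_id}: marker list has {len(markers)} genes (expected 50)"
            )
        present = [g for g in markers if g in freq.columns]
        if len(present) < len(markers):
            warnings.warn(
                f"{mgs_id}: {len(markers) - len(present)} marker genes "
                "absent from matrix; counted as zero"
            )
        sub = freq[present].to_numpy(dtype=float) if present else \
            np.zeros((len(freq), 0))
        npos = (sub > 0).sum(axis=1)
        mean = sub.sum(axis=1) / len(markers) if markers else \
            np.zeros(len(freq))
        detected = npos > detection_fraction * len(markers)
        cols[mgs_id] = np.where(detected, mean, 0.0)
    out = pd.DataFrame(cols, index=freq.index)
    if taxonomy is not None:
        out.attrs["taxonomy"] = dict(taxonomy)
    return out


def cellcount_correct(
    features: pd.DataFrame, cell_counts: pd.Series
) -> pd.DataFrame:
    """Rescale relative features to quasi-absolute values by cell count.

    Each sample row is multiplied by its bacterial cell count divided by
    the mean cell count over the dataset; samples without a count are
    dropped with a warning.
    """
    cc = cell_counts.reindex(features.index)
    if cc.notna().sum() == 0:
        raise ValueError("no samples with cell counts")
    if (cc.dropna() <= 0).any():
        raise ValueError("cell counts must be positive")
    if cc.isna().any():
        warnings.warn(
            f"samples without cell counts dropped: {list(cc.index[cc.isna()])[:5]}"
        )
    kept = features.loc[cc.notna()]
    factor = cc.dropna() / cc.dropna().mean()
    return kept.mul(factor, axis=0)


def rank_inverse_normal(values: pd.Series, offset: str = "uniform") -> pd.Series:
    """Empirical normal quantile (rank-based inverse normal) transform.

    Maps values to ``Phi^-1(rank / (n + 1))`` with average ranks for ties
    (``offset='uniform'``); ``offset='blom'`` uses ``(rank - 3/8)/(n + 1/4)``.
    Output is approximately standard normal. NA values stay NA; an all-tied
    vector maps to zeros with a warning.
    """
    v = pd.Series(values).astype(float)
    ok = v.notna()
    n = int(ok.sum())
    if n < 2:
        raise ValueError("need >= 2 non-missing values")
    x = v[ok].to_numpy()
    if np.ptp(x) == 0:
        warnings.warn("all values tied; transform returns zeros")
        out = pd.Series(np.nan, index=v.index)
        out[ok] = 0.0
        return out
    ranks = stats.rankdata(x, method="average")
    if offset == "uniform":
        u = ranks / (n + 1)
    elif offset == "blom":
        u = (ranks - 0.375) / (n + 0.25)
    else:
        raise ValueError(f"unknown offset {offset!r}")
    out = pd.Series(np.nan, index=v.index, name=v.name)
    out[ok] = stats.norm.ppf(u)
    return out
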