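"""Reading, validating and writing the tabular cohort inputs and results.

All tables are TSV with a header row; the participant or sample id is the
first column; missing values are encoded "NA". A cohort is carried through
the pipeline as a single validated :class:`CohortBundle`; downstream
modules consume only the bundle and a :class:`~.config.RunConfig`, never
raw files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, config_hash
from .diet import FoodIntakeTable
from .metagenome import GeneAbundanceMatrix

__all__ = ["CohortBundle", "load_bundle", "write_results",
           "read_table", "write_table"]

_NA = "NA"


def read_table(path: str | Path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=[_NA],
                       keep_default_na=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep=_NA)


@dataclass
class CohortBundle:
    """All inputs for one cohort, validated and id-reconciled.

    ``sample_map`` maps participant id -> sample id (bijective over the
    samples in use); ``mgs_def`` maps MGS id -> ordered marker gene list;
    ``mgs_taxonomy`` carries the taxonomy strings.
    """

    intake: FoodIntakeTable
    nutrients: pd.DataFrame
    lifestyle: pd.DataFrame
    clinical: pd.DataFrame
    genes: GeneAbundanceMatrix | None = None
    mgs_def: dict[str, list[str]] | None = None
    mgs_taxonomy: dict[str, str] | None = None
    metabolites: pd.DataFrame | None = None
    sample_map: pd.Series | None = None
    cell_counts: pd.Series | None = None

    def __post_init__(self) -> None:
        pid = self.intake.grams.index
        if pid.duplicated().any():
            raise ValueError("duplicate participant ids in intake table")
        for name in ("nutrients", "lifestyle", "clinical"):
            tab = getattr(self, name)
            orphans = tab.index.difference(pid)
            missing = pid.difference(tab.index)
            if len(orphans) or len(missing):
                raise ValueError(
                    f"id mismatch between intake and {name}: "
                    f"orphans={list(orphans)[:5]}, missing={list(missing)[:5]}"
                )
        if "energy_kcal" in self.nutrients.columns:
            e = self.nutrients["energy_kcal"].dropna()
            if (e <= 0).any():
                raise ValueError("energy_kcal must be positive where present")
        if self.genes is not None:
            if self.sample_map is None:
                raise ValueError("gene matrix requires a sample_map")
            samples = self.genes.counts.index
            mapped = pd.Index(self.sample_map.values)
            orphan = samples.difference(mapped)
            if len(orphan):
                raise ValueError(
                    f"samples in gene matrix absent from sample_map: "
                    f"{list(orphan)[:5]}"
                )
            if self.sample_map.duplicated().any() \
                    or self.sample_map.index.duplicated().any():
                raise ValueError("sample_map must be a bijection")

    @property
    def participants(self) -> pd.Index:
        return self.intake.grams.index

    def sample_for(self, participant_ids: pd.Index) -> pd.Index:
        return pd.Index(self.sample_map.loc[participant_ids].values)


_REQUIRED = {
    "intake": None,          # all columns are items
    "taxonomy": ["group42", "group22", "is_beverage", "is_liquid"],
    "nutrients": ["energy_kcal"],
    "lifestyle": ["activity_met_h_week", "smoking"],
    "clinical": ["age", "sex", "center"],
}


def load_bundle(paths: dict[str, str | Path],
                config: RunConfig | None = None) -> CohortBundle:
    """Load and validate a cohort from named TSV files.

    Required keys: ``intake``, ``taxonomy``, ``nutrients``, ``lifestyle``,
    ``clinical``. Optional: ``genes``, ``gene_lengths``, ``mgs_def``,
    ``metabolites``, ``sample_map``, ``cell_counts``.
    """
    for key in ("intake", "taxonomy", "nutrients", "lifestyle", "clinical"):
        if key not in paths:
            raise KeyError(f"missing required table {key!r}")
        if not Path(paths[key]).exists():
            raise FileNotFoundError(paths[key])
    tables = {k: read_table(paths[k]) for k in
              ("intake", "taxonomy", "nutrients", "lifestyle", "clinical")}
    for name, cols in _REQUIRED.items():
        if cols is None:
            continue
        missing = [c for c in cols if c not in tables[name].columns]
        if missing:
            raise ValueError(f"table {name!r} missing columns {missing}")
    for c in ("is_beverage", "is_liquid"):
        tables["taxonomy"][c] = tables["taxonomy"][c].astype(bool)
    intake = FoodIntakeTable(tables["intake"], tables["taxonomy"])

    genes = None
    if "genes" in paths:
        counts = read_table(paths["genes"])
        lengths = read_table(paths["gene_lengths"]).iloc[:, 0]
        genes = GeneAbundanceMatrix(counts.astype(np.int64), lengths)
    mgs_def = mgs_tax = None
    if "mgs_def" in paths:
        md = read_table(paths["mgs_def"], index_col=None)
        mgs_def = {k: list(g["gene_id"]) for k, g in md.groupby("mgs_id")}
        if "taxonomy" in md.columns:
            mgs_tax = md.drop_duplicates("mgs_id").set_index(
                "mgs_id")["taxonomy"].to_dict()
    metabolites = read_table(paths["metabolites"]) \
        if "metabolites" in paths else None
    sample_map = read_table(paths["sample_map"]).iloc[:, 0] \
        if "sample_map" in paths else None
    cell_counts = read_table(paths["cell_counts"]).iloc[:, 0] \
        if "cell_counts" in paths else None
    return CohortBundle(
        intake=intake, nutrients=tables["nutrients"],
        lifestyle=tables["lifestyle"], clinical=tables["clinical"],
        genes=genes, mgs_def=mgs_def, mgs_taxonomy=mgs_tax,
        metabolites=metabolites, sample_map=sample_map,
        cell_counts=cell_counts,
    )


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: RunConfig | None = None,
    overwrite: bool = False,
) -> dict:
    """Write result tables as TSVs plus a JSON manifest.

    Refuses to clobber existing files unless ``overwrite`` is set. The
    manifest records table names, row counts, the config hash and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = {}
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True")
        write_table(df, path)
        entries[name] = {"rows": int(df.shape[0]), "cols": int(df.shape[1])}
    manifest = {
        "tables": entries,
        "config_hash": config_hash(config) if config else None,
        "seed": config.seed if config else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
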