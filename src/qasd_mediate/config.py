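"""Run configuration: covariate sets, thresholds, and reproducibility knobs.

All statistical thresholds carry the defaults used throughout the analysis:
association screening at FDR 0.05, drug deconfounding at FDR 0.1 with a
|Cliff's delta| floor of 0.1, mediation significance at FDR 0.05 jointly on
ACME, ADE and total effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path


@dataclass
class RunConfig:
    """Configuration shared by every pipeline stage.

    Parameters
    ----------
    assoc_fdr : float
        BH-FDR threshold for association screens (default 0.05).
    deconf_fdr : float
        FDR threshold for the naive stage of drug deconfounding (default 0.1).
    mediation_fdr : float
        FDR threshold applied jointly to ACME, ADE and total effect (0.05).
    effect_size_floor : float
        Minimum absolute Cliff's delta for a feature to enter mediation (0.1).
    rarefaction_depth : int
        Reads per sample for gene-richness rarefaction.
    rarefaction_replicates : int
        Number of rarefaction replicates averaged into GMGR (default 10).
    mediation_draws : int
        Quasi-Bayesian simulation draws for mediation CIs (default 1000).
    permutations : int
        Permutations for distance-based tests (default 999).
    seed : int
        Master RNG seed.
    qasd_grouping : str
        "5-level" or "3-level" categorical grouping of the 0-7 total.
    clinical_covariates : tuple of str
        Adjustment set for mediation and deconfounding models.
    """

    assoc_fdr: float = 0.05
    deconf_fdr: float = 0.1
    mediation_fdr: float = 0.05
    effect_size_floor: float = 0.1
    rarefaction_depth: int = 10_000_000
    rarefaction_replicates: int = 10
    mediation_draws: int = 1000
    permutations: int = 999
    seed: int = 0
    qasd_grouping: str = "3-level"
    clinical_covariates: tuple[str, ...] = (
        "center", "age", "sex", "metformin", "statin", "ppi",
    )

    def __post_init__(self) -> None:
        for name in ("assoc_fdr", "deconf_fdr", "mediation_fdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("rarefaction_depth", "rarefaction_replicates",
                     "mediation_draws", "permutations"):
            v = getattr(self, name)
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.qasd_grouping not in ("5-level", "3-level"):
            raise ValueError(f"unknown qasd_grouping {self.qasd_grouping!r}")

    # -- flat key=value round trip -------------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        for raw in Path(path).read_text().splitlines():
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            key, _, val = raw.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise KeyError(f"unknown config key {key!r}")
            if key == "clinical_covariates":
                kwargs[key] = tuple(s.strip() for s in val.split(",") if s)
            elif key == "qasd_grouping":
                kwargs[key] = val
            elif key in ("assoc_fdr", "deconf_fdr", "mediation_fdr",
                         "effect_size_floor"):
                kwargs[key] = float(val)
            else:
                kwargs[key] = int(val)
        return cls(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of a configuration, for output manifests."""
    import hashlib

    payload = repr(sorted(
        (f.name, getattr(config, f.name)) for f in fields(config)
    )).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
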