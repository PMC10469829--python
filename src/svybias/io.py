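"""CSV interchange and run configuration.

Data interchange is plain CSV (UTF-8, comma-delimited, header row,
"NA"/empty for missing).  Child tables carry
``child_id,cluster_id,stratum,y,<covariates>,weight``; cluster frames
carry ``cluster_id,stratum,N_c,n_c``.  Every file the package writes
starts with a comment line embedding the configuration hash and seed,
and is read back with ``comment='#'``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from svybias.experiment import ExperimentConfig
from svybias.logit import ModelSpec
from svybias.simulate import CovariateSpec, SimConfig

__all__ = [
    "RunConfig",
    "read_child_table",
    "write_table",
    "read_table",
    "load_config",
    "config_hash",
]

logger = logging.getLogger(__name__)

REQUIRED_CHILD_COLUMNS = ("child_id", "cluster_id", "stratum", "y")


def read_child_table(
    path: str | Path, N_c: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a child-level CSV and derive its cluster frame.

    ``n_c`` is derived by counting records per cluster; ``N_c`` comes
    from an ``N_c`` column if present, else from the argument, else is
    left missing.  A missing weight column defaults to 1 with a logged
    warning.  Validation errors cite 1-based data row numbers.
    """
    data = pd.read_csv(path, comment="#", na_values=["NA", ""])
    missing_cols = [c for c in REQUIRED_CHILD_COLUMNS if c not in data.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    bad_y = data.index[~data["y"].isin([0, 1])].to_numpy()
    if len(bad_y):
        raise ValueError(
            f"{path}: non-binary outcome y on data rows {[int(i) + 1 for i in bad_y[:10]]}"
        )
    data["y"] = data["y"].astype(int)
    if "weight" not in data.columns:
        logger.warning("%s: no weight column; defaulting all weights to 1", path)
        data["weight"] = 1.0
    bad_w = data.index[~(data["weight"] > 0)].to_numpy()
    if len(bad_w):
        raise ValueError(
            f"{path}: non-positive weight on data rows {[int(i) + 1 for i in bad_w[:10]]}"
        )
    grouped = data.groupby("cluster_id", sort=False)
    clusters = grouped.agg(stratum=("stratum", "first"), n_c=("y", "size")).reset_index()
    if "N_c" in data.columns:
        clusters["N_c"] = grouped["N_c"].first().to_numpy()
    elif N_c is not None:
        clusters["N_c"] = float(N_c)
    else:
        clusters["N_c"] = float("nan")
    return data, clusters[["cluster_id", "stratum", "N_c", "n_c"]]


def config_hash(obj) -> str:
    """Short stable hash of a configuration dataclass or mapping."""
    try:
        payload = asdict(obj)
    except TypeError:
        payload = obj
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, config, seed: int) -> None:
    """Write a CSV with a header comment line carrying config hash + seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# svybias config={config_hash(config)} seed={seed}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", na_values=["NA", ""])


@dataclass
class RunConfig:
    """Parsed run configuration: data source, model, and experiment."""

    child_csv: str | None = None
    cluster_csv: str | None = None
    sim: SimConfig | None = None
    spec: ModelSpec | None = None
    experiment: ExperimentConfig | None = None
    out_dir: str = "results"
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if (self.child_csv is None) == (self.sim is None):
            raise ValueError(
                "exactly one of an input child_csv or a simulate block must "
                "supply the data"
            )


_SIM_KEYS = {
    "n_clusters_total",
    "children_per_cluster",
    "urban_fraction",
    "true_coefficients",
    "cluster_effect_sd",
    "covariates",
    "sampled_clusters",
    "children_sampled_per_cluster",
    "informativeness",
    "seed",
}
_MODEL_KEYS = {"outcome", "covariates", "weighting"}
_EXPERIMENT_KEYS = {
    "fractions",
    "reference_rate",
    "reference_unit",
    "replicates",
    "seed",
    "with_replacement",
    "include_population_weighted",
}
_TOP_KEYS = {"input", "simulate", "model", "experiment", "out_dir", "verbosity"}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


def _parse_sim(block: dict) -> SimConfig:
    _check_keys(block, _SIM_KEYS, "simulate")
    block = dict(block)
    if "covariates" in block:
        block["covariates"] = tuple(
            CovariateSpec(
                name=c["name"],
                levels=tuple(c["levels"]),
                probs=tuple(c["probs"]),
                by_stratum={k: tuple(v) for k, v in c["by_stratum"].items()}
                if c.get("by_stratum")
                else None,
            )
            for c in block["covariates"]
        )
    return SimConfig(**block)


def _parse_model(block: dict) -> ModelSpec:
    _check_keys(block, _MODEL_KEYS, "model")
    covariates = {
        name: tuple(levels) for name, levels in block.get("covariates", {}).items()
    }
    return ModelSpec(
        outcome=block.get("outcome", "y"),
        covariates=covariates,
        weighting=block.get("weighting", "unweighted"),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration, logging applied defaults."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    _check_keys(raw, _TOP_KEYS, "config")
    input_block = raw.get("input", {}) or {}
    _check_keys(input_block, {"child_csv", "cluster_csv"}, "input")
    sim = _parse_sim(raw["simulate"]) if "simulate" in raw else None
    spec = _parse_model(raw["model"]) if "model" in raw else None
    experiment = None
    if "experiment" in raw:
        block = dict(raw["experiment"])
        _check_keys(block, _EXPERIMENT_KEYS, "experiment")
        if spec is None:
            raise ValueError("experiment block requires a model block")
        if "fractions" not in block:
            logger.info("experiment: defaulting fractions to 1.0/0.75/0.50/0.25")
        block.setdefault("fractions", (1.0, 0.75, 0.50, 0.25))
        block["fractions"] = tuple(float(f) for f in block["fractions"])
        experiment = ExperimentConfig(spec=spec, **block)
    return RunConfig(
        child_csv=input_block.get("child_csv"),
        cluster_csv=input_block.get("cluster_csv"),
        sim=sim,
        spec=spec,
        experiment=experiment,
        out_dir=raw.get("out_dir", "results"),
        verbosity=raw.get("verbosity", "info"),
    )
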