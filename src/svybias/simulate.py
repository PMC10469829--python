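"""Synthetic finite population and two-stage stratified cluster samples.

The simulator emulates the structure of a national demographic and
health survey: a census frame of equally sized enumeration clusters
partitioned into urban and rural strata, a logistic outcome model with a
cluster-level random intercept, and a two-stage sample — simple random
sampling of clusters within strata at stage one, simple random sampling
of children within each selected cluster at stage two.

Each sampled child carries the design weight ``w_ic = N_c / n_c``, the
number of population children it represents, where ``N_c`` is the
cluster's population count and ``n_c`` its realized sample count.

Informative sampling is modelled at stage two: the per-child inclusion
log-odds in cluster *c* are shifted by ``informativeness * u_c``, where
``u_c`` is the cluster's random intercept.  Clusters with above-average
outcome risk are then over-sampled, so the unweighted sample rate is
biased while ``N_c / n_c`` remains exactly the inverse stage-two
inclusion weight and weighting corrects the bias.  At
``informativeness = 0`` the design is self-weighting within strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "CovariateSpec",
    "SimConfig",
    "SimConfigError",
    "generate_population",
    "draw_two_stage_sample",
    "population_rate",
]

STRATA = ("urban", "rural")


class SimConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class CovariateSpec:
    """A categorical child-level covariate.

    Parameters
    ----------
    name : str
        Column name in the generated tables.
    levels : tuple of str
        Declared level order; the first level is the reference in
        downstream model fitting.
    probs : tuple of float
        Marginal level probabilities (must sum to 1).
    by_stratum : dict, optional
        Stratum-specific level probabilities overriding ``probs``,
        keyed by ``"urban"`` / ``"rural"``.
    """

    name: str
    levels: tuple[str, ...]
    probs: tuple[float, ...]
    by_stratum: dict[str, tuple[float, ...]] | None = None

    def validate(self) -> None:
        if len(self.levels) < 2:
            raise SimConfigError(f"covariate {self.name!r}: needs >= 2 levels")
        for tag, p in [("probs", self.probs)] + (
            [(f"by_stratum[{s}]", q) for s, q in self.by_stratum.items()]
            if self.by_stratum
            else []
        ):
            p = np.asarray(p, dtype=float)
            if len(p) != len(self.levels):
                raise SimConfigError(
                    f"covariate {self.name!r}: {tag} length != number of levels"
                )
            if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-9:
                raise SimConfigError(
                    f"covariate {self.name!r}: {tag} must lie in [0,1] and sum to 1"
                )

    def level_probs(self, stratum: str) -> np.ndarray:
        if self.by_stratum and stratum in self.by_stratum:
            return np.asarray(self.by_stratum[stratum], dtype=float)
        return np.asarray(self.probs, dtype=float)


def _default_covariates() -> tuple[CovariateSpec, ...]:
    return (CovariateSpec("sex", ("male", "female"), (0.5, 0.5)),)


def _default_coefficients() -> dict[str, float]:
    # Baseline (urban male) log-odds -2.50, female aOR 0.75, rural aOR 1.28:
    # population outcome rate ~0.09 under the default frame.
    return {"intercept": -2.50, "sex=female": -0.29, "residence=rural": 0.25}


@dataclass(frozen=True)
class SimConfig:
    """Population frame, outcome model, and sampling design parameters.

    ``children_sampled_per_cluster`` may be a single count or a
    per-stratum mapping; the defaults sample fewer children per urban
    cluster (urban households hold fewer young children), so design
    weights vary by stratum as in the real survey.
    """

    n_clusters_total: int = 500
    children_per_cluster: int = 120
    urban_fraction: float = 0.15
    true_coefficients: dict[str, float] = field(default_factory=_default_coefficients)
    cluster_effect_sd: float = 0.5
    covariates: tuple[CovariateSpec, ...] = field(default_factory=_default_covariates)
    sampled_clusters: int = 100
    children_sampled_per_cluster: int | dict[str, int] = field(
        default_factory=lambda: {"urban": 12, "rural": 22}
    )
    informativeness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters_total < 1:
            raise SimConfigError("n_clusters_total: must be >= 1")
        if self.children_per_cluster < 1:
            raise SimConfigError("children_per_cluster: must be >= 1")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise SimConfigError("urban_fraction: must lie in [0, 1]")
        if self.cluster_effect_sd < 0:
            raise SimConfigError("cluster_effect_sd: must be >= 0")
        if not 1 <= self.sampled_clusters <= self.n_clusters_total:
            raise SimConfigError(
                "sampled_clusters: must satisfy 1 <= K <= n_clusters_total"
            )
        for n_c in self._stage2_targets().values():
            if not 1 <= n_c <= self.children_per_cluster:
                raise SimConfigError(
                    "children_sampled_per_cluster: must satisfy "
                    "1 <= n_c <= children_per_cluster"
                )
        if "intercept" not in self.true_coefficients:
            raise SimConfigError("true_coefficients: must include 'intercept'")
        names = {c.name for c in self.covariates}
        if "residence" in names or "stratum" in names:
            raise SimConfigError(
                "covariates: 'residence'/'stratum' are emitted automatically"
            )
        for cov in self.covariates:
            cov.validate()

    def _stage2_targets(self) -> dict[str, int]:
        if isinstance(self.children_sampled_per_cluster, dict):
            unknown = set(self.children_sampled_per_cluster) - set(STRATA)
            if unknown:
                raise SimConfigError(
                    f"children_sampled_per_cluster: unknown strata {sorted(unknown)}"
                )
            return {s: int(v) for s, v in self.children_sampled_per_cluster.items()}
        return {s: int(self.children_sampled_per_cluster) for s in STRATA}

    def stage2_target(self, stratum: str) -> int:
        targets = self._stage2_targets()
        if stratum not in targets:
            raise SimConfigError(
                f"children_sampled_per_cluster: no rule for stratum {stratum!r}"
            )
        return targets[stratum]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Derive independent substreams so stages regenerate independently."""
    pop, stage1, stage2 = np.random.SeedSequence(seed).spawn(3)
    return {
        "population": np.random.default_rng(pop),
        "stage1": np.random.default_rng(stage1),
        "stage2": np.random.default_rng(stage2),
    }


def _linear_predictor(frame: pd.DataFrame, coefficients: dict[str, float]) -> np.ndarray:
    eta = np.full(len(frame), coefficients["intercept"], dtype=float)
    for term, beta in coefficients.items():
        if term == "intercept":
            continue
        name, _, level = term.partition("=")
        if not level:
            raise SimConfigError(f"true_coefficients: malformed term {term!r}")
        column = "residence" if name in ("residence", "stratum") else name
        if column not in frame.columns:
            raise SimConfigError(f"true_coefficients: unknown covariate {name!r}")
        eta += beta * (frame[column].to_numpy() == level)
    return eta


def generate_population(config: SimConfig) -> pd.DataFrame:
    """Generate the census frame of children, one row per child.

    Columns: ``child_id``, ``cluster_id``, ``stratum``, ``residence``
    (mirrors the stratum, so it can enter models as a covariate), the
    configured covariates, the cluster random intercept
    ``cluster_effect``, the child's ``true_prob``, and the realized
    binary outcome ``y``.  Deterministic given ``config.seed``.
    """
    rng = _streams(config.seed)["population"]
    n_urban = int(round(config.urban_fraction * config.n_clusters_total))
    strata = np.where(np.arange(config.n_clusters_total) < n_urban, "urban", "rural")
    u = rng.normal(0.0, config.cluster_effect_sd, size=config.n_clusters_total)

    m = config.children_per_cluster
    cluster_id = np.repeat(np.arange(config.n_clusters_total), m)
    frame = pd.DataFrame(
        {
            "child_id": np.arange(len(cluster_id)),
            "cluster_id": cluster_id,
            "stratum": strata[cluster_id],
        }
    )
    frame["residence"] = frame["stratum"]
    for cov in config.covariates:
        values = np.empty(len(frame), dtype=object)
        for stratum in STRATA:
            mask = frame["stratum"].to_numpy() == stratum
            if mask.any():
                values[mask] = rng.choice(
                    cov.levels, size=int(mask.sum()), p=cov.level_probs(stratum)
                )
        frame[cov.name] = values

    frame["cluster_effect"] = u[cluster_id]
    eta = _linear_predictor(frame, config.true_coefficients) + frame[
        "cluster_effect"
    ].to_numpy()
    frame["true_prob"] = expit(eta)
    frame["y"] = (rng.random(len(frame)) < frame["true_prob"].to_numpy()).astype(int)
    return frame


def _allocate_clusters(counts: dict[str, int], total: int) -> dict[str, int]:
    """Proportional (largest-remainder) allocation of ``total`` clusters."""
    grand = sum(counts.values())
    quotas = {s: total * c / grand for s, c in counts.items()}
    alloc = {s: int(np.floor(q)) for s, q in quotas.items()}
    remainder = total - sum(alloc.values())
    order = sorted(counts, key=lambda s: quotas[s] - alloc[s], reverse=True)
    for s in order[:remainder]:
        alloc[s] += 1
    for s, k in alloc.items():
        if k > counts[s]:  # spill over into the other stratum
            alloc[s] = counts[s]
    spill = total - sum(alloc.values())
    for s in order:
        room = counts[s] - alloc[s]
        take = min(room, spill)
        alloc[s] += take
        spill -= take
    return alloc


def draw_two_stage_sample(
    pop: pd.DataFrame, config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a two-stage stratified cluster sample from the frame.

    Stage one draws ``sampled_clusters`` clusters by simple random
    sampling without replacement within strata, allocated proportionally
    to each stratum's cluster count.  Stage two draws children without
    replacement within each selected cluster; the realized per-cluster
    count is ``n_c = round(N_c * expit(logit(q_h) + informativeness * u_c))``
    where ``q_h`` is the stratum's target sampling fraction, so at
    ``informativeness = 0`` exactly the configured number of children is
    drawn.  Every child record carries ``weight = N_c / n_c``.

    Parameters
    ----------
    pop : DataFrame
        Output of :func:`generate_population`.
    config : SimConfig
        The design; ``config.seed`` drives the draw unless ``seed``
        overrides it (the population stream is never consumed here, so
        repeated draws from one frame are independent replicates).

    Returns
    -------
    sample : DataFrame
        Child records with columns ``child_id, cluster_id, stratum, y,
        <covariates>, weight``.
    clusters : DataFrame
        One row per selected cluster: ``cluster_id, stratum, N_c, n_c``.
    """
    streams = _streams(config.seed if seed is None else seed)
    rng1, rng2 = streams["stage1"], streams["stage2"]

    info = pop.groupby("cluster_id").agg(
        stratum=("stratum", "first"), cluster_effect=("cluster_effect", "first")
    )
    if config.sampled_clusters > len(info):
        raise SimConfigError("sampled_clusters: exceeds clusters in the frame")
    counts = info["stratum"].value_counts().to_dict()
    alloc = _allocate_clusters(counts, config.sampled_clusters)

    chosen: list[np.ndarray] = []
    for stratum in STRATA:
        if counts.get(stratum, 0) == 0 or alloc.get(stratum, 0) == 0:
            continue
        ids = info.index[info["stratum"] == stratum].to_numpy()
        chosen.append(rng1.choice(ids, size=alloc[stratum], replace=False))
    selected = np.sort(np.concatenate(chosen))

    member_index = pop.groupby("cluster_id").indices
    cluster_rows: list[dict] = []
    take_positions: list[np.ndarray] = []
    for cid in selected:
        stratum = info.at[cid, "stratum"]
        N_c = len(member_index[cid])
        target = config.stage2_target(stratum)
        if target > N_c:
            raise SimConfigError(
                f"children_sampled_per_cluster: n_c={target} exceeds cluster "
                f"population {N_c} (cluster {cid})"
            )
        q = target / N_c
        if config.informativeness != 0.0:
            q = float(
                expit(logit(q) + config.informativeness * info.at[cid, "cluster_effect"])
            )
        n_c = int(np.clip(round(N_c * q), 1, N_c))
        take = rng2.choice(member_index[cid], size=n_c, replace=False)
        take_positions.append(np.sort(take))
        cluster_rows.append(
            {"cluster_id": cid, "stratum": stratum, "N_c": float(N_c), "n_c": n_c}
        )

    clusters = pd.DataFrame(cluster_rows)
    sample = pop.iloc[np.concatenate(take_positions)].reset_index(drop=True)
    sample = sample.merge(
        clusters.assign(weight=clusters["N_c"] / clusters["n_c"])[
            ["cluster_id", "weight"]
        ],
        on="cluster_id",
    )
    keep = ["child_id", "cluster_id", "stratum", "residence"]
    keep += [c.name for c in config.covariates] + ["y", "weight"]
    return sample[keep], clusters


def population_rate(pop: pd.DataFrame) -> float:
    """Mean realized outcome over the whole frame — the reference rate."""
    if len(pop) == 0:
        raise ValueError("population frame is empty")
    return float(pop["y"].mean())
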