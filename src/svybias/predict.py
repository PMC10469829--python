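"""Predicted national outcome rates and their bias.

Two printed estimators are implemented.  The unweighted rate is the
mean of all fitted probabilities, ``pi_hat = sum(pi_hat_ic) / n``, with
binomial variance ``pi_hat (1 - pi_hat) / n``.  The cluster-weighted
rate averages cluster-specific rates with the terms ``n_c / m_bar``:

    pi_hat* = sum_c pi_hat_c (n_c / m_bar) / K,
    var(pi_hat*) = (1/K) sum_c (pi_hat_c - pi_hat*)^2 / (K-1) * (n_c / m_bar)^2.

As printed, the cluster-weighted point estimate is algebraically
identical to the unweighted one (``sum_c pi_hat_c n_c / (K m_bar) =
sum pi_hat_ic / n``); the implementation preserves that identity and
additionally offers a population-weighted variant
``pi_hat_pop = sum_c pi_hat_c N_c / sum_c N_c`` — cluster design
weights instead of sample shares — behind an explicit function, as an
interpretation of weighting the cluster rates by what each cluster
represents rather than by how many children it contributed.

Bias is ``estimate - reference``, the reference being either a known
population rate (synthetic data) or a reported raw rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from svybias.logit import LogitFit, NotConvergedError
from svybias.weights import cluster_weight_summary, finite_population_correction

__all__ = [
    "PredictionEstimate",
    "cluster_rates",
    "predict_rate_unweighted",
    "predict_rate_cluster_weighted",
    "predict_rate_population_weighted",
    "bias_of_estimate",
    "apply_fpc",
]


@dataclass(frozen=True)
class PredictionEstimate:
    """An overall predicted rate with its standard error."""

    method: str
    estimate: float
    variance: float
    n: int
    K: int
    cluster_rates: pd.DataFrame

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))

    def rounded(self, digits: int = 3) -> tuple[float, float]:
        """(estimate, SE) at reporting precision."""
        return round(self.estimate, digits), round(self.se, digits)


def cluster_rates(fit: LogitFit, data: pd.DataFrame) -> pd.DataFrame:
    """Cluster-specific predicted rates: mean fitted probability per cluster.

    Returns a DataFrame with columns ``cluster_id``, ``n_c``, ``rate``.
    """
    if not fit.converged:
        raise NotConvergedError("prediction requires a converged fit")
    probs = fit.predict(data)
    out = (
        pd.DataFrame({"cluster_id": data["cluster_id"].to_numpy(), "prob": probs})
        .groupby("cluster_id")
        .agg(n_c=("prob", "size"), rate=("prob", "mean"))
        .reset_index()
    )
    return out


def predict_rate_unweighted(fit: LogitFit, data: pd.DataFrame) -> PredictionEstimate:
    """Unweighted predicted rate: mean fitted probability, binomial variance."""
    if len(data) == 0:
        raise ValueError("no records to predict from")
    rates = cluster_rates(fit, data)
    n = int(rates["n_c"].sum())
    est = float((rates["rate"] * rates["n_c"]).sum() / n)
    var = est * (1.0 - est) / n
    return PredictionEstimate(
        method="unweighted",
        estimate=est,
        variance=var,
        n=n,
        K=len(rates),
        cluster_rates=rates,
    )


def predict_rate_cluster_weighted(rates: pd.DataFrame) -> PredictionEstimate:
    """Cluster-weighted rate with terms ``n_c / m_bar`` and its variance.

    With a single cluster the variance is undefined; the estimate is
    still computed and the variance reported as NaN.
    """
    if len(rates) == 0:
        raise ValueError("no cluster rates supplied")
    summary = cluster_weight_summary(rates)
    K = summary.K
    terms = summary.terms.to_numpy()
    pi_c = rates.set_index("cluster_id")["rate"].to_numpy()
    est = float(np.sum(pi_c * terms) / K)
    if K < 2:
        var = float("nan")
    else:
        var = float(np.sum((pi_c - est) ** 2 / (K - 1) * terms**2) / K)
    return PredictionEstimate(
        method="cluster_weighted",
        estimate=est,
        variance=var,
        n=int(rates["n_c"].sum()),
        K=K,
        cluster_rates=rates,
    )


def predict_rate_population_weighted(
    rates: pd.DataFrame, clusters: pd.DataFrame
) -> PredictionEstimate:
    """Population-weighted variant: cluster rates weighted by ``N_c``.

    ``pi_hat_pop = sum_c pi_hat_c N_c / sum_c N_c`` weights each
    cluster by the number of population children it represents rather
    than by its realized sample share, removing the distortion an
    unequal-probability design induces in the sample's cluster
    composition.  The variance uses the cluster-weighted form with the
    terms ``N_c / mean(N_c)``.  This is an explicit, opt-in
    interpretation, not one of the printed estimators.
    """
    if len(rates) == 0:
        raise ValueError("no cluster rates supplied")
    merged = rates.merge(clusters[["cluster_id", "N_c"]], on="cluster_id", how="left")
    if merged["N_c"].isna().any():
        missing = merged.loc[merged["N_c"].isna(), "cluster_id"].tolist()
        raise ValueError(f"clusters without N_c: {missing}")
    N = merged["N_c"].to_numpy(dtype=float)
    pi_c = merged["rate"].to_numpy()
    K = len(merged)
    terms = N / N.mean()
    est = float(np.sum(pi_c * terms) / K)
    if K < 2:
        var = float("nan")
    else:
        var = float(np.sum((pi_c - est) ** 2 / (K - 1) * terms**2) / K)
    return PredictionEstimate(
        method="population_weighted",
        estimate=est,
        variance=var,
        n=int(rates["n_c"].sum()),
        K=K,
        cluster_rates=rates,
    )


def bias_of_estimate(
    estimate: float, reference_rate: float, reference_unit: str = "proportion"
) -> float:
    """Bias ``estimate - reference``; per-1000 references are converted."""
    if reference_unit == "per_1000":
        reference_rate = reference_rate / 1000.0
    elif reference_unit != "proportion":
        raise ValueError("reference_unit must be 'proportion' or 'per_1000'")
    if not 0.0 <= estimate <= 1.0 or not 0.0 <= reference_rate <= 1.0:
        raise ValueError("estimate and reference must lie in [0, 1]")
    return estimate - reference_rate


def apply_fpc(pred: PredictionEstimate, population_size: float) -> PredictionEstimate:
    """Multiply the SE by the finite population correction (opt-in)."""
    f = finite_population_correction(population_size, pred.n)
    return replace(pred, variance=pred.variance * f * f)
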