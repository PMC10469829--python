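"""Sampling weights and survey-design constants.

The design weight of a sampled child is ``w_ic = N_c / n_c``: the
cluster's population count of eligible children divided by the number
sampled there.  ``N_c`` may be fractional, because in practice it is
derived by dividing a census total by the number of enumeration
clusters.  The finite population correction ``sqrt((N - n) / (N - 1))``
is computed for reporting but is not applied to any variance by
default, since it is approximately 1 for national surveys; see
:func:`svybias.predict.apply_fpc` for the opt-in multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClusterWeightSummary",
    "per_cluster_population",
    "child_weight",
    "finite_population_correction",
    "cluster_weight_summary",
]


@dataclass(frozen=True)
class ClusterWeightSummary:
    """Cluster weighting terms ``n_c / m_bar`` for the weighted rate.

    ``m_bar`` is the average number of sampled children per cluster;
    the per-cluster terms average to 1 by construction.
    """

    K: int
    m_bar: float
    terms: pd.Series  # indexed by cluster_id


def per_cluster_population(total_children: float, total_clusters: int) -> float:
    """Average cluster population ``N_c`` from census totals, unrounded."""
    if total_children <= 0:
        raise ValueError("total_children must be positive")
    if total_clusters <= 0:
        raise ValueError("total_clusters must be positive")
    return total_children / total_clusters


def child_weight(N_c: float, n_c: int) -> float:
    """Design weight ``N_c / n_c`` shared by all children of a cluster."""
    if N_c <= 0:
        raise ValueError("N_c must be positive")
    if n_c < 1:
        raise ValueError("n_c must be >= 1")
    return N_c / n_c


def finite_population_correction(N: float, n: int) -> float:
    """FPC factor ``sqrt((N - n) / (N - 1))`` for a sample of n from N."""
    if N < 2:
        raise ValueError("population size N must be >= 2")
    if not 1 <= n <= N:
        raise ValueError("sample size n must satisfy 1 <= n <= N")
    return float(np.sqrt((N - n) / (N - 1)))


def cluster_weight_summary(clusters: pd.DataFrame) -> ClusterWeightSummary:
    """Compute ``m_bar`` and the per-cluster terms ``n_c / m_bar``.

    Parameters
    ----------
    clusters : DataFrame
        Cluster frame with columns ``cluster_id`` and ``n_c``.
    """
    if len(clusters) == 0:
        raise ValueError("cluster set is empty")
    n_c = clusters.set_index("cluster_id")["n_c"].astype(float)
    K = len(n_c)
    m_bar = float(n_c.sum()) / K
    return ClusterWeightSummary(K=K, m_bar=m_bar, terms=n_c / m_bar)
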