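"""k-means partitioning of an activation time course and Fisher enrichment
of CLIP target sets across the clusters.

Genes are z-standardized across timepoints, partitioned by seeded k-means
(k-means++ initialization, best of ``n_init`` starts), and each cluster is
tested for enrichment/depletion of a target gene set with a two-sided
Fisher exact test, BH-corrected across clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "ClusterEnrichment",
    "zscore_timecourse",
    "kmeans_timecourse",
    "fisher_cluster_enrichment",
    "summarize_clusters",
]


@dataclass
class ClusterEnrichment:
    cluster: int
    n_in_cluster: int
    n_targets_in_cluster: int
    odds_ratio: float  # inf encoded as np.inf
    p_value: float
    q_value: float
    direction: str  # "enriched" / "depleted"


def zscore_timecourse(tm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across timepoints; constant genes map to 0."""
    if tm.isna().any().any():
        raise ValueError("time-course matrix contains missing values")
    mu = tm.mean(axis=1)
    sd = tm.std(axis=1, ddof=0).replace(0, 1.0)
    return tm.sub(mu, axis=0).div(sd, axis=0)


def kmeans_timecourse(
    tm: pd.DataFrame, k: int = 20, n_init: int = 10, seed: int = 0
) -> pd.Series:
    """Cluster genes by expression pattern; returns gene -> cluster label.

    Standardizes per gene first, then runs Lloyd's k-means with k-means++
    initialization, keeping the best of ``n_init`` seeded starts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(tm):
        raise ValueError(f"k={k} exceeds number of genes ({len(tm)})")
    z = zscore_timecourse(tm)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(z.to_numpy())
    return pd.Series(labels, index=tm.index, name="cluster")


def fisher_cluster_enrichment(
    assignments: pd.Series, target_set
) -> list[ClusterEnrichment]:
    """Two-sided Fisher exact test of target membership per cluster.

    The 2x2 table for cluster c is [[targets in c, non-targets in c],
    [targets elsewhere, non-targets elsewhere]] over the clustered-gene
    universe; BH across the k clusters.
    """
    targets = set(target_set) & set(assignments.index)
    if not targets:
        raise ValueError("target set is empty within the clustered universe")
    n_total = len(assignments)
    n_targ = len(targets)
    is_target = assignments.index.isin(targets)
    rows = []
    for c in sorted(assignments.unique()):
        in_c = (assignments == c).to_numpy()
        a = int((in_c & is_target).sum())
        b = int(in_c.sum()) - a
        c2 = n_targ - a
        d = n_total - a - b - c2
        odds, p = stats.fisher_exact([[a, b], [c2, d]], alternative="two-sided")
        expected = in_c.sum() * n_targ / n_total
        rows.append((int(c), int(in_c.sum()), a, float(odds), float(p),
                     "enriched" if a >= expected else "depleted"))
    qvals = stats.false_discovery_control([r[4] for r in rows], method="bh")
    return [
        ClusterEnrichment(c, n, a, odds, p, float(q), direction)
        for (c, n, a, odds, p, direction), q in zip(rows, qvals)
    ]


def summarize_clusters(
    assignments: pd.Series,
    enrichments: list[ClusterEnrichment],
    tm: pd.DataFrame,
    n_top: int = 3,
) -> pd.DataFrame:
    """Mean standardized expression profile of the most enriched and most
    depleted clusters.

    Within each direction, clusters rank by p ascending, ties broken by
    |log odds ratio| descending then cluster id.  Returns one row per
    selected cluster with the position-wise mean profile.
    """
    z = zscore_timecourse(tm)

    def sort_key(e: ClusterEnrichment):
        lor = np.abs(np.log(e.odds_ratio)) if 0 < e.odds_ratio < np.inf else np.inf
        return (e.p_value, -lor, e.cluster)

    rows = []
    for direction in ("enriched", "depleted"):
        group = sorted(
            (e for e in enrichments if e.direction == direction), key=sort_key
        )
        if len(group) < n_top:
            import logging

            logging.getLogger(__name__).warning(
                "only %d %s clusters available (wanted %d)",
                len(group), direction, n_top,
            )
        for e in group[:n_top]:
            members = assignments.index[assignments == e.cluster]
            profile = z.loc[members].mean(axis=0)
            rows.append(
                pd.Series(profile, name=(direction, e.cluster))
            )
    out = pd.DataFrame(rows)
    out.index = pd.MultiIndex.from_tuples(out.index, names=["direction", "cluster"])
    return out
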