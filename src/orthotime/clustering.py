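"""Clustering of standardized profiles and cross-species cluster comparison.

Profiles are clustered in one species (mouse-seeded or human-seeded) or on
the concatenation of both species' interpolated profiles (co-clustered);
orthologous genes inherit the cluster label, and per-cluster mean +- SD
summary profiles are computed for both species on a common equidistant
grid.  Because profiles are unit-SD, Euclidean k-means distance is
monotonically equivalent to correlation distance, so k-means recovers
correlation-coherent shape clusters deterministically under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .profile_compare import interpolate_profiles, _pearson_rows

log = logging.getLogger(__name__)

MODES = ("mouse", "human", "co")


@dataclass
class GeneClusterSet:
    """A partition of ortholog pairs into co-expression clusters.

    ``assignments`` has columns ``human_gene``, ``mouse_gene``,
    ``cluster`` (labels 1..K, ordered by decreasing size).  ``summaries``
    maps ``(cluster, species)`` to a DataFrame with columns ``day``,
    ``mean``, ``sd`` on the common grid.
    """

    mode: str
    assignments: pd.DataFrame
    summaries: dict[tuple[int, str], pd.DataFrame] = field(default_factory=dict)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(self.assignments["cluster"].unique())

    def members(self, cluster: int) -> pd.DataFrame:
        return self.assignments[self.assignments["cluster"] == cluster]

    def sizes(self) -> pd.Series:
        return self.assignments["cluster"].value_counts().sort_index()


def _feature_matrix(
    human_profiles, mouse_profiles, pairs, mode,
    human_interval, mouse_interval, n_grid,
):
    if mode == "mouse":
        return mouse_profiles.loc[pairs["mouse_gene"]].to_numpy()
    if mode == "human":
        return human_profiles.loc[pairs["human_gene"]].to_numpy()
    if mode == "co":
        h = interpolate_profiles(
            human_profiles.loc[pairs["human_gene"]], *human_interval, n_grid
        ).to_numpy()
        m = interpolate_profiles(
            mouse_profiles.loc[pairs["mouse_gene"]], *mouse_interval, n_grid
        ).to_numpy()
        return np.hstack([h, m])
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def _auto_k(x: np.ndarray, k_range, seed: int) -> int:
    best_k, best_score = k_range[0], -np.inf
    for k in range(k_range[0], k_range[1] + 1):
        if k >= len(x):
            break
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(x)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(x, labels)
        if score > best_score:
            best_k, best_score = k, score
    return best_k


def cluster_profiles(
    human_profiles: pd.DataFrame,
    mouse_profiles: pd.DataFrame,
    pairs: pd.DataFrame,
    mode: str = "mouse",
    k: int | str = "auto",
    seed: int = 0,
    min_cluster_size: int = 30,
    human_interval: tuple[float, float] = (0.0, 21.0),
    mouse_interval: tuple[float, float] = (0.0, 10.0),
    n_grid: int = 11,
) -> GeneClusterSet:
    """Cluster ortholog pairs by profile shape.

    ``mode`` selects the feature space: one species' standardized profiles
    (``"mouse"`` / ``"human"``) or the concatenated interpolated profiles
    of both (``"co"``).  ``k="auto"`` chooses the cluster count by mean
    silhouette over 2..12.  Clusters smaller than ``min_cluster_size`` are
    merged into the nearest remaining centroid; final labels are 1..K in
    decreasing size order.
    """
    keep = pairs["human_gene"].isin(human_profiles.index) & pairs[
        "mouse_gene"
    ].isin(mouse_profiles.index)
    pairs = pairs.loc[keep].reset_index(drop=True)
    if len(pairs) < 2 * min_cluster_size:
        raise ValueError("need at least 2 * min_cluster_size ortholog pairs")

    x = _feature_matrix(
        human_profiles, mouse_profiles, pairs, mode,
        human_interval, mouse_interval, n_grid,
    )
    if k == "auto":
        k = _auto_k(x, (2, 12), seed)
    k = int(k)
    if k < 1 or k > len(x):
        raise ValueError(f"infeasible cluster count k={k} for {len(x)} pairs")
    if k == 1:
        labels = np.zeros(len(x), dtype=int)
    else:
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(x)

    # merge undersized clusters into the nearest remaining centroid
    while True:
        counts = pd.Series(labels).value_counts()
        small = counts[counts < min_cluster_size]
        if small.empty or len(counts) == 1:
            break
        victim = small.index[np.argmin(small.to_numpy())]
        centroids = {
            c: x[labels == c].mean(axis=0) for c in counts.index if c != victim
        }
        members = np.where(labels == victim)[0]
        cids = list(centroids)
        cmat = np.stack([centroids[c] for c in cids])
        for i in members:
            labels[i] = cids[int(np.argmin(((cmat - x[i]) ** 2).sum(axis=1)))]
        log.info("merged undersized cluster (%d members)", len(members))

    # relabel 1..K by decreasing size (ties: smaller original label first)
    counts = pd.Series(labels).value_counts().sort_index()
    order = counts.sort_values(ascending=False, kind="mergesort").index
    relabel = {old: new for new, old in enumerate(order, start=1)}
    assignments = pairs.copy()
    assignments["cluster"] = [relabel[l] for l in labels]

    result = GeneClusterSet(mode=mode, assignments=assignments)
    for c in result.cluster_ids:
        members = result.members(c)
        result.summaries.update(
            summarize_cluster(
                c, members, human_profiles, mouse_profiles,
                human_interval, mouse_interval, n_grid,
            )
        )
    return result


def summarize_cluster(
    cluster_id: int,
    members: pd.DataFrame,
    human_profiles: pd.DataFrame,
    mouse_profiles: pd.DataFrame,
    human_interval: tuple[float, float] = (0.0, 21.0),
    mouse_interval: tuple[float, float] = (0.0, 10.0),
    n_grid: int = 11,
) -> dict[tuple[int, str], pd.DataFrame]:
    """Per-species pointwise mean and SD band of a cluster's profiles."""
    if members.empty:
        raise ValueError("cluster has no members")
    out = {}
    for species, profiles, col, interval in (
        ("human", human_profiles, "human_gene", human_interval),
        ("mouse", mouse_profiles, "mouse_gene", mouse_interval),
    ):
        grid = interpolate_profiles(profiles.loc[members[col]], *interval, n_grid)
        out[(cluster_id, species)] = pd.DataFrame(
            {
                "day": np.asarray(grid.columns, dtype=float),
                "mean": grid.mean(axis=0).to_numpy(),
                "sd": grid.std(axis=0, ddof=0).to_numpy(),
            }
        )
    return out


def compare_cluster_profiles(cluster_set: GeneClusterSet):
    """Correlate human vs mouse cluster mean profiles.

    Returns ``(table, sorted_curve)``: per-cluster PCC of the two mean
    profiles on the common grid, and the sorted correlation-vs-percentile
    curve used to compare clusterings with different cluster counts.
    """
    rows = []
    for c in cluster_set.cluster_ids:
        h = cluster_set.summaries[(c, "human")]["mean"].to_numpy()
        m = cluster_set.summaries[(c, "mouse")]["mean"].to_numpy()
        r = _pearson_rows(h[None, :], m[None, :])[0]
        rows.append(
            {"cluster": c, "n_genes": len(cluster_set.members(c)), "pcc": r}
        )
    table = pd.DataFrame(rows)
    sorted_pcc = np.sort(table["pcc"].to_numpy())
    curve = pd.DataFrame(
        {
            "percentile": 100.0 * (np.arange(1, len(sorted_pcc) + 1))
            / len(sorted_pcc),
            "pcc": sorted_pcc,
        }
    )
    return table, curve


def sorted_correlation_curve(pccs) -> pd.DataFrame:
    """Sorted correlation values against percentile of pairs."""
    v = np.sort(np.asarray(pccs, dtype=float))
    return pd.DataFrame(
        {"percentile": 100.0 * np.arange(1, len(v) + 1) / len(v), "pcc": v}
    )
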