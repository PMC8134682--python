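"""Resampling-based consensus clustering with delta-area k selection.

For each candidate k, items are repeatedly subsampled and clustered; the
consensus matrix records how often each pair co-clusters among the runs where
both were sampled. The preferred k maximizes the relative gain in area under
the consensus-value CDF (the standard delta-area criterion). Final labels at
each k come from hierarchical clustering of (1 - consensus).
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import kruskal
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, labels, CDF areas, and the chosen k."""

    consensus: dict[int, pd.DataFrame]
    labels: dict[int, pd.Series]
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int
    never_cosampled: pd.DataFrame = field(repr=False, default=None)
    reps: int = 0
    subsample_fraction: float = 0.8
    seed: int | None = None

    def __post_init__(self) -> None:
        for k, mat in self.consensus.items():
            v = mat.to_numpy()
            if not np.allclose(v, v.T):
                raise ValueError(f"consensus matrix for k={k} not symmetric")
            if (v < -1e-12).any() or (v > 1 + 1e-12).any():
                raise ValueError("consensus entries must lie in [0, 1]")


def _cluster_subsample(
    x: np.ndarray, ks: Sequence[int], method: str, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    if method == "ward":
        link = linkage(x, method="ward")
        return {k: fcluster(link, t=k, criterion="maxclust") for k in ks}
    if method == "kmeans":
        return {
            k: KMeans(
                n_clusters=k, n_init=3, random_state=int(rng.integers(2**31 - 1))
            ).fit_predict(x)
            for k in ks
        }
    raise ValueError(f"unknown base method {method!r}")


def consensus_cluster(
    data: pd.DataFrame,
    k_range: Sequence[int] = range(2, 7),
    reps: int = 1000,
    subsample: float = 0.8,
    base_method: str = "ward",
    seed: int | None = None,
) -> ConsensusResult:
    """Consensus-cluster the rows of ``data`` (items x features).

    The default base clusterer is hierarchical clustering with Euclidean
    distance and Ward linkage; ``base_method="kmeans"`` is the alternative.
    """
    ks = sorted(set(int(k) for k in k_range))
    n = len(data)
    if n < 10:
        raise ValueError("need at least 10 items to consensus-cluster")
    if reps < 10:
        raise ValueError("need at least 10 resampling repetitions")
    if max(ks) >= n:
        raise ValueError("largest k must be smaller than the number of items")
    rng = np.random.default_rng(seed)
    x = data.to_numpy(dtype=float)
    m = max(2, int(round(subsample * n)))
    cosampled = np.zeros((n, n))
    coclustered = {k: np.zeros((n, n)) for k in ks}
    for _ in range(reps):
        idx = rng.choice(n, size=m, replace=False)
        grid = np.ix_(idx, idx)
        cosampled[grid] += 1
        assignments = _cluster_subsample(x[idx], ks, base_method, rng)
        for k, lab in assignments.items():
            coclustered[k][grid] += lab[:, None] == lab[None, :]

    never = cosampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        logger.warning(
            "%d item pairs were never co-sampled; their consensus is undefined "
            "and reported as 0", int(never.sum()) // 2,
        )
    safe = np.where(cosampled > 0, cosampled, 1.0)

    consensus, labels, cdf_area = {}, {}, {}
    for k in ks:
        mat = coclustered[k] / safe
        mat[never] = 0.0
        mat = (mat + mat.T) / 2.0
        np.fill_diagonal(mat, 1.0)
        consensus[k] = pd.DataFrame(mat, index=data.index, columns=data.index)
        dist = squareform(1.0 - mat, checks=False)
        link = linkage(dist, method="average")
        labels[k] = pd.Series(
            fcluster(link, t=k, criterion="maxclust"), index=data.index, name="cluster"
        )
        # area under the CDF of off-diagonal consensus values = 1 - mean value
        tri = mat[np.triu_indices(n, k=1)]
        cdf_area[k] = float(1.0 - tri.mean())

    delta_area: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta_area[k] = cdf_area[k]
        else:
            prev = cdf_area[ks[i - 1]]
            delta_area[k] = (cdf_area[k] - prev) / prev if prev > 0 else 0.0
    # The delta-area curve stays high up to the true k and collapses after
    # it; the raw argmax is biased to k=2 (whose delta is an absolute area),
    # so the chosen k is where the curve drops most sharply.
    if len(ks) == 1:
        chosen_k = ks[0]
    else:
        eps = 1e-12
        drop = {
            k: max(delta_area[k], eps) / max(delta_area[ks[i + 1]], eps)
            for i, k in enumerate(ks[:-1])
        }
        chosen_k = max(drop, key=drop.get)
    return ConsensusResult(
        consensus=consensus,
        labels=labels,
        cdf_area=cdf_area,
        delta_area=delta_area,
        chosen_k=chosen_k,
        never_cosampled=pd.DataFrame(never, index=data.index, columns=data.index),
        reps=reps,
        subsample_fraction=subsample,
        seed=seed,
    )


def canonicalize_labels(labels: pd.Series, score: pd.Series) -> pd.Series:
    """Rename integer cluster labels to A, B, C... by descending mean score.

    Makes labels reproducible across runs: cluster A is always the one with
    the highest mean immune score.
    """
    means = score.groupby(labels).mean().sort_values(ascending=False)
    mapping = {lab: string.ascii_uppercase[i] for i, lab in enumerate(means.index)}
    return labels.map(mapping).rename("cluster")


def cluster_fraction_summary(
    fractions: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Per-cluster medians/IQRs and a Kruskal-Wallis p-value per cell type.

    Clusters with fewer than 2 members make the test ill-posed for that cell
    type; p is then reported missing.
    """
    missing = set(fractions.index) - set(labels.index)
    if missing:
        raise ValueError(f"labels missing for samples: {sorted(missing)[:5]}")
    labels = labels.loc[fractions.index]
    clusters = sorted(labels.unique())
    small = any((labels == c).sum() < 2 for c in clusters)
    rows = []
    for ct in fractions.columns:
        row: dict = {"cell_type": ct}
        groups = []
        for c in clusters:
            vals = fractions.loc[labels == c, ct]
            row[f"median_{c}"] = vals.median()
            row[f"iqr_{c}"] = vals.quantile(0.75) - vals.quantile(0.25)
            groups.append(vals.to_numpy())
        if small:
            row["kw_stat"], row["kw_p"] = np.nan, np.nan
        else:
            flat = np.concatenate(groups)
            if np.all(flat == flat[0]):
                row["kw_stat"], row["kw_p"] = 0.0, 1.0
            else:
                try:
                    stat, p = kruskal(*groups)
                except ValueError:  # all values identical within float tolerance
                    stat, p = 0.0, 1.0
                row["kw_stat"], row["kw_p"] = float(stat), float(p)
        rows.append(row)
    return pd.DataFrame(rows).set_index("cell_type")
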