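"""Trajectory-level analyses of regional ECS growth curves.

Operates on a trajectory matrix: regions x age-grid values of the
fitted (sex-0) nodal EC strength curves, in the overall, excitatory, or
inhibitory variant.  Provides K-means clustering of the curves with a
stable label convention, K-selection diagnostics, the between-curve
correlation matrix with network-block summaries, early-life versus
adult variability, and the first-principal-component developmental
gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from lifespan_ec.io import Parcellation
from lifespan_ec.synth import inverse_transform_age


@dataclass
class TrajectoryMatrix:
    """Fitted regional growth curves on a shared transformed-age grid."""

    values: np.ndarray          # R x G
    region_ids: tuple[str, ...]
    grid_t: np.ndarray
    variant: str = "overall"    # overall | excitatory | inhibitory

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.grid_t = np.asarray(self.grid_t, dtype=float)
        if self.values.shape != (len(self.region_ids), len(self.grid_t)):
            raise ValueError("trajectory matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite trajectory values")

    @property
    def ages(self) -> np.ndarray:
        return inverse_transform_age(self.grid_t)


@dataclass
class ClusterResult:
    labels: np.ndarray          # 1..K per region
    centroids: np.ndarray       # K x G
    k: int
    inertia: float
    composition: pd.DataFrame | None = None  # % of each cluster per network


def cluster_trajectories(
    tm: TrajectoryMatrix,
    k: int = 5,
    n_init: int = 50,
    seed: int = 0,
    standardize: bool = False,
    parcellation: Parcellation | None = None,
) -> ClusterResult:
    """K-means clustering of the regional growth curves.

    Squared-Euclidean K-means on the raw curves (curves keep their
    amplitude differences unless ``standardize``); best of ``n_init``
    k-means++ restarts.  Labels are renumbered by descending centroid
    value at the final grid point so runs are comparable.  With a
    parcellation, the percentage composition of clusters per network is
    attached.
    """
    if k < 1:
        raise ValueError("k must be positive")
    X = tm.values
    if X.shape[0] <= k:
        raise ValueError("need more regions than clusters")
    if standardize:
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=1, keepdims=True)) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(X)
    order = np.argsort(-km.cluster_centers_[:, -1])  # descending final value
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[raw_labels]
    centroids = km.cluster_centers_[order]

    composition = None
    if parcellation is not None:
        net_of = [parcellation.network_of[r] for r in tm.region_ids]
        df = pd.DataFrame({"network": net_of, "cluster": labels})
        composition = (
            df.groupby("network")["cluster"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(index=list(parcellation.networks),
                     columns=range(1, k + 1), fill_value=0.0)
            * 100.0
        )
    return ClusterResult(
        labels=labels, centroids=centroids, k=k,
        inertia=float(km.inertia_), composition=composition,
    )


def select_k(
    tm: TrajectoryMatrix, k_range: range | tuple = range(2, 11), n_init: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Inertia and mean silhouette per K.

    Reports diagnostics only — the working K is pinned in configuration
    (default 5); the choice between similar K values is substantive, not
    automatic.
    """
    rows = []
    for k in k_range:
        if not 2 <= k <= tm.values.shape[0] - 1:
            raise ValueError(f"K={k} outside [2, R-1]")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(tm.values)
        rows.append(
            {
                "k": k,
                "inertia": float(km.inertia_),
                "silhouette": float(silhouette_score(tm.values, labels)),
            }
        )
    return pd.DataFrame(rows)


def trajectory_correlation(
    tm: TrajectoryMatrix, parcellation: Parcellation | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Pearson correlation between fitted curves (+ network-block means).

    Zero-variance curves get NaN rows/columns rather than an error.
    """
    X = tm.values
    sd = X.std(axis=1)
    corr = np.full((len(X), len(X)), np.nan)
    ok = sd > 0
    if ok.sum() >= 2:
        corr_ok = np.corrcoef(X[ok])
        corr[np.ix_(ok, ok)] = corr_ok
    corr_df = pd.DataFrame(corr, index=list(tm.region_ids), columns=list(tm.region_ids))

    blocks = None
    if parcellation is not None:
        member = np.array([parcellation.network_of[r] for r in tm.region_ids])
        nets = list(parcellation.networks)
        blocks = pd.DataFrame(index=nets, columns=nets, dtype=float)
        for a in nets:
            for b in nets:
                sub = corr[np.ix_(member == a, member == b)]
                if a == b:
                    mask = ~np.eye(sub.shape[0], dtype=bool)
                    sub = sub[mask]
                blocks.loc[a, b] = np.nanmean(sub) if sub.size else np.nan
    return corr_df, blocks


def early_late_sd(
    tm: TrajectoryMatrix, early_cutoff: float = 12.0, late_cutoff: float = 20.0
) -> pd.DataFrame:
    """Per-region SD of the fitted curve before/after the two age cutoffs.

    Quantifies whether trajectories vary more during development
    (age < early_cutoff years) than during adulthood (> late_cutoff).
    """
    ages = tm.ages
    early = ages < early_cutoff
    late = ages > late_cutoff
    if early.sum() < 3 or late.sum() < 3:
        raise ValueError("each age window needs at least 3 grid points")
    return pd.DataFrame(
        {
            "region": list(tm.region_ids),
            "sd_early": tm.values[:, early].std(axis=1),
            "sd_late": tm.values[:, late].std(axis=1),
        }
    ).set_index("region")


@dataclass
class GradientResult:
    loadings: np.ndarray              # unit-norm first principal axis, per region
    explained_variance_ratio: float
    region_ids: tuple[str, ...]
    network_summary: pd.DataFrame | None = None


def pca_gradient(
    tm: TrajectoryMatrix, parcellation: Parcellation | None = None
) -> GradientResult:
    """First-principal-component loading of the regional growth curves.

    Curves are centered per grid point (regions are the observations);
    the loading per region is its coordinate on the first principal
    axis.  The sign convention fixes the VIS-network mean loading to be
    non-negative when a parcellation with a VIS network is supplied
    (otherwise the largest-|loading| entry is made positive).
    """
    X = tm.values
    if X.shape[0] < 2:
        raise ValueError("need at least 2 regions")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.max(np.abs(Xc)) <= 1e-12 * max(1.0, np.max(np.abs(X))):
        raise ValueError("no variance across regions after centering")
    # regions x grid: loadings are the left singular vector
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = U[:, 0]
    evr = float(s[0] ** 2 / np.sum(s**2))

    if parcellation is not None and "VIS" in parcellation.networks:
        vis = [i for i, r in enumerate(tm.region_ids)
               if parcellation.network_of[r] == "VIS"]
        if vis and loadings[vis].mean() < 0:
            loadings = -loadings
    elif loadings[np.argmax(np.abs(loadings))] < 0:
        loadings = -loadings

    summary = None
    if parcellation is not None:
        member = [parcellation.network_of[r] for r in tm.region_ids]
        df = pd.DataFrame({"network": member, "loading": loadings})
        summary = (
            df.groupby("network")["loading"]
            .agg(["mean", "std", "count"])
            .reindex(list(parcellation.networks))
        )
    return GradientResult(
        loadings=loadings, explained_variance_ratio=evr,
        region_ids=tm.region_ids, network_summary=summary,
    )
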