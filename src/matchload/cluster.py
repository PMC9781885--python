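"""Normalize, reduce and cluster minute features into intensity zones.

The training path is: drop excluded / low-distance minutes, min-max scale
each feature, project onto principal components retaining a variance
target, fit K-means over a grid of cluster counts, pick k at the elbow of
the WCSS curve (maximal perpendicular distance from the chord joining the
curve's endpoints), and name the k=3 clusters low/middle/high from their
feature means. The fitted model is a plain JSON-serializable object so a
frozen model can score new games later.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from matchload.features import FEATURE_ORDER

logger = logging.getLogger(__name__)

LABELS = ("low", "middle", "high")
UNCLASSIFIED = "unclassified"


class ClusteringError(ValueError):
    pass


@dataclass
class IntensityModel:
    """Frozen normalization bounds, PCA basis, centroids and label map."""

    feature_order: list
    minmax_min: np.ndarray
    minmax_max: np.ndarray
    pca_mean: np.ndarray
    pca_components: np.ndarray  # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    n_components: int
    kmeans_centroids: np.ndarray  # (k, n_components)
    label_map: dict  # cluster index -> label
    training_meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.kmeans_centroids.shape[0]

    def scale(self, X: np.ndarray) -> np.ndarray:
        span = self.minmax_max - self.minmax_min
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (X - self.minmax_min) / span
        Z[:, span == 0] = 0.0
        return Z

    def project(self, Z: np.ndarray) -> np.ndarray:
        return (Z - self.pca_mean) @ self.pca_components.T

    def to_json(self, path) -> None:
        payload = {
            "feature_order": self.feature_order,
            "minmax_min": self.minmax_min.tolist(),
            "minmax_max": self.minmax_max.tolist(),
            "pca_mean": self.pca_mean.tolist(),
            "pca_components": self.pca_components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "n_components": self.n_components,
            "kmeans_centroids": self.kmeans_centroids.tolist(),
            "label_map": {str(k): v for k, v in self.label_map.items()},
            "training_meta": self.training_meta,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "IntensityModel":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            feature_order=obj["feature_order"],
            minmax_min=np.asarray(obj["minmax_min"], dtype=float),
            minmax_max=np.asarray(obj["minmax_max"], dtype=float),
            pca_mean=np.asarray(obj["pca_mean"], dtype=float),
            pca_components=np.asarray(obj["pca_components"], dtype=float),
            explained_variance_ratio=np.asarray(obj["explained_variance_ratio"], dtype=float),
            n_components=int(obj["n_components"]),
            kmeans_centroids=np.asarray(obj["kmeans_centroids"], dtype=float),
            label_map={int(k): v for k, v in obj["label_map"].items()},
            training_meta=obj["training_meta"],
        )


# ---------------------------------------------------------------------------
# training steps
# ---------------------------------------------------------------------------


def exclude_low_distance(table: pd.DataFrame, threshold_m: float = 200.0) -> tuple:
    """Partition minutes into (train, excluded) by flag and prior distance.

    Minutes whose preceding-5-min distance falls below ``threshold_m`` are
    halftime/lull artifacts and would distort the low-intensity zone.
    """
    drop = table["excluded"].astype(bool) | (table["distance_m"] < threshold_m)
    train = table.loc[~drop]
    if train.empty:
        raise ClusteringError("no rows left for training after exclusions")
    return train, table.loc[drop]


def fit_minmax(train: pd.DataFrame) -> tuple:
    """Per-feature (min, max) bounds over the training rows."""
    X = train[FEATURE_ORDER].to_numpy(dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    constant = np.flatnonzero(hi == lo)
    for i in constant:
        warnings.warn(f"feature {FEATURE_ORDER[i]!r} is constant on training data; scaled to 0")
    return lo, hi


def transform_minmax(rows: pd.DataFrame, bounds: tuple) -> np.ndarray:
    lo, hi = bounds
    X = rows[FEATURE_ORDER].to_numpy(dtype=float)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - lo) / span
    Z[:, span == 0] = 0.0
    return Z


def fit_pca(Z: np.ndarray, variance_target: float = 0.92, n_components: int | None = None) -> PCA:
    """PCA keeping the smallest component count reaching the variance target
    (or exactly ``n_components`` when given)."""
    if Z.shape[0] < 2:
        raise ClusteringError("fit_pca needs at least two rows")
    if n_components is None and not 0 < variance_target <= 1:
        raise ClusteringError(f"variance_target {variance_target} outside (0, 1]")
    full = PCA(n_components=None, svd_solver="full").fit(Z)
    if n_components is None:
        cum = np.cumsum(full.explained_variance_ratio_)
        n_components = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        n_components = min(n_components, len(cum))
    full.components_ = full.components_[:n_components]
    full.explained_variance_ = full.explained_variance_[:n_components]
    full.explained_variance_ratio_ = full.explained_variance_ratio_[:n_components]
    full.n_components_ = n_components
    return full


def fit_kmeans(
    P: np.ndarray, k: int, seed: int = 0, n_init: int = 10, max_iter: int = 300, tol: float = 1e-6
) -> tuple:
    """K-means++ with restarts; returns (centroids, labels, WCSS)."""
    if k > P.shape[0]:
        raise ClusteringError(f"k={k} exceeds number of rows {P.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, max_iter=max_iter, tol=tol, random_state=seed)
    labels = km.fit_predict(P)
    return km.cluster_centers_, labels, float(km.inertia_)


def choose_k(wcss: dict) -> int:
    """Elbow of the WCSS curve: the grid point farthest (perpendicular
    distance) from the chord joining the curve's two endpoints. Ties break
    toward the smallest k."""
    if len(wcss) < 3:
        raise ClusteringError("choose_k needs at least 3 grid points")
    ks = np.array(sorted(wcss), dtype=float)
    ws = np.array([wcss[int(k)] for k in ks], dtype=float)
    x0, y0 = ks[0], ws[0]
    x1, y1 = ks[-1], ws[-1]
    norm = np.hypot(x1 - x0, y1 - y0)
    if norm == 0:
        return int(ks[0])
    dist = np.abs((y1 - y0) * ks - (x1 - x0) * ws + x1 * y0 - y1 * x0) / norm
    best = int(ks[np.argmax(dist)])  # argmax returns the first (smallest k) on ties
    return best


def label_clusters(train: pd.DataFrame, cluster_ids: np.ndarray, k: int) -> dict:
    """Name clusters by semantics: fewest current-minute events -> low; of
    the other two, more prior 5-min general energy -> high."""
    means = (
        pd.DataFrame(
            {
                "cluster": cluster_ids,
                "event_count": train["event_count"].to_numpy(),
                "general_energy_jkg": train["general_energy_jkg"].to_numpy(),
            }
        )
        .groupby("cluster")
        .mean()
    )
    order = means.sort_values(["event_count", "general_energy_jkg"]).index.to_list()
    if k != 3:
        warnings.warn(f"k={k} != 3: labels are ordinal ranks by mean event_count")
        return {int(c): f"zone_{rank}" for rank, c in enumerate(means["event_count"].sort_values().index)}
    low = order[0]
    rest = [c for c in means.index if c != low]
    e = means.loc[rest, "general_energy_jkg"]
    if e.iloc[0] == e.iloc[1]:
        warnings.warn("clusters tied on prior energy; breaking tie by cluster index")
        rest = sorted(rest)
        high, middle = rest[1], rest[0]
    else:
        high = int(e.idxmax())
        middle = [c for c in rest if c != high][0]
    return {int(low): "low", int(middle): "middle", int(high): "high"}


def fit_intensity_model(
    table: pd.DataFrame,
    k_grid=range(2, 16),
    seed: int = 17,
    variance_target: float = 0.92,
    n_components: int | None = None,
    distance_threshold_m: float = 200.0,
    n_init: int = 10,
) -> IntensityModel:
    """End-to-end training on a built (and ceilinged) minute table."""
    train, _ = exclude_low_distance(table, distance_threshold_m)
    bounds = fit_minmax(train)
    Z = transform_minmax(train, bounds)
    pca = fit_pca(Z, variance_target=variance_target, n_components=n_components)
    P = pca.transform(Z)

    wcss = {}
    fits = {}
    for k in k_grid:
        centroids, labels, inertia = fit_kmeans(P, k, seed=seed, n_init=n_init)
        wcss[int(k)] = inertia
        fits[int(k)] = (centroids, labels)
    k_star = choose_k(wcss)
    centroids, labels = fits[k_star]
    label_map = label_clusters(train, labels, k_star)
    logger.info("elbow chose k=%d from grid %s", k_star, sorted(wcss))

    return IntensityModel(
        feature_order=list(FEATURE_ORDER),
        minmax_min=bounds[0],
        minmax_max=bounds[1],
        pca_mean=pca.mean_,
        pca_components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_components=pca.n_components_,
        kmeans_centroids=centroids,
        label_map=label_map,
        training_meta={
            "k_grid": [int(k) for k in k_grid],
            "wcss": {str(k): v for k, v in wcss.items()},
            "chosen_k": k_star,
            "seed": int(seed),
            "n_init": int(n_init),
            "distance_threshold_m": float(distance_threshold_m),
            "variance_target": None if n_components is not None else float(variance_target),
        },
    )


def assign(model: IntensityModel, table: pd.DataFrame) -> pd.DataFrame:
    """Label every minute; excluded/low-distance minutes are unclassified.

    Returns the identity columns plus ``label``.
    """
    missing = [c for c in model.feature_order if c not in table.columns]
    if missing:
        raise ClusteringError(f"feature table missing column(s): {', '.join(missing)}")
    threshold = model.training_meta.get("distance_threshold_m", 200.0)
    out = table[["game_id", "player_id", "minute"]].copy()
    drop = table["excluded"].astype(bool) | (table["distance_m"] < threshold)

    Z = model.scale(table[model.feature_order].to_numpy(dtype=float))
    P = model.project(Z)
    d2 = ((P[:, None, :] - model.kmeans_centroids[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    out["label"] = [model.label_map[int(c)] for c in nearest]
    out.loc[drop.to_numpy(), "label"] = UNCLASSIFIED
    return out
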