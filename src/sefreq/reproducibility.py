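"""Multi-run reproducibility of the signature components.

Non-negative decompositions have local optima, so a component is only
meaningful if it re-appears across independent restarts.  The procedure
(as used for cancer mutational signatures): fit the model many times from
random starts, keep the lowest-loss solutions, pool their components —
columns of W in the drug view, rows of H in the side-effect view — and
cluster them with k-means++ under cosine distance.  The cosine-based
average silhouette width of each cluster, in [−1, 1], is the
reproducibility score of that component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import kmeans_plusplus
from sklearn.metrics import silhouette_samples

from .datamodel import FrequencyMatrix, ValidationError
from .decomposition import DecompositionConfig, FactorModel, fit

__all__ = [
    "RunEnsemble",
    "multirun_fit",
    "spherical_kmeans",
    "ClusterReport",
    "cluster_components",
]

#: desk-scale defaults; the full-scale protocol uses 10,000 runs / top 100
DESK_SCALE = {"n_runs": 100, "top_m": 20}
FULL_SCALE = {"n_runs": 10_000, "top_m": 100}


@dataclass
class RunEnsemble:
    """Independent fits of one matrix under one configuration."""

    models: list[FactorModel]
    losses: np.ndarray
    seeds: np.ndarray

    def __post_init__(self):
        shapes = {(m.W.shape, m.H.shape) for m in self.models}
        if len(shapes) > 1:
            raise ValidationError("ensemble models have inconsistent shapes")

    def top(self, m: int) -> list[FactorModel]:
        """The m lowest-loss models; loss ties broken by seed order."""
        if m > len(self.models):
            raise ValidationError("selection size exceeds ensemble size")
        order = np.lexsort((self.seeds, self.losses))
        return [self.models[i] for i in order[:m]]

    def best(self) -> FactorModel:
        return self.top(1)[0]

    def mean_scores(self, top_m: int | None = None) -> np.ndarray:
        """Average predicted score matrix over the (top) models."""
        models = self.top(top_m) if top_m is not None else self.models
        return np.mean([m.W @ m.H for m in models], axis=0)


def multirun_fit(
    matrix: FrequencyMatrix,
    config: DecompositionConfig | None = None,
    n_runs: int = 100,
    base_seed: int = 0,
) -> RunEnsemble:
    """Fit ``n_runs`` times with per-run seeds ``base_seed + run_index``."""
    from dataclasses import replace

    if n_runs < 2:
        raise ValidationError("n_runs must be >= 2")
    base = config or DecompositionConfig()
    models, losses, seeds = [], [], []
    for r in range(n_runs):
        seed = base_seed + r
        try:
            model = fit(matrix, config=replace(base, seed=seed))
        except FloatingPointError:  # pragma: no cover - defensive
            continue
        models.append(model)
        losses.append(model.loss_trace[-1])
        seeds.append(seed)
    return RunEnsemble(models=models, losses=np.asarray(losses), seeds=np.asarray(seeds))


def _unit_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValidationError("zero component vector cannot be clustered")
    return X / norms[:, None]


def spherical_kmeans(
    X: np.ndarray, n_clusters: int, seed: int = 0, max_iter: int = 300
) -> np.ndarray:
    """k-means under cosine distance: k-means++ start, re-normalised centroids.

    Points and centroids live on the unit sphere; assignment maximises the
    dot product, centroid update is the re-normalised mean.
    """
    Xn = _unit_rows(np.asarray(X, dtype=float))
    if n_clusters < 2:
        raise ValidationError("n_clusters must be >= 2")
    if np.unique(np.round(Xn, 12), axis=0).shape[0] < n_clusters:
        raise ValidationError("fewer distinct components than clusters")
    centers, _ = kmeans_plusplus(Xn, n_clusters=n_clusters, random_state=seed)
    centers = _unit_rows(centers)
    labels = np.zeros(Xn.shape[0], dtype=int)
    for _ in range(max_iter):
        sim = Xn @ centers.T
        new_labels = np.argmax(sim, axis=1)
        for c in range(n_clusters):  # re-seed empty clusters with the worst point
            if not np.any(new_labels == c):
                new_labels[np.argmin(np.max(sim, axis=1))] = c
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for c in range(n_clusters):
            mean = Xn[labels == c].mean(axis=0)
            norm = np.linalg.norm(mean)
            if norm > 0:
                centers[c] = mean / norm
    return labels


@dataclass
class ClusterReport:
    """Clustering of pooled components in one view (drug or side-effect)."""

    labels: np.ndarray
    silhouette_per_component: np.ndarray
    silhouette_per_cluster: np.ndarray

    @property
    def median_silhouette(self) -> float:
        return float(np.median(self.silhouette_per_cluster))


def cluster_components(
    ensemble: RunEnsemble,
    top_m: int = 20,
    n_clusters: int | None = None,
    seed: int = 0,
) -> dict[str, ClusterReport]:
    """Cluster pooled components of the top solutions, per view.

    The top ``top_m`` lowest-loss models contribute k components each: in
    the drug view each component is a column of W (its loadings over
    drugs), in the side-effect view a row of H.  Returns a
    :class:`ClusterReport` per view with cosine-silhouette scores.
    """
    models = ensemble.top(top_m)
    k = models[0].k
    n_clusters = n_clusters or k
    out = {}
    for view, stack in (
        ("drug", np.hstack([m.W for m in models]).T),       # (top_m·k) × n
        ("side_effect", np.vstack([m.H for m in models])),  # (top_m·k) × m
    ):
        labels = spherical_kmeans(stack, n_clusters=n_clusters, seed=seed)
        sil = silhouette_samples(stack, labels, metric="cosine")
        per_cluster = np.array([sil[labels == c].mean() for c in range(n_clusters)])
        out[view] = ClusterReport(
            labels=labels,
            silhouette_per_component=sil,
            silhouette_per_cluster=per_cluster,
        )
    return out
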