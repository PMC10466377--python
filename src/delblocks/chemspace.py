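"""2D chemical-space embedding, density clustering, and cluster validations.

A ``ChemSpace`` model embeds one position's building blocks into 2D with
UMAP (precomputed distances), clusters the coordinates with HDBSCAN, and
supports deterministic out-of-sample projection and cluster assignment for
new building blocks.  HDBSCAN hyperparameters are chosen by grid search
minimizing

    L = w_noise * n_noise / n  +  w_icd * ICD / max_pairwise_distance

where n_noise is the number of noise-labeled points and ICD the average
intracluster distance between clustered points: the two failure modes of a
density clustering (discarding everything as noise vs. merging everything
into diffuse clusters) pull the objective in opposite directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.cluster import HDBSCAN

from .distances import DistanceMatrix

__all__ = [
    "ClusterObjective",
    "ChemSpace",
    "embed_2d",
    "cluster",
    "project_and_assign",
    "fwhm",
    "fwhm_cluster_validation",
    "top10_distance_analysis",
]


@dataclass
class ClusterObjective:
    """One grid-search evaluation of the clustering objective."""

    min_cluster_size: int
    min_samples: int
    n_clusters: int
    n_noise: int
    icd: float
    objective: float


class DegenerateClusteringError(RuntimeError):
    """Every grid point labeled every point as noise."""


def _umap_embed(distances: np.ndarray, n_neighbors: int, min_dist: float, seed: int):
    # Imported lazily: umap pulls in numba and is slow to import.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import umap

        reducer = umap.UMAP(
            n_components=2,
            metric="precomputed",
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            random_state=seed,
        )
        return np.asarray(reducer.fit_transform(distances), dtype=float)


def _intracluster_distance(coords: np.ndarray, labels: np.ndarray) -> float:
    """Mean pairwise Euclidean distance pooled over all within-cluster pairs."""
    total, pairs = 0.0, 0
    for c in np.unique(labels[labels >= 0]):
        member = coords[labels == c]
        if len(member) < 2:
            continue
        d = pdist(member)
        total += d.sum()
        pairs += len(d)
    return total / pairs if pairs else 0.0


class ChemSpace(BaseEstimator):
    """Embed + cluster building blocks of one position; project new ones.

    Parameters
    ----------
    n_neighbors, min_dist : UMAP parameters (n_neighbors is capped at n-1).
    random_state : embedding seed, recorded on the fitted model.
    min_cluster_size_grid, min_samples_grid : HDBSCAN grid-search ranges.
    noise_weight, icd_weight : weights of the two objective terms.
    projection_neighbors : number of nearest training points used to place a
        projected point (inverse-distance weighting).  Kept small so the
        placement is local rather than pulled toward cluster centroids.
    assign_factor : a projected point joins the cluster of its nearest
        clustered training point when the distance is within ``assign_factor``
        times that cluster's reach (the largest member-to-nearest-member
        distance); otherwise it is labeled noise (-1).

    Attributes (after ``fit``)
    --------------------------
    ids_ : building-block IDs in matrix order.
    embedding_ : (n, 2) UMAP coordinates.
    labels_ : cluster ID per building block, -1 for noise.
    objectives_ : list of ClusterObjective, one per grid point, in grid order.
    best_params_ : dict with the selected min_cluster_size / min_samples.
    n_clusters_ : number of non-noise clusters.
    """

    def __init__(
        self,
        n_neighbors: int = 15,
        min_dist: float = 0.1,
        random_state: int = 42,
        min_cluster_size_grid: tuple = (5, 10, 15, 25),
        min_samples_grid: tuple = (1, 5, 10),
        noise_weight: float = 1.0,
        icd_weight: float = 1.0,
        projection_neighbors: int = 5,
        assign_factor: float = 2.0,
    ):
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.random_state = random_state
        self.min_cluster_size_grid = min_cluster_size_grid
        self.min_samples_grid = min_samples_grid
        self.noise_weight = noise_weight
        self.icd_weight = icd_weight
        self.projection_neighbors = projection_neighbors
        self.assign_factor = assign_factor

    # -- fitting -----------------------------------------------------------

    def fit(self, distances: DistanceMatrix | np.ndarray, ids=None) -> "ChemSpace":
        if isinstance(distances, DistanceMatrix):
            ids = distances.ids
            matrix = distances.values
        else:
            matrix = np.asarray(distances, dtype=float)
            if ids is None:
                ids = list(range(matrix.shape[0]))
        n = matrix.shape[0]
        if n < 4:
            raise ValueError(
                f"need at least 4 building blocks to embed, got {n}; "
                "reduce n_neighbors only goes so far"
            )
        self.ids_ = list(ids)
        self.embedding_ = _umap_embed(
            matrix,
            n_neighbors=min(self.n_neighbors, n - 1),
            min_dist=self.min_dist,
            seed=self.random_state,
        )
        self.labels_, self.objectives_, self.best_params_ = _grid_search(
            self.embedding_,
            self.min_cluster_size_grid,
            self.min_samples_grid,
            self.noise_weight,
            self.icd_weight,
        )
        self.n_clusters_ = int(len(np.unique(self.labels_[self.labels_ >= 0])))
        self._reach_ = self._cluster_reach()
        # Largest nearest-neighbor distance in the INPUT metric: a projected
        # point further than assign_factor times this from every training
        # point is outside the fitted space and must not inherit a cluster.
        offdiag = matrix + np.diag(np.full(n, np.inf))
        self._input_nn_max_ = float(offdiag.min(axis=1).max())
        return self

    def _cluster_reach(self) -> dict[int, float]:
        reach = {}
        for c in np.unique(self.labels_[self.labels_ >= 0]):
            member = self.embedding_[self.labels_ == c]
            d = squareform(pdist(member))
            np.fill_diagonal(d, np.inf)
            nearest = d.min(axis=1)
            reach[int(c)] = float(nearest.max()) if np.isfinite(nearest).all() else 0.0
        return reach

    # -- out-of-sample -----------------------------------------------------

    def transform(self, new_distances: np.ndarray) -> np.ndarray:
        """Project new building blocks into the fitted embedding.

        ``new_distances`` is (n_new, n_train): each row holds the distances
        from one new building block to every training building block, in
        training order.  Placement is inverse-distance-weighted interpolation
        over the ``projection_neighbors`` nearest training points; a new
        point at distance exactly 0 from a training point lands exactly on
        it, so training members re-project to their stored coordinates.
        """
        self._check_fitted()
        D = np.atleast_2d(np.asarray(new_distances, dtype=float))
        if D.shape[1] != len(self.ids_):
            raise ValueError(
                f"score matrix has {D.shape[1]} columns but the model was "
                f"trained on {len(self.ids_)} building blocks"
            )
        k = min(self.projection_neighbors, len(self.ids_))
        coords = np.empty((D.shape[0], 2))
        for i, row in enumerate(D):
            exact = np.flatnonzero(row <= 1e-12)
            if exact.size:
                coords[i] = self.embedding_[exact[0]]
                continue
            nearest = np.argsort(row, kind="stable")[:k]
            w = 1.0 / row[nearest]
            coords[i] = (w[:, None] * self.embedding_[nearest]).sum(0) / w.sum()
        return coords

    def assign(self, coords: np.ndarray) -> np.ndarray:
        """Cluster ID (or -1 noise) for points already in embedding space."""
        self._check_fitted()
        coords = np.atleast_2d(coords)
        clustered = self.labels_ >= 0
        if not clustered.any():
            return np.full(len(coords), -1, dtype=np.int64)
        ref = self.embedding_[clustered]
        ref_labels = self.labels_[clustered]
        d = cdist(coords, ref)
        nearest = d.argmin(axis=1)
        labels = ref_labels[nearest].astype(np.int64)
        dist = d[np.arange(len(coords)), nearest]
        for i, (lab, dd) in enumerate(zip(labels, dist)):
            if dd > self.assign_factor * max(self._reach_[int(lab)], 1e-12):
                labels[i] = -1
        return labels

    def predict(self, new_distances: np.ndarray) -> np.ndarray:
        """Project new building blocks and assign clusters in one step.

        A building block whose nearest training distance (in the input
        metric) exceeds ``assign_factor`` times the largest training
        nearest-neighbor distance is labeled noise: 2D interpolation always
        lands inside the embedding, so remoteness is only visible in the
        input distances.
        """
        D = np.atleast_2d(np.asarray(new_distances, dtype=float))
        labels = self.assign(self.transform(D))
        remote = D.min(axis=1) > self.assign_factor * max(self._input_nn_max_, 1e-12)
        labels[remote] = -1
        return labels

    def _check_fitted(self) -> None:
        if not hasattr(self, "embedding_"):
            raise RuntimeError("ChemSpace model is not fitted")

    # -- persistence helpers ----------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        self._check_fitted()
        return pd.DataFrame(
            {
                "bb_id": self.ids_,
                "x": self.embedding_[:, 0],
                "y": self.embedding_[:, 1],
                "cluster": self.labels_,
            }
        )


def _grid_search(coords, min_cluster_size_grid, min_samples_grid, w_noise, w_icd):
    n = len(coords)
    max_d = float(pdist(coords).max()) if n > 1 else 1.0
    if max_d <= 0:
        max_d = 1.0
    objectives: list[ClusterObjective] = []
    labelings: list[np.ndarray] = []
    for mcs in min_cluster_size_grid:
        for ms in min_samples_grid:
            if mcs > n or ms > n:
                continue
            model = HDBSCAN(
                min_cluster_size=int(mcs),
                min_samples=int(ms),
                allow_single_cluster=True,
                copy=True,
            )
            labels = model.fit_predict(coords)
            n_noise = int((labels == -1).sum())
            icd = _intracluster_distance(coords, labels)
            L = w_noise * n_noise / n + w_icd * icd / max_d
            objectives.append(
                ClusterObjective(int(mcs), int(ms), int(len(set(labels[labels >= 0]))), n_noise, icd, float(L))
            )
            labelings.append(labels)
    if not objectives:
        raise DegenerateClusteringError("hyperparameter grid is empty for this input size")
    if all(o.n_noise == len(coords) for o in objectives):
        raise DegenerateClusteringError(
            "every grid point labeled all points as noise; grid evaluated: "
            + ", ".join(
                f"(mcs={o.min_cluster_size}, ms={o.min_samples})" for o in objectives
            )
        )
    # Global minimum of L; ties broken by smallest n_noise, then grid order.
    best = min(range(len(objectives)), key=lambda i: (objectives[i].objective, objectives[i].n_noise, i))
    params = {
        "min_cluster_size": objectives[best].min_cluster_size,
        "min_samples": objectives[best].min_samples,
    }
    return labelings[best].astype(np.int64), objectives, params


# -- module-level wrappers over the estimator ------------------------------


def embed_2d(
    distances: DistanceMatrix | np.ndarray,
    seed: int = 42,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """2D UMAP coordinates from a precomputed distance matrix (deterministic
    for a fixed seed)."""
    matrix = distances.values if isinstance(distances, DistanceMatrix) else np.asarray(distances)
    n = matrix.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 points to embed, got {n}")
    return _umap_embed(matrix, n_neighbors=min(n_neighbors, n - 1), min_dist=min_dist, seed=seed)


def cluster(
    coords: np.ndarray,
    min_cluster_size_grid: tuple = (5, 10, 15, 25),
    min_samples_grid: tuple = (1, 5, 10),
    noise_weight: float = 1.0,
    icd_weight: float = 1.0,
):
    """Grid-searched HDBSCAN labels for 2D coordinates.

    Returns ``(labels, objectives, best_params)``; ``objectives`` holds every
    grid evaluation for audit, and the returned labeling is the grid point
    minimizing the objective.
    """
    return _grid_search(np.asarray(coords, float), min_cluster_size_grid, min_samples_grid, noise_weight, icd_weight)


def project_and_assign(model: ChemSpace, new_distances: np.ndarray):
    """Coordinates and cluster assignment for new building blocks given
    their distances to the training building blocks."""
    return model.transform(new_distances), model.predict(new_distances)


# -- validations -----------------------------------------------------------


def fwhm(values, n_bins: int = 10, value_range=None) -> float:
    """Full width at half maximum of a sample's histogram.

    The histogram spans the sample range by default (pass ``value_range``
    for fixed bins); the width is taken between the half-maximum crossings
    on either side of the modal bin, with linear interpolation between bin
    centers.  A degenerate (constant) sample has width 0.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("fwhm of an empty sample is undefined")
    if np.ptp(values) == 0:
        return 0.0
    counts, edges = np.histogram(values, bins=n_bins, range=value_range)
    centers = (edges[:-1] + edges[1:]) / 2
    peak = int(counts.argmax())
    half = counts[peak] / 2.0

    def _cross(direction: int) -> float:
        i = peak
        while 0 <= i + direction < len(counts) and counts[i + direction] >= half:
            i += direction
        j = i + direction
        if j < 0 or j >= len(counts):
            return centers[i]
        # linear interpolation between the last bin above half and the first below
        c1, c2 = counts[i], counts[j]
        frac = (c1 - half) / (c1 - c2) if c1 != c2 else 0.0
        return centers[i] + direction * frac * (centers[min(i, j) + 1] - centers[min(i, j)])

    return float(_cross(+1) - _cross(-1))


@dataclass
class FwhmValidation:
    real_mean_fwhm: float
    random_mean_fwhm: float
    n_clusters_used: int
    n_excluded: int


def fwhm_cluster_validation(
    pbind: pd.Series,
    labels: np.ndarray,
    ids,
    n_random_trials: int = 20,
    seed: int = 0,
    n_bins: int = 10,
) -> FwhmValidation:
    """Compare P(bind) spread inside real clusters vs. size-matched random ones.

    For each cluster (noise excluded) the fwhm of its members' P(bind)
    histogram is computed; random clusters are label permutations, so they
    are size-matched by construction.  A smaller real mean indicates that
    clusters group building blocks of similar productivity.  Size-1 clusters
    have undefined fwhm; they are excluded and counted.
    """
    labels = np.asarray(labels)
    values = pbind.reindex(ids).to_numpy(dtype=float)
    if np.isnan(values).any():
        raise KeyError("every building block in the model needs a P(bind) value")

    def _mean_fwhm(lab):
        widths, excluded = [], 0
        for c in np.unique(lab[lab >= 0]):
            member = values[lab == c]
            if len(member) < 2:
                excluded += 1
                continue
            widths.append(fwhm(member, n_bins=n_bins))
        return (float(np.mean(widths)) if widths else np.nan), len(widths), excluded

    real, n_used, n_excl = _mean_fwhm(labels)
    rng = np.random.default_rng(seed)
    randoms = []
    for _ in range(n_random_trials):
        perm = labels[rng.permutation(len(labels))]
        r, _, _ = _mean_fwhm(perm)
        if not np.isnan(r):
            randoms.append(r)
    return FwhmValidation(real, float(np.mean(randoms)), n_used, n_excl)


@dataclass
class TopDistanceResult:
    top_top: np.ndarray
    top_random: np.ndarray
    ratio: float
    zero_division: bool
    n_top: int


def top10_distance_analysis(
    pbind: pd.Series,
    coords: np.ndarray,
    ids,
    n_top: int = 10,
    n_random: int = 100,
    seed: int = 0,
) -> TopDistanceResult:
    """Embedding distances among the most productive building blocks vs.
    from them to random ones.

    The "top" set is the ``n_top`` building blocks by descending P(bind)
    (requiring P(bind) > 0; fewer eligible reduces the set with a warning).
    The random sample excludes the top set.  The reported ratio is
    mean(top-to-random) / mean(top-to-top); a ratio near 2 reproduces the
    observation that productive building blocks are about twice as close to
    one another as to arbitrary ones.
    """
    ids = list(ids)
    values = pbind.reindex(ids).to_numpy(dtype=float)
    eligible = np.flatnonzero(values > 0)
    if len(eligible) < n_top:
        warnings.warn(
            f"only {len(eligible)} building blocks with P(bind) > 0; "
            f"reducing top set from {n_top}",
            stacklevel=2,
        )
        n_top = len(eligible)
    order = eligible[np.argsort(values[eligible], kind="stable")[::-1]]
    top_idx = order[:n_top]
    rest = np.setdiff1d(np.arange(len(ids)), top_idx)
    rng = np.random.default_rng(seed)
    take = min(n_random, len(rest))
    rand_idx = rng.choice(rest, size=take, replace=False)

    top_coords = coords[top_idx]
    tt = pdist(top_coords) if len(top_idx) > 1 else np.array([0.0])
    tr = cdist(top_coords, coords[rand_idx]).ravel()
    mean_tt = float(tt.mean()) if tt.size else 0.0
    mean_tr = float(tr.mean()) if tr.size else 0.0
    zero = mean_tt == 0.0
    ratio = float("inf") if zero and mean_tr > 0 else (mean_tr / mean_tt if not zero else 0.0)
    return TopDistanceResult(tt, tr, ratio, zero, int(n_top))
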