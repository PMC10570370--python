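"""Self-organizing-map clustering of temporal intensity profiles.

Per-composition intensity traces over the timepoint grid are min-max rescaled
to [0, 1] and clustered on a 2 x 4 rectangular SOM grid (8 prototype units)
with a Gaussian neighborhood, Euclidean best-matching-unit selection, learning
rate 0.1 and 50,000 online iterations.  Each occupied grid node is one
temporal cluster; a cluster's peak time is the timepoint where its mean
member profile is maximal.

:class:`SOMClusterer` follows the scikit-learn estimator contract
(``fit`` / ``predict`` / ``fit_predict``, ``get_params`` / ``set_params``,
fitted attributes with trailing underscores) and composes with sklearn
pipelines and model selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .annotate import Annotation
from .chem import ElementalComposition

__all__ = [
    "TemporalProfile",
    "SOMClusterer",
    "scale_profiles",
    "train_som",
    "peak_time",
    "subspace_peaktime_distribution",
]


@dataclass
class TemporalProfile:
    """Per-composition intensity vector over the shared timepoint grid."""

    composition: ElementalComposition
    timepoints: tuple[float, ...]
    intensities: np.ndarray
    scaled: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.timepoints),):
            raise ValueError("intensity vector must match the timepoint grid")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


def scale_profiles(profiles: list[TemporalProfile]) -> list[TemporalProfile]:
    """Min-max rescale each profile to [0, 1]; constant profiles map to zeros."""
    for p in profiles:
        lo, hi = float(p.intensities.min()), float(p.intensities.max())
        if hi > lo:
            p.scaled = (p.intensities - lo) / (hi - lo)
        else:
            p.scaled = np.zeros_like(p.intensities)
    return profiles


def archetype_profiles(
    n_per_archetype: int = 50,
    n_timepoints: int = 6,
    noise: float = 0.08,
    random_state: int | None = 0,
) -> np.ndarray:
    """Synthetic scaled temporal profiles spanning eight archetype shapes.

    A benchmark population for the temporal clusterer: four transient bumps
    peaking early to late, two sigmoidal risers, one decayer and one broad
    plateau, each with within-family variation of peak position and width
    plus additive noise.  Returns an (8 * n_per_archetype, n_timepoints)
    array of min-max-scaled rows.
    """
    rng = np.random.default_rng(random_state)
    t = np.arange(n_timepoints, dtype=float)
    hi = n_timepoints - 1.0

    def bump(p, w):
        return np.exp(-0.5 * ((t - p) / w) ** 2)

    def riser(p, w):
        return 1.0 / (1.0 + np.exp(-(t - p) / w))

    # four transient families tile the time axis contiguously, so together
    # with the monotone families the population fills the profile manifold
    # (an isolated-island geometry leaves SOM units dead between islands)
    families = (
        lambda: bump(rng.uniform(0.00, 0.25) * hi, rng.uniform(0.5, 1.2)),
        lambda: bump(rng.uniform(0.25, 0.50) * hi, rng.uniform(0.5, 1.2)),
        lambda: bump(rng.uniform(0.50, 0.75) * hi, rng.uniform(0.5, 1.2)),
        lambda: bump(rng.uniform(0.75, 1.00) * hi, rng.uniform(0.5, 1.2)),
        lambda: riser(rng.uniform(0.1, 0.5) * hi, rng.uniform(0.6, 1.4)),
        lambda: riser(rng.uniform(0.5, 0.9) * hi, rng.uniform(0.6, 1.4)),
        lambda: 1.0 - riser(rng.uniform(0.2, 0.8) * hi, rng.uniform(0.6, 1.4)),
        lambda: bump(rng.uniform(0.3, 0.7) * hi, rng.uniform(1.6, 2.6)),
    )
    rows = []
    for make in families:
        for _ in range(n_per_archetype):
            v = np.clip(make() + noise * rng.standard_normal(n_timepoints), 0.0, None)
            span = v.max() - v.min()
            rows.append((v - v.min()) / span if span > 0 else np.zeros_like(v))
    return np.vstack(rows)


class SOMClusterer(BaseEstimator, ClusterMixin):
    """Online Kohonen self-organizing map on a small rectangular grid.

    Parameters
    ----------
    grid_shape : (rows, cols) of the unit grid (default (2, 4) = 8 units).
    learning_rate : initial online learning rate (default 0.1), decaying
        linearly to ``learning_rate_final``.
    sigma : initial Gaussian neighborhood radius in grid units (default 1.0),
        decaying linearly to ``sigma_final``.
    n_iterations : number of single-sample online updates (default 50,000).
    random_state : seed for weight initialization and sample draws.

    Attributes
    ----------
    weights_ : (n_units, n_features) prototype vectors after training.
    labels_ : best-matching-unit index per training sample.
    quantization_error_ : mean Euclidean distance of samples to their BMU.
    """

    def __init__(
        self,
        grid_shape: tuple[int, int] = (2, 4),
        learning_rate: float = 0.1,
        learning_rate_final: float = 0.01,
        sigma: float = 1.0,
        sigma_final: float = 0.1,
        n_iterations: int = 50_000,
        random_state: int | None = None,
    ) -> None:
        self.grid_shape = grid_shape
        self.learning_rate = learning_rate
        self.learning_rate_final = learning_rate_final
        self.sigma = sigma
        self.sigma_final = sigma_final
        self.n_iterations = n_iterations
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y=None) -> "SOMClusterer":
        X = check_array(X, ensure_min_samples=1)
        rng = np.random.default_rng(self.random_state)
        rows, cols = self.grid_shape
        n_units = rows * cols
        n_features = X.shape[1]

        # grid coordinates of each unit, for the neighborhood kernel
        coords = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)
        grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)

        # scaled data live in the unit cube; init uniformly inside it
        w = rng.uniform(0.0, 1.0, size=(n_units, n_features))

        T = self.n_iterations
        lr0, lr1 = self.learning_rate, self.learning_rate_final
        s0, s1 = self.sigma, self.sigma_final
        sample_idx = rng.integers(0, X.shape[0], size=T)
        for t in range(T):
            x = X[sample_idx[t]]
            frac = t / T
            lr = lr0 + (lr1 - lr0) * frac
            sig = s0 + (s1 - s0) * frac
            d2 = ((w - x) ** 2).sum(1)
            bmu = int(np.argmin(d2))
            h = np.exp(-grid_d2[bmu] / (2.0 * sig * sig))
            w += (lr * h)[:, None] * (x - w)

        self.weights_ = w
        self.grid_coords_ = coords.astype(int)
        self.n_features_in_ = n_features
        self.labels_ = self._bmu(X)
        self.quantization_error_ = float(
            np.mean(np.linalg.norm(X - w[self.labels_], axis=1))
        )
        # mean scaled member profile per occupied node
        centers = np.full((n_units, n_features), np.nan)
        for u in range(n_units):
            members = X[self.labels_ == u]
            if len(members):
                centers[u] = members.mean(0)
        self.cluster_centers_ = centers
        return self

    def _bmu(self, X: np.ndarray) -> np.ndarray:
        d = ((X[:, None, :] - self.weights_[None, :, :]) ** 2).sum(-1)
        return np.argmin(d, axis=1)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = check_array(X)
        return self._bmu(X)

    def quantization_error(self, X) -> float:
        """Mean Euclidean distance of samples to their best-matching unit."""
        check_is_fitted(self, "weights_")
        X = check_array(X)
        labels = self._bmu(X)
        return float(np.mean(np.linalg.norm(X - self.weights_[labels], axis=1)))

    def n_occupied_clusters(self, X=None) -> int:
        """Number of grid nodes with at least one assigned sample."""
        check_is_fitted(self, "labels_")
        labels = self.labels_ if X is None else self.predict(X)
        return int(np.unique(labels).size)


def train_som(
    profiles: list[TemporalProfile],
    grid_shape: tuple[int, int] = (2, 4),
    learning_rate: float = 0.1,
    n_iterations: int = 50_000,
    random_state: int | None = 0,
    **kwargs,
) -> tuple[SOMClusterer, np.ndarray]:
    """Scale (if needed) and cluster profiles; returns (fit, labels)."""
    if not profiles:
        raise ValueError("cannot train a SOM on zero profiles")
    if any(p.scaled is None for p in profiles):
        scale_profiles(profiles)
    X = np.vstack([p.scaled for p in profiles])
    som = SOMClusterer(
        grid_shape=grid_shape, learning_rate=learning_rate,
        n_iterations=n_iterations, random_state=random_state, **kwargs,
    ).fit(X)
    return som, som.labels_


def peak_time(vector: np.ndarray, timepoints: tuple[float, ...]) -> float | None:
    """Timepoint of the maximum; ties break to the earliest; None if all-zero."""
    v = np.asarray(vector, dtype=float)
    if not np.any(v > 0):
        return None
    return float(timepoints[int(np.argmax(v))])


def subspace_peaktime_distribution(
    profiles: list[TemporalProfile],
    labels: np.ndarray,
    som: SOMClusterer,
    subspaces: dict[tuple[int, int], list[Annotation]],
) -> pd.DataFrame:
    """Percentage of each subspace's members per cluster peak time.

    Clusters are identified by their node's peak time (argmax of the mean
    member profile); rows of one subspace sum to 100%.
    """
    tp = profiles[0].timepoints if profiles else ()
    comp_cluster = {
        p.composition.neutral(): int(l) for p, l in zip(profiles, labels)
    }
    cluster_pt = {
        u: peak_time(som.cluster_centers_[u], tp)
        for u in range(som.cluster_centers_.shape[0])
        if not np.all(np.isnan(som.cluster_centers_[u]))
    }
    rows = []
    for (o, s), anns in sorted(subspaces.items()):
        comps = {a.composition.neutral() for a in anns}
        members = [c for c in comps if c in comp_cluster]
        if not members:
            continue
        counts: dict[int, int] = {}
        for c in members:
            u = comp_cluster[c]
            counts[u] = counts.get(u, 0) + 1
        for u in sorted(counts):
            rows.append({
                "o_count": o, "s_count": s, "cluster": u,
                "cluster_peak_time_h": cluster_pt.get(u),
                "n": counts[u],
                "pct": 100.0 * counts[u] / len(members),
            })
    return pd.DataFrame(
        rows, columns=["o_count", "s_count", "cluster", "cluster_peak_time_h", "n", "pct"]
    )
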