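"""k-means excitability phenotyping with bootstrap stability validation.

Neurons are clustered on z-scored morpho-electric features (default five:
gain, rheobase, spike latency, C_m, R_in) pooled across genotypes and ages.
With k = 2 the clusters are labelled "hyperexcitable" vs "normal" by the
signs of the centroid loadings (hyperexcitable: higher gain and R_in, lower
rheobase, latency and C_m).  Stability is assessed by repeatedly refitting
on random 80% subsamples and recording, per cell, the probability of
retaining its full-data cluster.  Strength of membership is the residual:
the difference of z-scored distances to the two centroids, i.e. the signed
perpendicular offset from the unity line in the distance-distance plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from ._rng import stream

__all__ = [
    "FeatureMatrix",
    "ClusterModel",
    "MembershipResult",
    "StabilityResult",
    "CANONICAL_FEATURES",
    "EXPECTED_SIGNS",
    "zscore_features",
    "fit_kmeans",
    "bootstrap_stability",
    "label_clusters",
    "membership_residuals",
    "compare_residuals",
]

CANONICAL_FEATURES = ["gain", "rheobase", "spike_latency", "c_m", "r_in"]

# expected centroid-loading signs of the hyperexcitable phenotype
EXPECTED_SIGNS = {"gain": +1, "r_in": +1, "rheobase": -1, "spike_latency": -1, "c_m": -1}


@dataclass
class FeatureMatrix:
    """Neurons x features, with group labels carried alongside."""

    values: np.ndarray
    feature_names: list[str]
    groups: pd.DataFrame | None = None  # genotype / age / cell_type per row
    zscored: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if np.isnan(self.values).any():
            raise ValueError("missing values must be filtered before clustering")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray  # k x p, in z-space
    feature_names: list[str]
    inertia: float
    labels_: np.ndarray  # training assignment
    cluster_names: dict[int, str] = field(default_factory=dict)  # e.g. {0: "hyperexcitable"}

    def assign(self, values: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(values[:, None, :] - self.centroids[None, :, :], axis=2)
        return np.argmin(d, axis=1)

    def distances(self, values: np.ndarray) -> np.ndarray:
        return np.linalg.norm(values[:, None, :] - self.centroids[None, :, :], axis=2)

    @property
    def centroid_loadings(self) -> pd.DataFrame:
        return pd.DataFrame(self.centroids, columns=self.feature_names)


@dataclass
class MembershipResult:
    distances: np.ndarray       # n x k raw Euclidean distances
    z_distances: np.ndarray     # distances z-scored across cells, per centroid
    residual: np.ndarray        # signed; positive = more hyperexcitable
    assigned: np.ndarray        # cluster index per cell
    assigned_name: list[str]
    retention_probability: np.ndarray | None = None


@dataclass
class StabilityResult:
    retention_probability: np.ndarray  # per cell
    iteration_agreement: np.ndarray    # per iteration, fraction matching full-data labels
    mean_retention: float
    mean_agreement: float
    stable: bool
    stability_threshold: float
    n_iter: int


def zscore_features(matrix: FeatureMatrix, ddof: int = 1) -> FeatureMatrix:
    """Column-standardize to mean 0, sd 1 (sample sd, n-1 denominator)."""
    x = matrix.values
    sd = x.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [matrix.feature_names[i] for i in bad]
        raise ValueError(f"constant feature column(s): {names}")
    z = (x - x.mean(axis=0)) / sd
    return FeatureMatrix(z, list(matrix.feature_names), matrix.groups, zscored=True)


def fit_kmeans(matrix: FeatureMatrix, k: int = 2, seed: int = 0,
               n_init: int = 10) -> ClusterModel:
    """Lloyd's k-means with k-means++ initialisation and multiple restarts."""
    if matrix.n < k:
        raise ValueError(f"need at least k={k} observations, got {matrix.n}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(matrix.values)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_.copy(),
        feature_names=list(matrix.feature_names),
        inertia=float(km.inertia_),
        labels_=km.labels_.copy(),
    )


def _match_centroids(ref: np.ndarray, other: np.ndarray) -> np.ndarray:
    """mapping[j] = reference cluster paired with other-cluster j (optimal assignment)."""
    cost = np.linalg.norm(ref[:, None, :] - other[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    mapping = np.empty(other.shape[0], dtype=int)
    mapping[cols] = rows
    return mapping


def bootstrap_stability(
    matrix: FeatureMatrix,
    k: int = 2,
    n_iter: int = 1000,
    train_frac: float = 0.8,
    seed: int = 0,
    model: ClusterModel | None = None,
    stability_threshold: float = 0.97,
    n_init: int = 10,
) -> StabilityResult:
    """Cluster stability by repeated 80/20 subsample refits.

    Each iteration fits k-means on a random ``train_frac`` subsample,
    assigns *all* cells to the nearest iteration centroid, matches
    iteration clusters to the full-data clusters by minimum-total-distance
    centroid pairing, and records whether each cell keeps its full-data
    cluster.  The per-cell retention probability and the per-iteration
    agreement fraction serve as k-selection diagnostics; clustering is
    flagged unstable when mean retention falls below ``stability_threshold``.
    The default threshold (0.97) was calibrated on synthetic data: genuinely
    separated clusters retain essentially every cell, while a single
    isotropic Gaussian forced to k=2 retains 0.73-0.93 of cells on average
    (the subsample split direction is anchored by sample anisotropy, so null
    retention sits well above chance).
    """
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    n_train = int(round(train_frac * matrix.n))
    if n_train < k:
        raise ValueError("training fraction leaves fewer samples than clusters")
    rng = stream(seed, "bootstrap")
    if model is None:
        model = fit_kmeans(matrix, k, seed=int(rng.integers(2**31 - 1)), n_init=n_init)
    full_labels = model.assign(matrix.values)

    retained = np.zeros(matrix.n)
    agreement = np.empty(n_iter)
    for it in range(n_iter):
        idx = rng.choice(matrix.n, size=n_train, replace=False)
        km = KMeans(n_clusters=k, n_init=n_init,
                    random_state=int(rng.integers(2**31 - 1))).fit(matrix.values[idx])
        mapping = _match_centroids(model.centroids, km.cluster_centers_)
        it_labels = mapping[
            np.argmin(
                np.linalg.norm(matrix.values[:, None, :] - km.cluster_centers_[None], axis=2),
                axis=1,
            )
        ]
        same = it_labels == full_labels
        retained += same
        agreement[it] = same.mean()

    retention = retained / n_iter
    mean_ret = float(retention.mean())
    return StabilityResult(
        retention_probability=retention,
        iteration_agreement=agreement,
        mean_retention=mean_ret,
        mean_agreement=float(agreement.mean()),
        stable=mean_ret >= stability_threshold,
        stability_threshold=stability_threshold,
        n_iter=n_iter,
    )


def label_clusters(model: ClusterModel,
                   expected_signs: dict[str, int] = EXPECTED_SIGNS) -> ClusterModel:
    """Name the k=2 centroids "hyperexcitable" / "normal" by loading signs.

    For each feature with an expected hyperexcitable sign, the centroid on
    the expected side (higher for +, lower for -) earns one vote; the
    majority winner is hyperexcitable.  A tie demands a manual label.
    """
    if model.k != 2:
        raise ValueError("labelling is defined for k=2 models only")
    votes = [0, 0]
    for feat, sign in expected_signs.items():
        if feat not in model.feature_names:
            continue
        j = model.feature_names.index(feat)
        a, b = model.centroids[0, j], model.centroids[1, j]
        if a == b:
            continue
        winner = int((b - a) * sign > 0)  # centroid further in the expected direction
        votes[winner] += 1
    if votes[0] == votes[1]:
        raise ValueError("tie vote on centroid loadings; assign labels manually")
    hyper = int(votes[1] > votes[0])
    model.cluster_names = {hyper: "hyperexcitable", 1 - hyper: "normal"}
    return model


def membership_residuals(model: ClusterModel, matrix: FeatureMatrix,
                         retention: np.ndarray | None = None) -> MembershipResult:
    """Signed membership strength relative to the unity line.

    Distances to the hyperexcitable (d_H) and normal (d_N) centroids are
    z-scored across cells; residual = (z(d_N) - z(d_H)) / sqrt(2), the
    perpendicular offset from the unity line.  Positive = closer to the
    hyperexcitable centroid than typical, i.e. more hyperexcitable.
    """
    if not model.cluster_names:
        raise ValueError("label_clusters must be applied first")
    d = model.distances(matrix.values)
    mu, sd = d.mean(axis=0), d.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    z = (d - mu) / sd
    hyper = next(i for i, nm in model.cluster_names.items() if nm == "hyperexcitable")
    normal = 1 - hyper
    residual = (z[:, normal] - z[:, hyper]) / np.sqrt(2.0)
    assigned = model.assign(matrix.values)
    return MembershipResult(
        distances=d,
        z_distances=z,
        residual=residual,
        assigned=assigned,
        assigned_name=[model.cluster_names[int(a)] for a in assigned],
        retention_probability=retention,
    )


def compare_residuals(residuals: np.ndarray, genotype, age):
    """Two-way ANOVA (type II) on residuals with Tukey HSD contrasts.

    Returns ``(anova_table, tukey_frame)`` where the Tukey comparison is run
    over the genotype x age cell combinations.
    """
    from .stats import anova  # local import to avoid cycle at import time

    df = pd.DataFrame({
        "residual": np.asarray(residuals, dtype=float),
        "genotype": np.asarray(genotype),
        "age": np.asarray(age),
    })
    return anova(df["residual"], {"genotype": df["genotype"], "age": df["age"]},
                 design="twoway")
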