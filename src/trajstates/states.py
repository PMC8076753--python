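"""State discovery: pool high-density points, pick k, cluster, assign.

High-density timepoints from all subjects are stacked and clustered with
k-means; the number of clusters can be fixed or chosen by a geometric
elbow rule on the within-cluster sum-of-squares (WSS) curve. The fitted
centroids — the high-traffic nodes — then label every timepoint of every
subject by nearest centroid. Centroids are NOT re-fitted during
assignment: they are defined purely by the high-density points, which is
the point of the method (an optional refit reproduces the alternative
reading where k-means is re-run on all data seeded at the centroids).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .density import DensityProfile
from .io import TrajectorySet

__all__ = [
    "StateModel",
    "StateSequence",
    "pool_high_density",
    "select_k_elbow",
    "fit_states",
    "assign_states",
]

DEFAULT_RESTARTS = 50


@dataclass
class StateModel:
    """Fitted high-traffic nodes: k centroids in C-space plus provenance."""

    k: int
    centroids: np.ndarray
    seed: int
    k_selection: str = "fixed"
    wss_curve: dict[int, float] = field(default_factory=dict)
    inertia: float = float("nan")

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count does not match k")

    @property
    def n_components(self) -> int:
        return self.centroids.shape[1]


@dataclass
class StateSequence:
    """Per-subject state labels, one 1-based label in 1..k per timepoint."""

    labels: dict[str, np.ndarray]
    k: int

    def __post_init__(self) -> None:
        for sid, lab in self.labels.items():
            lab = np.asarray(lab, dtype=int)
            if lab.size and (lab.min() < 1 or lab.max() > self.k):
                raise ValueError(f"subject {sid!r}: labels outside 1..{self.k}")
            self.labels[sid] = lab

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (sid, t, int(state))
            for sid, lab in self.labels.items()
            for t, state in enumerate(lab)
        ]
        return pd.DataFrame(rows, columns=["subject", "time_index", "state"])


def pool_high_density(
    trajectories: TrajectorySet, profile: DensityProfile
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack all subjects' high-density points into one M x C matrix.

    Returns the matrix and a provenance frame with one (subject,
    time_index) row per pooled point. Subjects contributing zero points
    trigger a warning.
    """
    blocks: list[np.ndarray] = []
    prov: list[tuple[str, int]] = []
    for sid in trajectories.subjects:
        mask = profile.mask[sid]
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            warnings.warn(
                f"subject {sid!r} contributes no high-density points", RuntimeWarning, stacklevel=2
            )
            continue
        blocks.append(trajectories.data[sid][idx])
        prov.extend((sid, int(t)) for t in idx)
    if not blocks:
        raise ValueError("no high-density points selected for any subject")
    pooled = np.concatenate(blocks, axis=0)
    provenance = pd.DataFrame(prov, columns=["subject", "time_index"])
    return pooled, provenance


def _best_kmeans(
    points: np.ndarray,
    k: int,
    seed: int,
    restarts: int,
    warm_centroids: np.ndarray | None = None,
) -> KMeans:
    """Best-of-restarts k-means; optionally also tries a warm start built
    from a (k-1)-solution plus its worst-served point, which guarantees the
    WSS curve is non-increasing in k."""
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed % (2**31)).fit(points)
    if warm_centroids is not None and warm_centroids.shape[0] == k - 1:
        d = cdist(points, warm_centroids).min(axis=1)
        extra = points[int(np.argmax(d))]
        init = np.vstack([warm_centroids, extra])
        km_warm = KMeans(n_clusters=k, n_init=1, init=init, random_state=seed % (2**31)).fit(
            points
        )
        if km_warm.inertia_ < km.inertia_:
            km = km_warm
    return km


def select_k_elbow(
    points: np.ndarray,
    k_range: range | tuple[int, ...] = range(2, 11),
    seed: int = 0,
    restarts: int = 10,
) -> tuple[int, dict[int, float]]:
    """Choose k by the geometric elbow of the WSS curve.

    k-means is run for every k' in ``k_range``; the chosen k' maximizes the
    perpendicular distance from the (normalized) WSS curve to the chord
    joining its endpoints — a deterministic, parameter-free elbow rule.
    """
    points = np.asarray(points, dtype=float)
    ks = sorted(int(k) for k in k_range)
    if ks[0] < 2 or ks[-1] > points.shape[0] - 1:
        raise ValueError(f"k_range must lie within [2, M-1] = [2, {points.shape[0] - 1}]")
    wss: dict[int, float] = {}
    prev_centroids = None
    for k in ks:
        km = _best_kmeans(points, k, seed + k, restarts, warm_centroids=prev_centroids)
        wss[k] = float(km.inertia_)
        prev_centroids = km.cluster_centers_
    w = np.array([wss[k] for k in ks])
    if np.allclose(w, w[0]):
        raise ValueError("no elbow: WSS curve is flat over the requested k range")
    # normalize both axes to [0, 1] so the chord distance is scale-free
    x = (np.array(ks, dtype=float) - ks[0]) / (ks[-1] - ks[0])
    y = (w - w[-1]) / (w[0] - w[-1])
    # distance from (x, y) to the chord joining (0, 1) and (1, 0)
    dist = np.abs(x + y - 1.0) / np.sqrt(2.0)
    return ks[int(np.argmax(dist))], wss


def fit_states(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
    wss_curve: dict[int, float] | None = None,
    k_selection: str = "fixed",
) -> StateModel:
    """k-means on the pooled high-density points, best of ``restarts``."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] < k:
        raise ValueError(
            f"only {points.shape[0]} high-density points for k={k}; lower the cutoff"
        )
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed % (2**31)).fit(points)
    return StateModel(
        k=k,
        centroids=km.cluster_centers_,
        seed=seed,
        k_selection=k_selection,
        wss_curve=wss_curve or {},
        inertia=float(km.inertia_),
    )


def assign_states(trajectories: TrajectorySet, model: StateModel) -> StateSequence:
    """Label every timepoint of every subject with its nearest centroid.

    Labels are 1-based; distance ties break toward the lowest state index
    (argmin over centroids in order). Centroids are left untouched.
    """
    labels: dict[str, np.ndarray] = {}
    for sid in trajectories.subjects:
        mat = trajectories.data[sid]
        if mat.shape[1] != model.n_components:
            raise ValueError(
                f"subject {sid!r}: C={mat.shape[1]} does not match model C={model.n_components}"
            )
        labels[sid] = cdist(mat, model.centroids).argmin(axis=1) + 1
    return StateSequence(labels=labels, k=model.k)


def refit_states(
    trajectories: TrajectorySet, model: StateModel
) -> tuple[StateModel, StateSequence]:
    """Alternative final step: one k-means on ALL timepoints, initialized at
    the high-density centroids (updates the centroids)."""
    pooled = np.concatenate([trajectories.data[s] for s in trajectories.subjects], axis=0)
    km = KMeans(
        n_clusters=model.k, n_init=1, init=model.centroids, random_state=model.seed % (2**31)
    ).fit(pooled)
    refitted = StateModel(
        k=model.k,
        centroids=km.cluster_centers_,
        seed=model.seed,
        k_selection=model.k_selection,
        wss_curve=model.wss_curve,
        inertia=float(km.inertia_),
    )
    return refitted, assign_states(trajectories, refitted)
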