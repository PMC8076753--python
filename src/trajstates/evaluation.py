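"""Validation machinery: centroid recovery, scenario sweeps, resampling null.

Accuracy of a clustering run is scored as the matched centroid distance:
the minimum-total-cost one-to-one pairing (Hungarian assignment) between
estimated centroids and the true node locations, summed over pairs.

Scenario sweeps mirror the simulation designs used to validate the method:

* scenario 1 — one simulation per path spread; reports the high-density
  mask so the spread's effect on selection can be visualized;
* scenario 2 — one simulation analyzed at several city sizes (balanced and
  unbalanced cluster sizes); shows how the neighborhood size bounds the
  smallest detectable cluster;
* scenario 3 — replicated comparison of clustering all timepoints vs only
  the high-density ones, by matched centroid distance, plus the fraction
  of cluster and noise points passing the threshold;
* scenario 4 — a resampling null: random timepoint subsets of the same
  cardinality as the high-density set are clustered; the empirical p-value
  is the fraction of random subsets achieving a strictly lower matched
  distance than the high-density method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .density import DensityParams, density_series, density_threshold
from .synthetic import LabeledTrajectory, SimulationSpec, generate_trajectory

__all__ = [
    "RecoveryResult",
    "NullTestResult",
    "matched_centroid_distance",
    "run_scenario1",
    "run_scenario2",
    "run_scenario3",
    "run_scenario4_null",
    "run_scenario4",
]

# Scenario geometry: nodes drawn in the unit box with a fixed 0.5 minimum
# separation, so clusters are resolvable at path spread 0.1 and start to
# overlap by 0.3. Noise timepoints are uniform over a box much wider than
# the node box (high noise amplitude): distant noise has low density and is
# excluded by the threshold, which is the regime the method is designed
# for — noise at intermediate distance from the nodes degrades it.
SCENARIO_NODE_BOX = ((0.0, 1.0), (0.0, 1.0))
SCENARIO_MIN_SEPARATION = 0.5
SCENARIO_NOISE_BOX = ((-2.0, 3.0), (-2.0, 3.0))


@dataclass
class RecoveryResult:
    """Matched centroid distance between estimated and true node sets."""

    matched_distance_sum: float
    matching: np.ndarray  # matching[i] = index of truth matched to estimated i
    per_pair: np.ndarray

    def __float__(self) -> float:
        return self.matched_distance_sum


@dataclass
class NullTestResult:
    """One resampling-null test: method distance vs B null distances."""

    method_distance: float
    null_distances: np.ndarray
    p_value: float
    p_value_conservative: float
    n_high_density: int


def matched_centroid_distance(estimated: np.ndarray, truth: np.ndarray) -> RecoveryResult:
    """Optimal one-to-one matching of estimated centroids to true locations.

    Hungarian assignment on the pairwise Euclidean cost matrix; the score
    is the summed distance over matched pairs. Zero iff the two sets are
    identical; invariant to the order of either set.
    """
    estimated = np.atleast_2d(np.asarray(estimated, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if estimated.shape != truth.shape:
        raise ValueError(
            f"estimated {estimated.shape} and truth {truth.shape} must have equal shape"
        )
    cost = cdist(estimated, truth)
    rows, cols = linear_sum_assignment(cost)
    per_pair = cost[rows, cols]
    matching = np.empty(len(rows), dtype=int)
    matching[rows] = cols
    return RecoveryResult(
        matched_distance_sum=float(per_pair.sum()), matching=matching, per_pair=per_pair
    )


# ---------------------------------------------------------------------------
# batched Lloyd k-means
#
# Scenario 4 clusters ~1,000 equally-sized point subsets per replicate; a
# vectorized Lloyd iteration over all subsets at once (kmeans++ init,
# several restarts, best WSS kept) makes that tractable and — applied
# identically to the method's point set and every null draw — keeps the
# comparison symmetric.
# ---------------------------------------------------------------------------


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """kmeans++ seeding, vectorized over a batch. X is (B, M, C)."""
    B, M, _ = X.shape
    centers = np.empty((B, k, X.shape[2]))
    idx = rng.integers(M, size=B)
    centers[:, 0] = X[np.arange(B), idx]
    d2 = ((X - centers[:, None, 0]) ** 2).sum(-1)  # (B, M)
    for j in range(1, k):
        probs = d2 / np.maximum(d2.sum(axis=1, keepdims=True), 1e-300)
        cum = np.cumsum(probs, axis=1)
        u = rng.random((B, 1))
        idx = (cum < u).sum(axis=1).clip(max=M - 1)
        centers[:, j] = X[np.arange(B), idx]
        d2 = np.minimum(d2, ((X - centers[:, None, j]) ** 2).sum(-1))
    return centers


def batched_kmeans(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    restarts: int = 8,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd k-means run simultaneously on a batch of point sets.

    X is (B, M, C); returns (centroids (B, k, C), wss (B,)), the best of
    ``restarts`` kmeans++-seeded runs per batch element. Empty clusters are
    re-seeded at the point farthest from its assigned centroid.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    B, M, C = X.shape
    if M < k:
        raise ValueError(f"batch point sets of size {M} cannot support k={k}")
    best_wss = np.full(B, np.inf)
    best_centers = np.empty((B, k, C))
    b_idx = np.arange(B)
    for _ in range(restarts):
        centers = _kmeans_pp_init(X, k, rng)
        prev = np.inf
        for _ in range(max_iter):
            d2 = ((X[:, :, None, :] - centers[:, None, :, :]) ** 2).sum(-1)  # (B, M, k)
            assign = d2.argmin(axis=2)
            onehot = assign[..., None] == np.arange(k)  # (B, M, k)
            counts = onehot.sum(axis=1)  # (B, k)
            sums = np.einsum("bmc,bmk->bkc", X, onehot.astype(float))
            new_centers = sums / np.maximum(counts[..., None], 1)
            empty_b, empty_k = np.nonzero(counts == 0)
            if empty_b.size:
                worst = d2.min(axis=2).argmax(axis=1)  # farthest point per batch
                new_centers[empty_b, empty_k] = X[empty_b, worst[empty_b]]
            wss = (d2.min(axis=2)).sum(axis=1)
            shift = np.abs(prev - wss).max() if np.ndim(prev) else np.inf
            centers = new_centers
            prev = wss
            if shift < tol:
                break
        d2 = ((X[:, :, None, :] - centers[:, None, :, :]) ** 2).sum(-1)
        wss = d2.min(axis=2).sum(axis=1)
        better = wss < best_wss
        best_wss[better] = wss[better]
        best_centers[better] = centers[better]
    return best_centers, best_wss


# ---------------------------------------------------------------------------
# scenario runners
# ---------------------------------------------------------------------------


def _scenario_spec(
    path_spread: float,
    cluster_sizes: tuple[int, ...] = (50, 50, 50),
    n_noise: int | None = None,
    seed: int = 0,
) -> SimulationSpec:
    return SimulationSpec(
        n_nodes=len(cluster_sizes),
        dims=2,
        node_locations="random",
        cluster_sizes=cluster_sizes,
        path_spread=path_spread,
        n_noise=n_noise,
        noise_box=SCENARIO_NOISE_BOX,
        node_box=SCENARIO_NODE_BOX,
        min_separation=SCENARIO_MIN_SEPARATION,
        seed=seed,
    )


def _mask_for(traj: LabeledTrajectory, params: DensityParams) -> np.ndarray:
    d = density_series(traj.points, params.resolve_city_size(traj.n_points))
    return d > density_threshold(d, params)


def run_scenario1(
    path_spreads=(0.1, 0.2, 0.3),
    cluster_size: int = 60,
    city_size: int = 20,
    cutoff: float = 0.9,
    seed: int = 0,
) -> dict[float, tuple[LabeledTrajectory, np.ndarray]]:
    """One simulation per path spread; returns trajectory + selection mask."""
    rng = np.random.default_rng(seed)
    params = DensityParams(city_size=city_size, cutoff=cutoff)
    out = {}
    for ps in path_spreads:
        traj = generate_trajectory(_scenario_spec(ps, (cluster_size,) * 3), rng=rng)
        out[ps] = (traj, _mask_for(traj, params))
    return out


def run_scenario2(
    city_sizes=(10, 20, 40, 60),
    cluster_sizes: tuple[int, ...] = (60, 60, 60),
    path_spread: float = 0.1,
    cutoff: float = 0.9,
    seed: int = 0,
) -> tuple[LabeledTrajectory, dict[int, np.ndarray]]:
    """One simulation analyzed at several city sizes; returns the masks.

    With unbalanced ``cluster_sizes`` (e.g. 30/50/80) a city size larger
    than the smallest cluster leaves that cluster without any high-density
    points — the behavior the city-size parameter is designed to control.
    """
    rng = np.random.default_rng(seed)
    traj = generate_trajectory(_scenario_spec(path_spread, tuple(cluster_sizes)), rng=rng)
    masks = {
        cs: _mask_for(traj, DensityParams(city_size=cs, cutoff=cutoff)) for cs in city_sizes
    }
    return traj, masks


def _fit_centroids(points: np.ndarray, k: int, rng: np.random.Generator, restarts: int) -> np.ndarray:
    centers, _ = batched_kmeans(points[None], k, rng, restarts=restarts)
    return centers[0]


def run_scenario3(
    path_spreads=(0.1, 0.2, 0.3),
    n_reps: int = 200,
    cluster_sizes: tuple[int, ...] = (50, 50, 50),
    n_noise: int | None = None,
    city_size: int = 50,
    cutoff: float = 0.9,
    k: int = 3,
    restarts: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """High-density vs all-points clustering accuracy across path spreads.

    Per replicate: simulate, threshold, cluster twice (all timepoints vs
    high-density only) and score both by matched centroid distance to the
    true nodes. Also records the fraction of cluster-member and of noise
    points passing the density threshold.

    Returns one row per path spread with the replicate means.
    """
    rng = np.random.default_rng(seed)
    params = DensityParams(city_size=city_size, cutoff=cutoff)
    rows = []
    for ps in path_spreads:
        rec = {
            "dist_high_density": [],
            "dist_all_points": [],
            "cluster_pass_frac": [],
            "noise_pass_frac": [],
            "n_high_density": [],
        }
        for _ in range(n_reps):
            traj = generate_trajectory(
                _scenario_spec(ps, tuple(cluster_sizes), n_noise=n_noise), rng=rng
            )
            mask = _mask_for(traj, params)
            is_noise = traj.is_noise
            rec["cluster_pass_frac"].append(mask[~is_noise].mean())
            rec["noise_pass_frac"].append(mask[is_noise].mean() if is_noise.any() else 0.0)
            rec["n_high_density"].append(int(mask.sum()))
            hd = traj.points[mask]
            if hd.shape[0] >= k:
                cent_hd = _fit_centroids(hd, k, rng, restarts)
                rec["dist_high_density"].append(
                    matched_centroid_distance(cent_hd, traj.node_locations).matched_distance_sum
                )
            cent_all = _fit_centroids(traj.points, k, rng, restarts)
            rec["dist_all_points"].append(
                matched_centroid_distance(cent_all, traj.node_locations).matched_distance_sum
            )
        rows.append(
            {
                "path_spread": ps,
                "n_reps": n_reps,
                **{key: float(np.mean(vals)) for key, vals in rec.items()},
            }
        )
    return pd.DataFrame(rows)


def run_scenario4_null(
    traj: LabeledTrajectory,
    params: DensityParams,
    k: int = 3,
    n_draws: int = 1000,
    restarts: int = 8,
    rng: np.random.Generator | int | None = None,
) -> NullTestResult:
    """Resampling null test for one simulated trajectory.

    The high-density points are clustered (k-means, k fixed at the
    simulated truth) and scored by matched centroid distance. Then
    ``n_draws`` random timepoint subsets of the same cardinality are drawn
    without replacement, clustered identically, and scored. The empirical
    p-value counts strictly lower null distances; a conservative
    (count+1)/(B+1) variant is reported alongside.
    """
    rng = np.random.default_rng(rng)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    mask = _mask_for(traj, params)
    m = int(mask.sum())
    if m < k:
        raise ValueError(f"only {m} high-density points for k={k}; lower the cutoff")
    truth = traj.node_locations
    method_cent = _fit_centroids(traj.points[mask], k, rng, restarts)
    method_dist = matched_centroid_distance(method_cent, truth).matched_distance_sum
    T = traj.n_points
    subsets = np.stack([rng.choice(T, size=m, replace=False) for _ in range(n_draws)])
    null_points = traj.points[subsets]  # (B, m, C)
    null_centers, _ = batched_kmeans(null_points, k, rng, restarts=restarts)
    null_dists = np.array(
        [matched_centroid_distance(c, truth).matched_distance_sum for c in null_centers]
    )
    n_lower = int((null_dists < method_dist).sum())
    return NullTestResult(
        method_distance=method_dist,
        null_distances=null_dists,
        p_value=n_lower / n_draws,
        p_value_conservative=(int((null_dists <= method_dist).sum()) + 1) / (n_draws + 1),
        n_high_density=m,
    )


def run_scenario4(
    path_spreads=(0.1, 0.2, 0.3),
    n_reps: int = 100,
    n_draws: int = 1000,
    cluster_sizes: tuple[int, ...] = (50, 50, 50),
    n_noise: int | None = None,
    city_size: int = 50,
    cutoff: float = 0.9,
    k: int = 3,
    restarts: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated resampling-null sweep; one row of mean p per path spread."""
    rng = np.random.default_rng(seed)
    params = DensityParams(city_size=city_size, cutoff=cutoff)
    rows = []
    for ps in path_spreads:
        pvals, pcons = [], []
        for _ in range(n_reps):
            traj = generate_trajectory(
                _scenario_spec(ps, tuple(cluster_sizes), n_noise=n_noise), rng=rng
            )
            res = run_scenario4_null(
                traj, params, k=k, n_draws=n_draws, restarts=restarts, rng=rng
            )
            pvals.append(res.p_value)
            pcons.append(res.p_value_conservative)
        rows.append(
            {
                "path_spread": ps,
                "n_reps": n_reps,
                "n_draws": n_draws,
                "mean_p": float(np.mean(pvals)),
                "mean_p_conservative": float(np.mean(pcons)),
                "max_p": float(np.max(pvals)),
            }
        )
    return pd.DataFrame(rows)
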