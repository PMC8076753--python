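"""Per-timepoint density, subject-level threshold, and the high-density mask.

The density of timepoint t is the reciprocal of the summed Euclidean
distances from x_t to its ``city_size`` nearest other timepoints of the
same subject:

    d_t = 1 / sum_{t0 in N_t} ||x_t - x_t0||_2

where N_t holds the ``city_size`` nearest neighbors of t (self excluded).
The city size sets the smallest cluster the statistic can resolve: a
neighborhood larger than a cluster is forced to include far-away points,
deflating the cluster members' density.

Each subject then gets its own threshold, a fraction ``cutoff`` of that
subject's maximum density (or of the mean of the top-percentile densities,
to blunt outliers), and timepoints strictly above the threshold form the
subject's high-density mask. Because the statistic is built entirely from
pairwise distances it is invariant to adding a constant offset per
component, i.e. insensitive to the absolute level of the time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import TrajectorySet

__all__ = [
    "DensityParams",
    "DensityProfile",
    "density_series",
    "density_threshold",
    "high_density_mask",
    "default_city_size",
]

THRESHOLD_MODES = ("max", "top_percentile_mean")


def default_city_size(n_timepoints: int) -> int:
    """Rule-of-thumb neighborhood size: 10% of the series length."""
    return max(1, int(round(0.10 * n_timepoints)))


@dataclass(frozen=True)
class DensityParams:
    """Density / threshold parameters.

    city_size : neighborhood cardinality (None -> 10% of T per subject).
    cutoff : fraction in (0, 1] of the reference density forming the
        threshold; 0.9 is the documented default.
    threshold_mode : "max" uses the subject's maximum density as reference,
        "top_percentile_mean" uses the mean of the top ``top_percentile``
        percent of densities (outlier-robust alternative).
    """

    city_size: int | None = None
    cutoff: float = 0.9
    threshold_mode: str = "max"
    top_percentile: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff <= 1.0):
            raise ValueError(f"cutoff must be in (0, 1], got {self.cutoff}")
        if self.threshold_mode not in THRESHOLD_MODES:
            raise ValueError(
                f"threshold_mode must be one of {THRESHOLD_MODES}, got {self.threshold_mode!r}"
            )
        if self.city_size is not None and self.city_size < 1:
            raise ValueError("city_size must be >= 1")
        if not (0.0 < self.top_percentile <= 100.0):
            raise ValueError("top_percentile must be in (0, 100]")

    def resolve_city_size(self, n_timepoints: int) -> int:
        cs = self.city_size if self.city_size is not None else default_city_size(n_timepoints)
        if cs > n_timepoints - 1:
            raise ValueError(
                f"city_size {cs} out of range for T={n_timepoints} (must be <= T-1)"
            )
        return cs


@dataclass
class DensityProfile:
    """Per-subject density series, thresholds, and high-density masks."""

    density: dict[str, np.ndarray]
    threshold: dict[str, float]
    mask: dict[str, np.ndarray]
    params: DensityParams
    flagged: list[str] = field(default_factory=list)

    def n_selected(self, subject: str) -> int:
        return int(self.mask[subject].sum())

    @property
    def total_selected(self) -> int:
        return int(sum(m.sum() for m in self.mask.values()))


def density_series(points: np.ndarray, city_size: int) -> np.ndarray:
    """Density of every timepoint of one subject.

    For each row, Euclidean distances to all other rows are computed, the
    ``city_size`` smallest are summed, and the reciprocal is returned. A
    distance sum of exactly zero (all neighbors duplicated) is floored at
    1e-12 times the data scale so the density stays finite.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    T = points.shape[0]
    if not 1 <= city_size <= T - 1:
        raise ValueError(f"city_size must be in [1, T-1] = [1, {T - 1}], got {city_size}")
    dist = squareform(pdist(points))
    np.fill_diagonal(dist, np.inf)  # exclude self from the neighborhood
    nearest = np.partition(dist, city_size - 1, axis=1)[:, :city_size]
    sums = nearest.sum(axis=1)
    scale = max(1.0, float(np.abs(points).max()))
    floor = 1e-12 * scale
    if np.any(sums < floor):
        warnings.warn(
            "duplicate timepoints produced a zero distance sum; density floored",
            RuntimeWarning,
            stacklevel=2,
        )
        sums = np.maximum(sums, floor)
    return 1.0 / sums


def density_series_naive(points: np.ndarray, city_size: int) -> np.ndarray:
    """Literal double-loop density; the reference oracle for testing."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    T = points.shape[0]
    if not 1 <= city_size <= T - 1:
        raise ValueError("city_size out of range")
    out = np.empty(T)
    for t in range(T):
        dists = sorted(
            float(np.linalg.norm(points[t] - points[t0])) for t0 in range(T) if t0 != t
        )
        out[t] = 1.0 / max(sum(dists[:city_size]), 1e-300)
    return out


def density_threshold(density: np.ndarray, params: DensityParams) -> float:
    """Subject-level threshold: ``reference density x cutoff``."""
    density = np.asarray(density, dtype=float)
    if density.size == 0:
        raise ValueError("density vector is empty")
    if not np.all(np.isfinite(density)):
        raise ValueError("density vector contains non-finite values")
    if params.threshold_mode == "max":
        reference = float(density.max())
    else:
        cut = np.percentile(density, 100.0 - params.top_percentile)
        reference = float(density[density >= cut].mean())
    return reference * params.cutoff


def high_density_mask(
    trajectories: TrajectorySet, params: DensityParams | None = None
) -> DensityProfile:
    """Compute densities, thresholds, and strict-inequality masks per subject.

    A subject whose mask selects zero timepoints (possible with
    ``top_percentile_mean``, or with ``cutoff == 1`` and a unique maximum)
    is flagged and a warning emitted; it is never dropped silently.
    """
    params = params or DensityParams()
    densities: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    masks: dict[str, np.ndarray] = {}
    flagged: list[str] = []
    for sid in trajectories.subjects:
        mat = trajectories.data[sid]
        cs = params.resolve_city_size(mat.shape[0])
        d = density_series(mat, cs)
        thr = density_threshold(d, params)
        mask = d > thr
        if not mask.any():
            flagged.append(sid)
            warnings.warn(
                f"subject {sid!r}: no timepoint exceeds the density threshold "
                f"({thr:.6g}); subject flagged",
                RuntimeWarning,
                stacklevel=2,
            )
        densities[sid] = d
        thresholds[sid] = thr
        masks[sid] = mask
    return DensityProfile(
        density=densities, threshold=thresholds, mask=masks, params=params, flagged=flagged
    )
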