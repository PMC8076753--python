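"""Simulated trajectories with known high-traffic nodes.

A simulated "subject" is a temporal sequence of points in a C-dimensional
component space. Most points scatter isotropically (Gaussian, std =
``path_spread``) around a small number of node locations ``L_i``; the rest
are uniform noise points belonging to no node. The generator carries the
ground-truth node index of every point so that downstream density
thresholding and clustering can be scored against the truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SimulationSpec",
    "LabeledTrajectory",
    "sample_node_locations",
    "generate_trajectory",
    "write_trajectory",
    "read_trajectory",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated trajectory.

    Parameters
    ----------
    n_nodes : int
        Number of high-traffic nodes (clusters).
    dims : int
        Dimensionality C of the component space.
    node_locations : "random" or sequence of C-vectors
        Fixed node locations, or ``"random"`` to draw them uniformly in
        ``node_box`` subject to ``min_separation``.
    cluster_sizes : sequence of int
        Number of timepoints CS_i drawn around each node.
    path_spread : float
        Standard deviation of the isotropic Gaussian scatter around each
        node; models the noise level of the trajectory.
    n_noise : int or None
        Number of uniform noise timepoints; ``None`` means 10% of the total
        cluster size.
    noise_box : sequence of (low, high) per dimension, or None
        Support of the uniform noise; ``None`` means the bounding box of the
        node locations padded by ``3 * path_spread`` on every side.
    node_box : sequence of (low, high) per dimension
        Sampling box for random node locations.
    min_separation : float or None
        Minimum pairwise Euclidean distance enforced (by rejection sampling)
        between randomly drawn node locations; ``None`` means
        ``10 * path_spread``.
    seed : int
        Seed for all randomness of this spec.
    """

    n_nodes: int = 3
    dims: int = 2
    node_locations: object = "random"
    cluster_sizes: Sequence[int] = (50, 50, 50)
    path_spread: float = 0.1
    n_noise: int | None = None
    noise_box: Sequence[Sequence[float]] | None = None
    node_box: Sequence[Sequence[float]] = field(default=None)  # type: ignore[assignment]
    min_separation: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.dims < 1:
            raise ValueError("dims must be >= 1")
        if len(self.cluster_sizes) != self.n_nodes:
            raise ValueError(
                f"cluster_sizes has {len(self.cluster_sizes)} entries for "
                f"{self.n_nodes} nodes"
            )
        if any(cs < 0 for cs in self.cluster_sizes):
            raise ValueError("cluster sizes must be nonnegative")
        if self.path_spread < 0:
            raise ValueError("path_spread must be nonnegative")
        if self.n_noise is not None and self.n_noise < 0:
            raise ValueError("n_noise must be nonnegative")
        object.__setattr__(self, "cluster_sizes", tuple(int(c) for c in self.cluster_sizes))
        if self.node_box is None:
            object.__setattr__(self, "node_box", ((0.0, 1.0),) * self.dims)
        else:
            object.__setattr__(
                self, "node_box", tuple(tuple(float(v) for v in b) for b in self.node_box)
            )
        if self.noise_box is not None:
            object.__setattr__(
                self, "noise_box", tuple(tuple(float(v) for v in b) for b in self.noise_box)
            )
        if not isinstance(self.node_locations, str):
            locs = np.asarray(self.node_locations, dtype=float)
            if locs.shape != (self.n_nodes, self.dims):
                raise ValueError(
                    f"node_locations shape {locs.shape} does not match "
                    f"({self.n_nodes}, {self.dims})"
                )
            object.__setattr__(self, "node_locations", locs.tolist())
        elif self.node_locations != "random":
            raise ValueError("node_locations must be 'random' or explicit vectors")

    @property
    def total_cluster_points(self) -> int:
        return int(sum(self.cluster_sizes))

    @property
    def effective_n_noise(self) -> int:
        if self.n_noise is not None:
            return int(self.n_noise)
        return int(round(0.10 * self.total_cluster_points))

    @property
    def effective_min_separation(self) -> float:
        if self.min_separation is not None:
            return float(self.min_separation)
        return 10.0 * self.path_spread

    @property
    def n_points(self) -> int:
        return self.total_cluster_points + self.effective_n_noise

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        payload["cluster_sizes"] = list(self.cluster_sizes)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SimulationSpec":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        return cls(**payload)


@dataclass
class LabeledTrajectory:
    """A simulated trajectory with ground truth.

    ``points`` is the T x C temporal sequence; ``true_labels[t]`` is the
    1-based node index that generated point t, or 0 for noise points.
    ``node_locations`` are the resolved (possibly randomly drawn) L_i.
    """

    points: np.ndarray
    true_labels: np.ndarray
    node_locations: np.ndarray
    spec: SimulationSpec

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.true_labels = np.asarray(self.true_labels, dtype=int)
        self.node_locations = np.asarray(self.node_locations, dtype=float)
        if self.points.shape[0] != self.true_labels.shape[0]:
            raise ValueError("points and true_labels length mismatch")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def is_noise(self) -> np.ndarray:
        return self.true_labels == 0


def sample_node_locations(
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
    max_attempts: int = 100_000,
) -> np.ndarray:
    """Resolve the node locations of ``spec``.

    Fixed locations pass through unchanged. Random locations are drawn
    uniformly in ``spec.node_box`` and rejected until all pairwise distances
    reach ``spec.effective_min_separation``.
    """
    if not isinstance(spec.node_locations, str):
        return np.asarray(spec.node_locations, dtype=float)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.node_box, dtype=float)
    lo, hi = box[:, 0], box[:, 1]
    sep = spec.effective_min_separation
    for _ in range(max_attempts):
        locs = rng.uniform(lo, hi, size=(spec.n_nodes, spec.dims))
        if spec.n_nodes == 1:
            return locs
        diff = locs[:, None, :] - locs[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        iu = np.triu_indices(spec.n_nodes, k=1)
        if np.all(dist[iu] >= sep):
            return locs
    raise RuntimeError(
        f"could not draw {spec.n_nodes} node locations with pairwise "
        f"separation >= {sep} in box {box.tolist()} after {max_attempts} "
        f"attempts; lower min_separation or enlarge node_box"
    )


def generate_trajectory(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> LabeledTrajectory:
    """Draw one labeled trajectory from ``spec``.

    CS_i points are drawn from an isotropic Gaussian (std ``path_spread``)
    around each node, ``n_noise`` points uniformly from the noise box, and
    the full set is shuffled into one random temporal order. The density
    statistic is order-invariant, so the shuffle only matters for dwell and
    transition demonstrations.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    locations = sample_node_locations(spec, rng)
    chunks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for i, cs in enumerate(spec.cluster_sizes):
        pts = locations[i] + spec.path_spread * rng.standard_normal((int(cs), spec.dims))
        chunks.append(pts)
        labels.append(np.full(int(cs), i + 1, dtype=int))
    n_noise = spec.effective_n_noise
    if n_noise > 0:
        if spec.noise_box is not None:
            box = np.asarray(spec.noise_box, dtype=float)
        else:
            pad = 3.0 * spec.path_spread
            lo = locations.min(axis=0) - pad
            hi = locations.max(axis=0) + pad
            # a degenerate box (single node, zero spread) gets a unit width
            flat = hi - lo <= 0
            lo[flat] -= 0.5
            hi[flat] += 0.5
            box = np.stack([lo, hi], axis=1)
        noise = rng.uniform(box[:, 0], box[:, 1], size=(n_noise, spec.dims))
        chunks.append(noise)
        labels.append(np.zeros(n_noise, dtype=int))
    points = np.concatenate(chunks, axis=0)
    all_labels = np.concatenate(labels)
    order = rng.permutation(points.shape[0])
    return LabeledTrajectory(
        points=points[order],
        true_labels=all_labels[order],
        node_locations=locations,
        spec=spec,
    )


def write_trajectory(traj: LabeledTrajectory, outdir: str | Path, stem: str = "trajectory") -> dict:
    """Write a trajectory as delimited text plus sidecar labels and spec JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    points_path = outdir / f"{stem}_points.csv"
    labels_path = outdir / f"{stem}_labels.csv"
    spec_path = outdir / f"{stem}_spec.json"
    nodes_path = outdir / f"{stem}_nodes.csv"
    np.savetxt(points_path, traj.points, delimiter=",", fmt="%.17g")
    np.savetxt(labels_path, traj.true_labels[:, None], delimiter=",", fmt="%d")
    np.savetxt(nodes_path, traj.node_locations, delimiter=",", fmt="%.17g")
    traj.spec.to_json(spec_path)
    return {
        "points": str(points_path),
        "labels": str(labels_path),
        "nodes": str(nodes_path),
        "spec": str(spec_path),
    }


def read_trajectory(outdir: str | Path, stem: str = "trajectory") -> LabeledTrajectory:
    outdir = Path(outdir)
    points = np.loadtxt(outdir / f"{stem}_points.csv", delimiter=",", ndmin=2)
    labels = np.loadtxt(outdir / f"{stem}_labels.csv", delimiter=",", dtype=int, ndmin=1)
    nodes = np.loadtxt(outdir / f"{stem}_nodes.csv", delimiter=",", ndmin=2)
    spec = SimulationSpec.from_json(outdir / f"{stem}_spec.json")
    return LabeledTrajectory(points=points, true_labels=labels, node_locations=nodes, spec=spec)
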