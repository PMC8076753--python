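"""Data containers, manifest reading, and run configuration.

The interchange format for component time courses is delimited text: one
matrix per subject, rows = timepoints, columns = components. A JSON
manifest lists the per-subject files and optional group labels.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["TrajectorySet", "Manifest", "RunConfig", "read_manifest", "write_manifest"]


@dataclass
class TrajectorySet:
    """Per-subject T x C component time-course matrices.

    T may differ across subjects; C must not. Subject j's row t is the
    location x_{j,t} of that subject's brain trajectory in component space.
    """

    subjects: list[str]
    data: dict[str, np.ndarray]
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.subjects) != len(set(self.subjects)):
            raise ValueError("subject IDs must be unique")
        if set(self.subjects) != set(self.data):
            raise ValueError("subjects and data keys do not match")
        cs = {}
        for sid in self.subjects:
            mat = np.asarray(self.data[sid], dtype=float)
            if mat.ndim != 2:
                raise ValueError(f"subject {sid!r}: matrix must be 2-D, got {mat.ndim}-D")
            if mat.shape[0] < 3:
                raise ValueError(f"subject {sid!r}: need at least 3 timepoints, got {mat.shape[0]}")
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"subject {sid!r}: matrix contains non-finite values")
            self.data[sid] = mat
            cs[sid] = mat.shape[1]
        if len(set(cs.values())) > 1:
            detail = ", ".join(f"{sid}: C={c}" for sid, c in sorted(cs.items()))
            raise ValueError(f"inconsistent component count across subjects ({detail})")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_components(self) -> int:
        return self.data[self.subjects[0]].shape[1]

    def n_timepoints(self, subject: str) -> int:
        return self.data[subject].shape[0]

    @classmethod
    def from_arrays(
        cls,
        data,
        subject_ids: list[str] | None = None,
        groups: dict[str, str] | None = None,
    ) -> "TrajectorySet":
        """Build from a dict of id -> matrix or a list of matrices."""
        if isinstance(data, dict):
            d = {str(k): np.asarray(v, dtype=float) for k, v in data.items()}
            ids = list(d)
        else:
            mats = [np.asarray(m, dtype=float) for m in data]
            ids = subject_ids or [f"sub-{i + 1:03d}" for i in range(len(mats))]
            d = dict(zip(map(str, ids), mats))
            ids = list(d)
        return cls(subjects=ids, data=d, groups=groups)


@dataclass
class Manifest:
    """JSON manifest describing a set of subject time-course files."""

    subjects: list[dict]
    delimiter: str = ","
    has_header: bool = False
    tr: float | None = None
    version: int = 1

    @classmethod
    def from_json(cls, path: str | Path) -> "Manifest":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"manifest not found: {path}")
        payload = json.loads(path.read_text())
        return cls(
            subjects=payload["subjects"],
            delimiter=payload.get("delimiter", ","),
            has_header=bool(payload.get("has_header", False)),
            tr=payload.get("tr"),
            version=int(payload.get("version", 1)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def read_manifest(path: str | Path) -> TrajectorySet:
    """Read a manifest and load every subject matrix, validating shapes.

    Raises distinct errors for missing files, non-numeric cells and
    inconsistent component counts (the latter names the offending subjects).
    """
    manifest = Manifest.from_json(path)
    base = Path(path).parent
    data: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    ids: list[str] = []
    for entry in manifest.subjects:
        sid = str(entry["id"])
        fpath = Path(entry["path"])
        if not fpath.is_absolute():
            fpath = base / fpath
        if not fpath.exists():
            raise FileNotFoundError(f"subject {sid!r}: matrix file not found: {fpath}")
        try:
            mat = np.loadtxt(
                fpath,
                delimiter=manifest.delimiter,
                skiprows=1 if manifest.has_header else 0,
                ndmin=2,
            )
        except ValueError as exc:
            raise ValueError(f"subject {sid!r}: non-numeric or malformed cell in {fpath}: {exc}") from exc
        ids.append(sid)
        data[sid] = mat
        if entry.get("group") is not None:
            groups[sid] = str(entry["group"])
    return TrajectorySet(subjects=ids, data=data, groups=groups or None)


def write_manifest(
    trajectories: TrajectorySet, outdir: str | Path, delimiter: str = ",", tr: float | None = None
) -> Path:
    """Write every subject matrix plus a manifest pointing at them."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for sid in trajectories.subjects:
        fname = f"{sid}.csv"
        np.savetxt(outdir / fname, trajectories.data[sid], delimiter=delimiter, fmt="%.17g")
        entry = {"id": sid, "path": fname}
        if trajectories.groups and sid in trajectories.groups:
            entry["group"] = trajectories.groups[sid]
        entries.append(entry)
    manifest = Manifest(subjects=entries, delimiter=delimiter, tr=tr)
    mpath = outdir / "manifest.json"
    manifest.to_json(mpath)
    return mpath


@dataclass
class RunConfig:
    """Parameters of one end-to-end run; serializes losslessly to JSON."""

    city_size: int | None = None
    cutoff: float = 0.9
    threshold_mode: str = "max"
    top_percentile: float = 5.0
    k: object = "auto"
    k_min: int = 2
    k_max: int = 10
    restarts: int = 50
    refit: bool = False
    standardize: bool = False
    lag: int = 1
    alpha: float = 0.01
    tr: float | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
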