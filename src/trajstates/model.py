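"""Model/results interface tying the pipeline together.

:class:`DensityStateModel` is built from a set of per-subject component
time courses and the analysis parameters; ``fit()`` runs density
computation, thresholding, pooling, k selection, k-means and state
assignment, and returns a :class:`DensityStateResults` carrying the
density profile, the fitted state model, the per-subject state sequences
and the dynamics metrics, with ``summary()``, group comparison, saving and
plotting attached.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .density import DensityParams, DensityProfile, high_density_mask
from .io import RunConfig, TrajectorySet, read_manifest
from .states import (
    StateModel,
    StateSequence,
    assign_states,
    fit_states,
    pool_high_density,
    refit_states,
    select_k_elbow,
)

__all__ = ["DensityStateModel", "DensityStateResults"]


class DensityStateModel:
    """Density-based state model for multivariate trajectories.

    Parameters
    ----------
    trajectories : TrajectorySet
        Per-subject T x C component time courses.
    city_size : int, optional
        Density neighborhood size; default 10% of each subject's T.
    cutoff : float
        Threshold fraction of the per-subject reference density.
    threshold_mode : {"max", "top_percentile_mean"}
        Reference density used in the threshold.
    k : int or "auto"
        Number of states; "auto" selects by the geometric elbow over
        ``k_range``.
    k_range : iterable of int
        Candidate k values for the elbow search.
    restarts : int
        k-means restarts (best WSS kept).
    standardize : bool
        z-score each component across time per subject before analysis.
    refit : bool
        After assignment, re-run k-means on all timepoints initialized at
        the high-density centroids (alternative final step).
    seed : int
        Seed for all randomness of the fit.
    """

    def __init__(
        self,
        trajectories: TrajectorySet,
        *,
        city_size: int | None = None,
        cutoff: float = 0.9,
        threshold_mode: str = "max",
        top_percentile: float = 5.0,
        k: int | str = "auto",
        k_range=range(2, 11),
        restarts: int = 50,
        standardize: bool = False,
        refit: bool = False,
        seed: int = 0,
    ) -> None:
        if standardize:
            data = {}
            for sid in trajectories.subjects:
                mat = trajectories.data[sid]
                std = mat.std(axis=0, ddof=0)
                data[sid] = (mat - mat.mean(axis=0)) / np.where(std > 0, std, 1.0)
            trajectories = TrajectorySet(
                subjects=list(trajectories.subjects), data=data, groups=trajectories.groups
            )
        self.trajectories = trajectories
        self.params = DensityParams(
            city_size=city_size,
            cutoff=cutoff,
            threshold_mode=threshold_mode,
            top_percentile=top_percentile,
        )
        if k != "auto" and (not isinstance(k, (int, np.integer)) or k < 2):
            raise ValueError("k must be 'auto' or an integer >= 2")
        self.k = k
        self.k_range = list(k_range)
        self.restarts = int(restarts)
        self.standardize = bool(standardize)
        self.refit = bool(refit)
        self.seed = int(seed)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_manifest(cls, path, **kwargs) -> "DensityStateModel":
        return cls(read_manifest(path), **kwargs)

    @classmethod
    def from_arrays(cls, data, subject_ids=None, groups=None, **kwargs) -> "DensityStateModel":
        return cls(TrajectorySet.from_arrays(data, subject_ids, groups), **kwargs)

    @classmethod
    def from_config(cls, trajectories: TrajectorySet, config: RunConfig) -> "DensityStateModel":
        return cls(
            trajectories,
            city_size=config.city_size,
            cutoff=config.cutoff,
            threshold_mode=config.threshold_mode,
            top_percentile=config.top_percentile,
            k=config.k,
            k_range=range(config.k_min, config.k_max + 1),
            restarts=config.restarts,
            standardize=config.standardize,
            refit=config.refit,
            seed=config.seed,
        )

    # -- fitting ----------------------------------------------------------
    def fit(self) -> "DensityStateResults":
        profile = high_density_mask(self.trajectories, self.params)
        pooled, provenance = pool_high_density(self.trajectories, profile)
        wss_curve: dict[int, float] = {}
        if self.k == "auto":
            k_range = [k for k in self.k_range if k <= pooled.shape[0] - 1]
            if not k_range:
                raise ValueError("too few high-density points for the elbow search")
            k, wss_curve = select_k_elbow(
                pooled, k_range, seed=self.seed, restarts=min(self.restarts, 10)
            )
            k_selection = "auto_elbow"
        else:
            k, k_selection = int(self.k), "fixed"
        state_model = fit_states(
            pooled,
            k,
            seed=self.seed,
            restarts=self.restarts,
            wss_curve=wss_curve,
            k_selection=k_selection,
        )
        sequences = assign_states(self.trajectories, state_model)
        if self.refit:
            state_model, sequences = refit_states(self.trajectories, state_model)
        return DensityStateResults(
            model=self,
            profile=profile,
            state_model=state_model,
            sequences=sequences,
            pooled=pooled,
            provenance=provenance,
        )


class DensityStateResults:
    """Fit results: density profile, centroids, state sequences, metrics."""

    def __init__(
        self,
        model: DensityStateModel,
        profile: DensityProfile,
        state_model: StateModel,
        sequences: StateSequence,
        pooled: np.ndarray,
        provenance: pd.DataFrame,
    ) -> None:
        self.model = model
        self.profile = profile
        self.state_model = state_model
        self.sequences = sequences
        self.pooled = pooled
        self.provenance = provenance

    # -- convenience accessors -------------------------------------------
    @property
    def k(self) -> int:
        return self.state_model.k

    @property
    def centroids(self) -> np.ndarray:
        return self.state_model.centroids

    def subject_metrics(self, lag: int = 1, tr: float | None = None) -> pd.DataFrame:
        return _metrics.subject_metrics(self.sequences, lag=lag, tr=tr)

    def compare_groups(
        self,
        groups: dict[str, str] | None = None,
        alpha: float = 0.01,
        lag: int = 1,
        test: str = "welch",
    ) -> pd.DataFrame:
        groups = groups or self.model.trajectories.groups
        if not groups:
            raise ValueError("no group labels available")
        return _metrics.compare_groups(
            self.subject_metrics(lag=lag), groups, alpha=alpha, test=test
        )

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        traj = self.model.trajectories
        lines = [
            "Density-based trajectory state model",
            "=" * 52,
            f"Subjects:             {traj.n_subjects}",
            f"Components (C):       {traj.n_components}",
            f"Timepoints (T):       "
            + ", ".join(str(traj.n_timepoints(s)) for s in traj.subjects[:5])
            + ("..." if traj.n_subjects > 5 else ""),
            f"City size:            {self.profile.params.city_size or 'auto (10% of T)'}",
            f"Cutoff:               {self.profile.params.cutoff}",
            f"Threshold mode:       {self.profile.params.threshold_mode}",
            f"High-density points:  {self.pooled.shape[0]}",
            f"States (k):           {self.k} ({self.state_model.k_selection})",
            f"k-means WSS:          {self.state_model.inertia:.6g}",
            f"Seed:                 {self.model.seed}",
            "",
            "State occupancy (fraction of all timepoints):",
        ]
        all_labels = np.concatenate([self.sequences.labels[s] for s in traj.subjects])
        for s in range(1, self.k + 1):
            frac = float((all_labels == s).mean())
            lines.append(f"  state {s}: {frac:6.1%}")
        if self.state_model.wss_curve:
            lines.append("")
            lines.append("Elbow WSS curve: " + ", ".join(
                f"k={k}: {v:.4g}" for k, v in sorted(self.state_model.wss_curve.items())
            ))
        return "\n".join(lines)

    def save(self, outdir: str | Path, config: RunConfig | None = None, lag: int = 1,
             tr: float | None = None) -> dict[str, str]:
        """Write density CSVs, centroid CSV, states CSV, metrics TSV and a
        run log; every file carries the config hash that produced it."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config = config or RunConfig(
            city_size=self.model.params.city_size,
            cutoff=self.model.params.cutoff,
            threshold_mode=self.model.params.threshold_mode,
            top_percentile=self.model.params.top_percentile,
            k=self.model.k,
            restarts=self.model.restarts,
            refit=self.model.refit,
            standardize=self.model.standardize,
            lag=lag,
            tr=tr,
            seed=self.model.seed,
        )
        chash = config.config_hash()
        header = f"# config_hash={chash}\n"
        written: dict[str, str] = {}

        def _write(name: str, text: str) -> None:
            path = outdir / name
            path.write_text(header + text)
            written[name] = str(path)

        for sid in self.model.trajectories.subjects:
            df = pd.DataFrame(
                {
                    "time_index": np.arange(self.profile.density[sid].size),
                    "density": self.profile.density[sid],
                    "selected": self.profile.mask[sid].astype(int),
                }
            )
            _write(f"density_{sid}.csv", df.to_csv(index=False))
        cent = pd.DataFrame(
            self.centroids, columns=[f"c{j + 1}" for j in range(self.centroids.shape[1])]
        )
        cent.insert(0, "state", np.arange(1, self.k + 1))
        _write("centroids.csv", cent.to_csv(index=False))
        _write("states.csv", self.sequences.to_frame().to_csv(index=False))
        _write("metrics.tsv", self.subject_metrics(lag=lag, tr=tr).to_csv(sep="\t"))
        log = {
            "config": config.to_dict(),
            "config_hash": chash,
            "k": self.k,
            "k_selection": self.state_model.k_selection,
            "wss_curve": {str(k): v for k, v in self.state_model.wss_curve.items()},
            "n_high_density": int(self.pooled.shape[0]),
            "thresholds": {s: float(v) for s, v in self.profile.threshold.items()},
            "flagged_subjects": self.profile.flagged,
        }
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
        written["run_log.json"] = str(outdir / "run_log.json")
        return written

    # -- plotting ---------------------------------------------------------
    def plot_density(self, subject: str, ax=None):
        """Density trace with the subject's threshold and selected points."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        d = self.profile.density[subject]
        thr = self.profile.threshold[subject]
        mask = self.profile.mask[subject]
        t = np.arange(d.size)
        ax.plot(t, d, lw=0.8, color="0.4")
        ax.scatter(t[mask], d[mask], s=12, color="crimson", zorder=3, label="high density")
        ax.axhline(thr, ls="--", color="k", lw=0.8, label="threshold")
        ax.set(xlabel="timepoint", ylabel="density", title=f"subject {subject}")
        ax.legend(frameon=False, fontsize=8)
        return ax

    def plot_states(self, subject: str, ax=None):
        """State sequence of one subject as a step plot."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 2.2))
        lab = self.sequences.labels[subject]
        ax.step(np.arange(lab.size), lab, where="post", lw=1.0)
        ax.set(
            xlabel="timepoint",
            ylabel="state",
            yticks=range(1, self.k + 1),
            title=f"subject {subject}",
        )
        return ax
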