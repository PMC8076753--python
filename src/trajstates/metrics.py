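"""Dynamics metrics on state sequences and case/control comparison.

From each subject's state-label sequence we compute:

* mean dwell time — average length (in timepoints) of maximal consecutive
  runs of each state; multiply by the TR for seconds;
* transition number — how many consecutive-timepoint label changes occur;
* lag-L transition matrix — k x k counts of (state at t, state at t+L)
  pairs, diagonal included.

Group comparison runs a two-sample test per metric entry (Welch t by
default, Mann-Whitney optional) with Benjamini-Hochberg FDR applied within
each metric family: the k dwell-time tests form one family, the k^2
transition-matrix cells another, and the single transition-number test is
reported uncorrected.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .states import StateSequence

__all__ = [
    "run_lengths",
    "mean_dwell_time",
    "transition_number",
    "transition_matrix",
    "subject_metrics",
    "compare_groups",
]


def _validate_labels(labels: np.ndarray, k: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1 or labels.size == 0:
        raise ValueError("labels must be a nonempty 1-D vector")
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"labels must lie in 1..{k}")
    return labels


def run_lengths(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal-run encoding: list of (state, run length) in temporal order."""
    labels = np.asarray(labels, dtype=int)
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [labels.size]])
    return [(int(labels[s]), int(e - s)) for s, e in zip(starts, ends)]


def mean_dwell_time(labels: np.ndarray, k: int) -> np.ndarray:
    """Mean run length per state, NaN for states never visited.

    An unvisited state has no dwell episodes; reporting zero would bias
    group means downward, so it is reported missing instead.
    """
    labels = _validate_labels(labels, k)
    out = np.full(k, np.nan)
    runs = run_lengths(labels)
    for state in range(1, k + 1):
        lens = [length for s, length in runs if s == state]
        if lens:
            out[state - 1] = float(np.mean(lens))
    return out


def transition_number(labels: np.ndarray) -> int:
    """Count of consecutive-timepoint state changes."""
    labels = np.asarray(labels, dtype=int)
    return int(np.count_nonzero(np.diff(labels)))


def transition_matrix(labels: np.ndarray, k: int, lag: int = 1) -> np.ndarray:
    """k x k counts of (state at t, state at t+lag) pairs; sums to T-lag."""
    labels = _validate_labels(labels, k)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if lag >= labels.size:
        raise ValueError(f"lag {lag} must be smaller than T={labels.size}")
    mat = np.zeros((k, k), dtype=int)
    np.add.at(mat, (labels[:-lag] - 1, labels[lag:] - 1), 1)
    return mat


def subject_metrics(
    sequences: StateSequence, lag: int = 1, tr: float | None = None
) -> pd.DataFrame:
    """One row per subject: dwell times, transition number, matrix cells.

    Dwell columns are ``dwell_<s>`` in timepoints (``dwell_<s>_s`` in
    seconds when ``tr`` is given); matrix cells are ``trans_<a>_<b>``.
    """
    k = sequences.k
    rows = []
    for sid, labels in sequences.labels.items():
        row: dict[str, object] = {"subject": sid, "T": int(labels.size)}
        dwell = mean_dwell_time(labels, k)
        for s in range(1, k + 1):
            row[f"dwell_{s}"] = dwell[s - 1]
            if tr is not None:
                row[f"dwell_{s}_s"] = dwell[s - 1] * tr
        row["n_transitions"] = transition_number(labels)
        mat = transition_matrix(labels, k, lag=lag)
        for a in range(1, k + 1):
            for b in range(1, k + 1):
                row[f"trans_{a}_{b}"] = int(mat[a - 1, b - 1])
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (thin wrapper for one family)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def _two_sample(x: np.ndarray, y: np.ndarray, test: str) -> tuple[float, float]:
    if np.allclose(x.var(), 0) and np.allclose(y.var(), 0) and np.isclose(x.mean(), y.mean()):
        return 0.0, 1.0  # identical constant groups: no evidence by definition
    if test == "welch":
        res = stats.ttest_ind(x, y, equal_var=False)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    metrics: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    alpha: float = 0.01,
    test: str = "welch",
    diff_direction: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Two-group comparison of every dynamics metric with per-family FDR.

    Parameters
    ----------
    metrics : frame from :func:`subject_metrics` (index = subject).
    groups : subject -> group label; exactly two groups, each n >= 2.
    alpha : significance level applied to the FDR-adjusted p-values.
    test : "welch" (default) or "mannwhitney".
    diff_direction : optional (g1, g2) ordering; the reported difference is
        mean(g2) - mean(g1). Defaults to sorted group names.

    Returns a frame with one row per metric entry: group means, difference,
    statistic, raw and adjusted p, significance flag. Entries missing for
    more than half of either group (e.g. dwell time of a state that group
    rarely visits) are excluded with a warning.
    """
    groups = pd.Series(dict(groups))
    names = sorted(groups.unique()) if diff_direction is None else list(diff_direction)
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {list(names)}")
    g1_ids = groups.index[groups == names[0]].intersection(metrics.index)
    g2_ids = groups.index[groups == names[1]].intersection(metrics.index)
    if len(g1_ids) < 2 or len(g2_ids) < 2:
        raise ValueError("each group needs at least 2 subjects with metrics")

    dwell_cols = sorted(
        (c for c in metrics.columns if c.startswith("dwell_") and not c.endswith("_s")),
        key=lambda c: int(c.split("_")[1]),
    )
    trans_cols = sorted(c for c in metrics.columns if c.startswith("trans_"))
    families = {
        "dwell": dwell_cols,
        "transition_number": ["n_transitions"] if "n_transitions" in metrics else [],
        "transition_matrix": trans_cols,
    }

    rows = []
    for family, cols in families.items():
        tested = []
        for col in cols:
            x = metrics.loc[g1_ids, col].dropna().to_numpy(dtype=float)
            y = metrics.loc[g2_ids, col].dropna().to_numpy(dtype=float)
            if len(x) < max(2, len(g1_ids) // 2) or len(y) < max(2, len(g2_ids) // 2):
                warnings.warn(
                    f"{col}: metric missing for more than half of a group; excluded",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            stat, p = _two_sample(x, y, test)
            tested.append(
                {
                    "family": family,
                    "metric": col,
                    f"mean_{names[0]}": float(x.mean()),
                    f"mean_{names[1]}": float(y.mean()),
                    "diff": float(y.mean() - x.mean()),
                    "statistic": stat,
                    "p_raw": p,
                }
            )
        if not tested:
            continue
        praw = np.array([r["p_raw"] for r in tested])
        padj = benjamini_hochberg(praw) if family != "transition_number" else praw
        for r, p_adj in zip(tested, padj):
            r["p_fdr"] = float(p_adj)
            r["significant"] = bool(p_adj < alpha)
            rows.append(r)
    return pd.DataFrame(rows)
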