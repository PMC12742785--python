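"""Window-size selection, robust summaries, and the group-comparison battery.

Inference is restricted to an a-priori region of interest (default
channels 1 and 15, the bilateral IFG-triangularis sites of the montage).
Per subject, improv-task window errors are pooled over the ROI channels,
log-transformed (natural log, epsilon-guarded), and condensed into three
robust summaries: median, 10%-per-tail trimmed mean, and the 90th
percentile (linear interpolation, inclusive).  Each summary is compared
between groups with Welch's t, Mann-Whitney U, and a seeded label
permutation test, alongside Cohen's d (pooled SD) and Cliff's delta.

No multiple-testing correction is applied across the 3 summaries x 3
tests: all nine results are reported, as is conventional for an
exploratory a-priori-ROI analysis; readers should weigh them accordingly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .autoencoder import ChannelErrorMap
from .io import CohortManifest

LOG_EPSILON = 1e-12


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given (degenerate) samples."""

    def __init__(self, message: str, cliffs_delta: float | None = None):
        super().__init__(message)
        self.cliffs_delta = cliffs_delta


@dataclass(frozen=True)
class WindowSweepTable:
    """Replicate-averaged train/test reconstruction error per window size."""

    rows: tuple  # of (window_size, train_error, test_error)

    def __post_init__(self) -> None:
        sizes = [r[0] for r in self.rows]
        if len(set(sizes)) != len(sizes):
            raise ValueError("window sizes must be unique")
        if any(r[1] < 0 or r[2] < 0 for r in self.rows):
            raise ValueError("errors must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["window_size", "train_error", "test_error"])


@dataclass(frozen=True)
class RobustSummary:
    median_log_mse: float
    trimmed_mean_log_mse: float
    p90_log_mse: float

    def as_dict(self) -> dict:
        return {
            "median_log_mse": self.median_log_mse,
            "trimmed_mean_log_mse": self.trimmed_mean_log_mse,
            "p90_log_mse": self.p90_log_mse,
        }


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class EffectSizes:
    cohens_d: float
    cliffs_delta: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.cliffs_delta <= 1.0:
            raise ValueError("Cliff's delta outside [-1, 1]")


@dataclass
class GroupComparison:
    summaries: pd.DataFrame  # subject_id, group, median_log_mse, trimmed_mean_log_mse, p90_log_mse
    tests: dict  # (summary_name, method) -> TestResult
    effects: dict  # summary_name -> EffectSizes
    roi_channels: tuple

    def to_dict(self) -> dict:
        return {
            "roi_channels": list(self.roi_channels),
            "summaries": self.summaries.to_dict(orient="records"),
            "tests": {
                f"{summary}|{method}": {
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "method": r.method,
                    "n_a": r.n_a,
                    "n_b": r.n_b,
                }
                for (summary, method), r in sorted(self.tests.items())
            },
            "effect_sizes": {
                summary: {"cohens_d": e.cohens_d, "cliffs_delta": e.cliffs_delta}
                for summary, e in sorted(self.effects.items())
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def to_text(self) -> str:
        lines = [f"ROI channels: {list(self.roi_channels)}", ""]
        lines.append(f"{'summary':<22}{'method':<14}{'statistic':>12}{'p':>10}")
        for (summary, method), r in sorted(self.tests.items()):
            lines.append(f"{summary:<22}{method:<14}{r.statistic:>12.4f}{r.p_value:>10.4f}")
        lines.append("")
        for summary, e in sorted(self.effects.items()):
            lines.append(
                f"{summary:<22}Cohen's d = {e.cohens_d:.3f}   Cliff's delta = {e.cliffs_delta:.3f}"
            )
        return "\n".join(lines)


def select_window_size(table: WindowSweepTable) -> int:
    """Window size with minimum mean test error; ties go to the smallest size."""
    frame = table.to_frame()
    if frame.empty:
        raise ValueError("empty sweep table")
    best = frame.sort_values(["test_error", "window_size"]).iloc[0]
    return int(best["window_size"])


def roi_pool(
    window_errors: np.ndarray,
    provenance: pd.DataFrame,
    roi_channels: Sequence[int],
    channel_ids: Sequence[int],
    task: str = "improv",
) -> dict:
    """Per-subject vectors of window errors averaged over the ROI channels.

    Only windows of the requested task contribute; a subject with no such
    windows raises.
    """
    roi_channels = [int(c) for c in roi_channels]
    if not roi_channels:
        raise ValueError("roi_channels must be non-empty")
    channel_ids = [int(c) for c in channel_ids]
    missing = [c for c in roi_channels if c not in channel_ids]
    if missing:
        raise KeyError(f"invalid ROI channel(s) {missing}; montage has {channel_ids}")
    cols = [channel_ids.index(c) for c in roi_channels]
    pooled = np.asarray(window_errors)[:, cols].mean(axis=1)
    out: dict[str, np.ndarray] = {}
    task_mask = np.asarray(provenance["task"] == task)
    subjects = np.asarray(provenance["subject_id"])
    for sid in pd.unique(subjects):
        mask = task_mask & (subjects == sid)
        if not mask.any():
            raise ValueError(f"subject {sid} has no {task!r} windows")
        out[str(sid)] = pooled[mask]
    return out


def robust_summaries(errors: np.ndarray, epsilon: float = LOG_EPSILON) -> RobustSummary:
    """Median, 10%-per-tail trimmed mean, and inclusive-linear p90 of log errors."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("empty error vector")
    if np.any(errors < 0):
        raise ValueError("errors must be >= 0")
    logs = np.log(np.maximum(errors, epsilon))
    n = logs.size
    k = int(np.floor(0.10 * n))
    trimmed = np.sort(logs)[k : n - k] if n - 2 * k > 0 else np.sort(logs)
    return RobustSummary(
        median_log_mse=float(np.median(logs)),
        trimmed_mean_log_mse=float(trimmed.mean()),
        p90_log_mse=float(np.percentile(logs, 90, method="linear")),
    )


def _check_two_samples(a: np.ndarray, b: np.ndarray, min_a: int, min_b: int) -> tuple:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < min_a or b.size < min_b:
        raise ValueError(f"need |a| >= {min_a} and |b| >= {min_b}; got {a.size}, {b.size}")
    return a, b


def welch_t_test(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Unequal-variance t test (Welch-Satterthwaite df, two-sided)."""
    a, b = _check_two_samples(a, b, 2, 2)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise UndefinedStatisticError("both samples are constant; t undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="welch_t",
        n_a=a.size,
        n_b=b.size,
    )


def mann_whitney_test(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Mann-Whitney U (U = #{a_i > b_j} + half-ties).

    Two-sided p is exact (full enumeration) when |a|+|b| <= 12 with no
    ties, otherwise the tie-corrected normal approximation.
    """
    a, b = _check_two_samples(a, b, 1, 1)
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if np.isnan(p):  # zero-variance normal approximation (all values tied)
        p = 1.0
    return TestResult(
        statistic=float(res.statistic),
        p_value=p,
        method=f"mann_whitney_{method}",
        n_a=a.size,
        n_b=b.size,
    )


_STATISTICS: dict[str, Callable] = {
    "mean_diff": lambda a, b: float(np.mean(a) - np.mean(b)),
    "median_diff": lambda a, b: float(np.median(a) - np.median(b)),
}


def permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    statistic: str = "mean_diff",
    n_iter: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Seeded two-sided label-permutation test with the add-one estimator:

        p = (1 + #{|stat_perm| >= |stat_obs|}) / (n_iter + 1)

    which never returns exactly zero.
    """
    a, b = _check_two_samples(a, b, 1, 1)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    try:
        stat = _STATISTICS[statistic]
    except KeyError:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {sorted(_STATISTICS)}") from None
    observed = abs(stat(a, b))
    pooled = np.concatenate([a, b])
    na = a.size
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_iter):
        perm = rng.permutation(pooled)
        if abs(stat(perm[:na], perm[na:])) >= observed:
            count += 1
    return TestResult(
        statistic=float(stat(a, b)),
        p_value=(1 + count) / (n_iter + 1),
        method=f"permutation_{statistic}",
        n_a=na,
        n_b=b.size,
    )


def effect_sizes(a: np.ndarray, b: np.ndarray) -> EffectSizes:
    """Cohen's d (pooled SD, n-1 weights) and Cliff's delta.

    delta = (#{a_i > b_j} - #{a_i < b_j}) / (|a| * |b|).  With zero pooled
    SD, d is undefined and an :class:`UndefinedStatisticError` is raised
    carrying the (still well-defined) delta.
    """
    a, b = _check_two_samples(a, b, 2, 2)
    greater = np.sum(a[:, None] > b[None, :])
    less = np.sum(a[:, None] < b[None, :])
    delta = float((greater - less) / (a.size * b.size))
    sp2 = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) / (
        a.size + b.size - 2
    )
    if sp2 == 0:
        raise UndefinedStatisticError("zero pooled SD; Cohen's d undefined", cliffs_delta=delta)
    d = float((np.mean(a) - np.mean(b)) / np.sqrt(sp2))
    return EffectSizes(cohens_d=d, cliffs_delta=delta)


SUMMARY_NAMES = ("median_log_mse", "trimmed_mean_log_mse", "p90_log_mse")


def compare_groups(
    window_errors: np.ndarray,
    provenance: pd.DataFrame,
    manifest: CohortManifest,
    roi_channels: Sequence[int] = (1, 15),
    channel_ids: Sequence[int] | None = None,
    task: str = "improv",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> GroupComparison:
    """Full ROI battery: per-subject robust summaries, three tests, effect sizes.

    Group A is "pianist", group B "non_pianist"; positive statistics mean
    larger values in group A.
    """
    if channel_ids is None:
        channel_ids = list(range(1, np.asarray(window_errors).shape[1] + 1))
    vectors = roi_pool(window_errors, provenance, roi_channels, channel_ids, task=task)
    rows = []
    for sid, vec in vectors.items():
        summ = robust_summaries(vec)
        rows.append({"subject_id": sid, "group": manifest.group_of(sid), **summ.as_dict()})
    summaries = pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)
    for group in ("pianist", "non_pianist"):
        if not (summaries["group"] == group).any():
            raise ValueError(f"group {group!r} has no subjects with {task!r} windows")

    tests: dict = {}
    effects: dict = {}
    for name in SUMMARY_NAMES:
        a = summaries.loc[summaries["group"] == "pianist", name].to_numpy()
        b = summaries.loc[summaries["group"] == "non_pianist", name].to_numpy()
        tests[(name, "welch_t")] = welch_t_test(a, b)
        tests[(name, "mann_whitney")] = mann_whitney_test(a, b)
        tests[(name, "permutation")] = permutation_test(a, b, n_iter=n_permutations, seed=seed)
        effects[name] = effect_sizes(a, b)
    return GroupComparison(
        summaries=summaries, tests=tests, effects=effects, roi_channels=tuple(int(c) for c in roi_channels)
    )


def rank_channels(errmap: ChannelErrorMap, task: str = "improv") -> pd.DataFrame:
    """Channels sorted by descending grand-mean error; ties by ascending id."""
    means = errmap.grand_means(task)
    frame = means.reset_index().rename(columns={"mean_error": "grand_mean_error"})
    frame = frame.sort_values(
        ["grand_mean_error", "channel"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return frame
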