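"""TF-to-target concordance metrics on smoothed bin profiles.

Four base metrics capture different relationship shapes: squared Pearson
(linear), squared Spearman (monotone), dynamic time warping distance
(shape-matched with flexible delays), and mutual information (arbitrary
dependency).  Each has a "rolling" variant that rescans the metric at
successive target-vs-TF bin lags and reports the best score with its delay,
for regulons whose targets respond after a shared lag.

Correlations are squared so that positive and negative regulation land on a
common strength scale comparable to a random background; the raw sign is kept
separately for the direction-consistency filter downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import Regulon

BASE_METRICS = ("pearson", "spearman", "dtw", "mi")
ROLLING_METRICS = ("rolling_pearson", "rolling_spearman", "rolling_dtw", "rolling_mi")
ALL_METRICS = BASE_METRICS + ROLLING_METRICS

# Metrics where larger means a stronger association (DTW is the reverse).
LARGER_IS_STRONGER = {
    "pearson": True,
    "spearman": True,
    "dtw": False,
    "mi": True,
    "rolling_pearson": True,
    "rolling_spearman": True,
    "rolling_dtw": False,
    "rolling_mi": True,
}

CORRELATION_METRICS = {"pearson", "spearman", "rolling_pearson", "rolling_spearman"}


class ZeroVarianceError(ValueError):
    """Correlation is undefined on a constant series."""


@dataclass(frozen=True)
class TargetScore:
    tf: str
    target: str
    metric: str
    score: float
    sign: int  # sign of the un-squared correlation; 0 for dtw/mi
    lag: int = 0  # nonzero only for rolling metrics


def pearson_sq(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Squared Pearson correlation with the sign of r kept separately."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r, int(np.sign(r))


def spearman_sq(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Squared Spearman correlation (average ranks for ties), sign kept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("zero-variance input")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    return pearson_sq(rx, ry)


def _fractional(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    total = v.sum()
    if total <= 0:
        return np.full(len(v), 1.0 / len(v))
    return v / total


def dtw_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Path-length-normalized dynamic time warping distance.

    Both series are rescaled to fractional form (value / series sum; an
    all-zero series becomes a uniform profile) so profiles of different
    expression scales are comparable.  The dynamic program minimizes the
    cumulative |difference| cost under the symmetric step pattern
    (diagonal/left/down), preferring the shortest path among cost ties, and
    returns cost / path length.
    """
    x = _fractional(x)
    y = _fractional(y)
    n, m = len(x), len(y)
    if n < 2 or m < 2:
        raise ValueError("need series of length >= 2")
    cost = np.abs(x[:, None] - y[None, :])
    acc = np.full((n, m), np.inf)
    plen = np.zeros((n, m), dtype=int)
    acc[0, 0] = cost[0, 0]
    plen[0, 0] = 1
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        plen[i, 0] = i + 1
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
        plen[0, j] = j + 1
    for i in range(1, n):
        for j in range(1, m):
            candidates = (
                (acc[i - 1, j - 1], plen[i - 1, j - 1]),
                (acc[i - 1, j], plen[i - 1, j]),
                (acc[i, j - 1], plen[i, j - 1]),
            )
            best_cost, best_len = min(candidates, key=lambda t: (t[0], t[1]))
            acc[i, j] = best_cost + cost[i, j]
            plen[i, j] = best_len + 1
    return float(acc[-1, -1] / plen[-1, -1])


def mutual_information(x: np.ndarray, y: np.ndarray, n_mi_bins: int = 8) -> float:
    """Plug-in mutual information (nats) on equal-frequency discretizations.

    Each series is split into ``n_mi_bins`` equal-count bins via ordinal
    ranks; a (near-)constant series yields MI = 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 2:
        raise ValueError("need equal-length vectors of length >= 2")
    if np.ptp(x) < 1e-12 or np.ptp(y) < 1e-12:
        return 0.0
    b = min(n_mi_bins, n)
    bx = (stats.rankdata(x, method="ordinal") - 1) * b // n
    by = (stats.rankdata(y, method="ordinal") - 1) * b // n
    joint = np.zeros((b, b))
    np.add.at(joint, (bx.astype(int), by.astype(int)), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])))
    return max(mi, 0.0)


def _eval_base(metric: str, x: np.ndarray, y: np.ndarray, n_mi_bins: int) -> tuple[float, int]:
    if metric == "pearson":
        return pearson_sq(x, y)
    if metric == "spearman":
        return spearman_sq(x, y)
    if metric == "dtw":
        return dtw_distance(x, y), 0
    if metric == "mi":
        return mutual_information(x, y, n_mi_bins=n_mi_bins), 0
    raise ValueError(f"unknown base metric: {metric}")


def rolling_best(
    base_metric: str,
    x: np.ndarray,
    y: np.ndarray,
    max_lag: int,
    n_mi_bins: int = 8,
) -> tuple[float, int, int]:
    """Best base-metric score over target lags 0..max_lag.

    At lag k the metric is scored on (x[:n-k], y[k:]); lags with overlap
    shorter than 3 are skipped.  Returns (score, sign, lag); ties break toward
    the smaller lag.  Correlations/MI maximize, DTW minimizes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if max_lag >= n - 3:
        max_lag = max(0, n - 4)
    best: tuple[float, int, int] | None = None
    maximize = LARGER_IS_STRONGER[base_metric]
    for k in range(max_lag + 1):
        xs = x[: n - k] if k else x
        ys = y[k:]
        if len(xs) < 3:
            continue
        try:
            score, sign = _eval_base(base_metric, xs, ys, n_mi_bins)
        except ZeroVarianceError:
            continue
        if best is None or (score > best[0] if maximize else score < best[0]):
            best = (score, sign, k)
    if best is None:
        raise ZeroVarianceError("no lag produced a defined score")
    return best


def default_max_lag(n_bins: int) -> int:
    return int(np.ceil(0.25 * n_bins))


def score_pair(
    metric: str,
    x: np.ndarray,
    y: np.ndarray,
    max_lag: int | None = None,
    n_mi_bins: int = 8,
) -> tuple[float, int, int]:
    """Score one TF profile against one target profile; returns (score, sign, lag)."""
    if metric in BASE_METRICS:
        score, sign = _eval_base(metric, x, y, n_mi_bins)
        return score, sign, 0
    if metric in ROLLING_METRICS:
        base = metric.removeprefix("rolling_")
        if max_lag is None:
            max_lag = default_max_lag(len(x))
        return rolling_best(base, x, y, max_lag, n_mi_bins=n_mi_bins)
    raise ValueError(f"unknown metric: {metric}")


def score_regulon(
    tf: str,
    regulon: Regulon,
    smoothed,
    metric: str,
    max_lag: int | None = None,
    n_mi_bins: int = 8,
    min_targets: int = 3,
) -> list[TargetScore]:
    """Score a TF against each of its targets present in the smoothed matrix.

    ``smoothed`` is a pandas DataFrame (genes x bins).  Targets absent from
    the matrix are dropped; the TF is never scored against itself.  Targets
    whose score is undefined (zero variance under a correlation metric) are
    skipped.  Raises KeyError when the TF itself is absent and ValueError when
    fewer than ``min_targets`` scorable targets remain.
    """
    if tf not in smoothed.index:
        raise KeyError(f"TF {tf} absent from the smoothed matrix")
    x = smoothed.loc[tf].to_numpy(dtype=float)
    scores: list[TargetScore] = []
    for gene, _mode in regulon.targets:
        if gene == tf or gene not in smoothed.index:
            continue
        y = smoothed.loc[gene].to_numpy(dtype=float)
        try:
            s, sign, lag = score_pair(metric, x, y, max_lag=max_lag, n_mi_bins=n_mi_bins)
        except ZeroVarianceError:
            continue
        scores.append(TargetScore(tf=tf, target=gene, metric=metric, score=s, sign=sign, lag=lag))
    if len(scores) < min_targets:
        raise ValueError(
            f"regulon {tf}: only {len(scores)} scorable targets (< {min_targets})"
        )
    return scores
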