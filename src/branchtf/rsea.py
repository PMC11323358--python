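"""Relational Set Enrichment Analysis (RSEA).

For each (TF, metric) on a branch, the distribution of TF-to-target scores is
compared to the scores the same TF achieves against a random background gene
set with a two-sample Kolmogorov-Smirnov test.  Before the test, targets are
(1) filtered for direction consistency against the annotated
activation/repression mode when the metric carries a sign, and (2) "focused"
to the top-concordance subset (default top 75%).  The background scores go
through the same focusing so the comparison is like-for-like.  p-values are
Benjamini-Hochberg adjusted across TFs within one branch x metric family, and
an ensemble result takes each TF's most significant metric.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .association_metrics import (
    ALL_METRICS,
    CORRELATION_METRICS,
    LARGER_IS_STRONGER,
    TargetScore,
    ZeroVarianceError,
    score_pair,
    score_regulon,
)
from .io_formats import Mode, Regulon
from .spline_model import stable_seed

EXACT_ENUM_LIMIT = 20_000  # max C(n+m, n) for permutation enumeration


@dataclass
class RSEAResult:
    tf: str
    branch_id: str
    metric: str
    n_initial: int
    n_direction_removed: int
    n_focused: int
    ks_stat: float
    p_value: float
    fdr: float
    direction: str  # above | below
    focused_targets: list[str] = field(default_factory=list)
    best_lag: int | None = None


@dataclass
class EnsembleResult:
    tf: str
    branch_id: str
    best_metric: str
    best_fdr: float
    per_metric: dict[str, float] = field(default_factory=dict)


def direction_filter(
    scores: list[TargetScore], regulon: Regulon
) -> tuple[list[TargetScore], int]:
    """Drop targets whose correlation sign contradicts the annotated mode.

    Only applies to correlation-family metrics; for unsigned metrics (DTW,
    MI) the list passes through unchanged.  Unknown-mode targets are always
    kept (the consistency check is skipped when no annotation exists).
    """
    if not scores or scores[0].metric not in CORRELATION_METRICS:
        return list(scores), 0
    modes = regulon.modes
    kept = []
    for s in scores:
        mode = modes.get(s.target, Mode.UNKNOWN)
        consistent = (
            mode is Mode.UNKNOWN
            or (mode is Mode.ACTIVATION and s.sign >= 0)
            or (mode is Mode.REPRESSION and s.sign <= 0)
        )
        if consistent:
            kept.append(s)
    return kept, len(scores) - len(kept)


def target_focus(
    scores: list[TargetScore], percentile: float = 25.0, min_targets: int = 3
) -> list[TargetScore]:
    """Retain the top-concordance core of a target set.

    For correlations/MI keep scores at or above the ``percentile``-th
    percentile; for DTW (smaller = stronger) keep scores at or below the
    (100 - percentile)-th percentile.  Ties at the threshold are kept; if
    fewer than ``min_targets`` survive, the ``min_targets`` strongest are
    kept instead.
    """
    if not scores:
        return []
    metric = scores[0].metric
    vals = np.array([s.score for s in scores])
    if LARGER_IS_STRONGER[metric]:
        thr = np.percentile(vals, percentile)
        focused = [s for s in scores if s.score >= thr]
        strongest_order = sorted(scores, key=lambda s: -s.score)
    else:
        thr = np.percentile(vals, 100.0 - percentile)
        focused = [s for s in scores if s.score <= thr]
        strongest_order = sorted(scores, key=lambda s: s.score)
    if len(focused) < min_targets:
        focused = strongest_order[: min_targets]
    return focused


def sample_background(
    gene_pool: list[str], size: int, exclude: set[str], seed: int
) -> list[str]:
    """Uniform sample without replacement from the pool minus ``exclude``."""
    eligible = sorted(set(gene_pool) - set(exclude))
    if len(eligible) < size:
        raise ValueError(
            f"background pool too small: {len(eligible)} eligible < {size} requested"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(eligible), size=size, replace=False)
    return [eligible[i] for i in sorted(pick)]


def _ks_stat(a: np.ndarray, b: np.ndarray) -> float:
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def _exact_permutation_p(a: np.ndarray, b: np.ndarray, observed: float) -> float:
    """Exact permutation p-value for the two-sample KS statistic.

    Enumerates all assignments of the pooled values to the two groups
    (tie-safe), evaluating the statistic for every assignment in a vectorized
    pass over the pooled support.
    """
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    picks = np.array(list(combinations(range(n + m), n)))  # combos x n
    vals_a = pooled[picks]
    support = np.unique(pooled)
    n_combo = len(picks)
    # counts of pooled values <= v per combo (group A); group B by complement
    d_max = np.zeros(n_combo)
    pooled_le = {v: float(np.sum(pooled <= v)) for v in support}
    for v in support:
        ca = np.sum(vals_a <= v, axis=1)
        cb = pooled_le[v] - ca
        d_max = np.maximum(d_max, np.abs(ca / n - cb / m))
    return float(np.mean(d_max >= observed - 1e-12))


def ks_compare(
    observed: np.ndarray, background: np.ndarray, metric: str
) -> tuple[float, float, str]:
    """Two-sided two-sample KS test of observed scores vs background scores.

    Small samples get an exact permutation p (tie-safe); moderate samples use
    the exact KS distribution; large samples the asymptotic one.  The
    direction is "above" when the observed median exceeds the background
    median, else "below" (for DTW, "below" is the strengthening direction).
    """
    observed = np.asarray(observed, dtype=float)
    background = np.asarray(background, dtype=float)
    if observed.size == 0 or background.size == 0:
        raise ValueError("empty sample for KS comparison")
    n, m = len(observed), len(background)
    d = _ks_stat(observed, background)
    if math.comb(n + m, n) <= EXACT_ENUM_LIMIT:
        p = _exact_permutation_p(observed, background, d)
    elif n * m <= 10_000:
        p = float(stats.ks_2samp(observed, background, method="exact").pvalue)
    else:
        p = float(stats.ks_2samp(observed, background, method="asymp").pvalue)
    p = min(max(p, np.finfo(float).tiny), 1.0)
    direction = "above" if np.median(observed) > np.median(background) else "below"
    return d, p, direction


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclass
class UntestableTF:
    tf: str
    metric: str
    reason: str


def _modal_lag(focused: list[TargetScore]) -> int | None:
    if not focused or not focused[0].metric.startswith("rolling_"):
        return None
    counts = Counter(s.lag for s in focused)
    top = max(counts.values())
    return min(lag for lag, c in counts.items() if c == top)


def run_rsea_branch(
    smoothed,
    regulons: list[Regulon],
    metrics: tuple[str, ...] = ALL_METRICS,
    alpha: float = 0.05,
    seed: int = 0,
    focus_percentile: float = 25.0,
    min_targets: int = 3,
    max_lag: int | None = None,
    n_mi_bins: int = 8,
    background_mode: str = "shared_max",
    background_repeats: int = 5,
    branch_id: str = "",
) -> tuple[list[RSEAResult], list[EnsembleResult], list[UntestableTF]]:
    """RSEA over all regulons and metrics on one smoothed branch.

    ``smoothed`` is a pandas DataFrame (genes x bins) from an accepted branch.
    Per metric: score regulons, direction-filter, focus, compare against a
    random background of size equal to the largest testable regulon (or the
    TF's own regulon size under ``background_mode='per_tf'``), then BH-adjust
    within the branch x metric family.  The ensemble takes each TF's minimum
    FDR across metrics.

    The p-value averages ``background_repeats`` independent background draws
    (the first draw is shared across TFs; a single draw is fragile because an
    unlucky background shifts every TF's test in the same direction).  The
    reported statistic is the mean KS distance over draws and the direction
    the majority call.
    """
    if background_mode not in ("shared_max", "per_tf"):
        raise ValueError("background_mode must be 'shared_max' or 'per_tf'")
    gene_pool = list(smoothed.index.astype(str))
    tf_names = {r.tf for r in regulons}
    results: list[RSEAResult] = []
    ensembles: dict[str, EnsembleResult] = {}
    untestable: list[UntestableTF] = []
    for metric in metrics:
        per_tf_rows = []
        scored: dict[str, list[TargetScore]] = {}
        for reg in regulons:
            try:
                scored[reg.tf] = score_regulon(
                    reg.tf, reg, smoothed, metric,
                    max_lag=max_lag, n_mi_bins=n_mi_bins, min_targets=min_targets,
                )
            except KeyError:
                untestable.append(UntestableTF(reg.tf, metric, "tf_absent_from_matrix"))
            except ValueError:
                untestable.append(UntestableTF(reg.tf, metric, "too_few_scorable_targets"))
        if not scored:
            continue
        max_size = max(len(v) for v in scored.values())
        bg_seed = stable_seed(seed, f"background:{branch_id}:{metric}")
        shared_bg = None
        if background_mode == "shared_max":
            shared_bg = sample_background(gene_pool, max_size, tf_names, bg_seed)
        for reg in regulons:
            if reg.tf not in scored:
                continue
            scores = scored[reg.tf]
            kept, n_removed = direction_filter(scores, reg)
            if len(kept) < min_targets:
                untestable.append(
                    UntestableTF(reg.tf, metric, "too_few_direction_consistent_targets")
                )
                continue
            focused = target_focus(kept, percentile=focus_percentile, min_targets=min_targets)
            obs = np.array([s.score for s in focused])
            x = smoothed.loc[reg.tf].to_numpy(dtype=float)
            p_draws: list[float] = []
            d_draws: list[float] = []
            dir_draws: list[str] = []
            for rep in range(max(1, background_repeats)):
                if shared_bg is not None and rep == 0:
                    bg_genes = shared_bg
                else:
                    rep_seed = stable_seed(seed, f"background:{branch_id}:{metric}:{reg.tf}:{rep}")
                    bg_genes = sample_background(
                        gene_pool,
                        max_size if background_mode == "shared_max" else len(scores),
                        {reg.tf},
                        rep_seed,
                    )
                bg_scores = []
                for g in bg_genes:
                    if g == reg.tf:
                        continue
                    try:
                        s, sign, lag = score_pair(
                            metric, x, smoothed.loc[g].to_numpy(dtype=float),
                            max_lag=max_lag, n_mi_bins=n_mi_bins,
                        )
                    except ZeroVarianceError:
                        continue
                    bg_scores.append(
                        TargetScore(reg.tf, g, metric, s, sign, lag)
                    )
                if len(bg_scores) < min_targets:
                    continue
                bg_focused = target_focus(
                    bg_scores, percentile=focus_percentile, min_targets=min_targets
                )
                bg = np.array([s.score for s in bg_focused])
                d, p, direction = ks_compare(obs, bg, metric)
                p_draws.append(p)
                d_draws.append(d)
                dir_draws.append(direction)
            if not p_draws:
                untestable.append(UntestableTF(reg.tf, metric, "background_unscorable"))
                continue
            per_tf_rows.append(
                RSEAResult(
                    tf=reg.tf,
                    branch_id=branch_id,
                    metric=metric,
                    n_initial=len(scores),
                    n_direction_removed=n_removed,
                    n_focused=len(focused),
                    ks_stat=float(np.mean(d_draws)),
                    p_value=float(np.mean(p_draws)),
                    fdr=np.nan,
                    direction=sorted(
                        Counter(dir_draws).items(), key=lambda kv: (-kv[1], kv[0])
                    )[0][0],
                    focused_targets=[s.target for s in focused],
                    best_lag=_modal_lag(focused),
                )
            )
        if per_tf_rows:
            fdrs = bh_adjust(np.array([r.p_value for r in per_tf_rows]))
            for r, f in zip(per_tf_rows, fdrs):
                r.fdr = float(f)
                results.append(r)
                ens = ensembles.setdefault(
                    r.tf,
                    EnsembleResult(tf=r.tf, branch_id=branch_id, best_metric=r.metric,
                                   best_fdr=r.fdr),
                )
                ens.per_metric[r.metric] = r.fdr
                if r.fdr < ens.best_fdr:
                    ens.best_fdr = r.fdr
                    ens.best_metric = r.metric
    ensemble_list = [ensembles[tf] for tf in sorted(ensembles)]
    for e in ensemble_list:
        e.best_fdr = min(e.per_metric.values())
        e.best_metric = min(e.per_metric, key=lambda k: (e.per_metric[k], k))
    return results, ensemble_list, untestable
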