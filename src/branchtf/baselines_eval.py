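"""Differential-expression baselines, marker-based evaluation, and the
TF-to-TF network export.

The DE baselines split a branch into equal-count "start" and "end" halves
(cells for raw mode after pseudotime focusing, bins for smooth mode) and run
a Welch t-test per gene; the target-set variant compares the |t| statistics
of a regulon's targets against a random background with a KS test.
Evaluation ranks TFs by FDR and scores the ranking against marker TFs of the
tissue with precision-recall, trapezoidal AUC, and early precision (precision
at recall <= 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import BranchMatrix, MarkerSet, Regulon
from .rsea import EnsembleResult, bh_adjust, ks_compare, sample_background


@dataclass
class DEResult:
    gene: str
    branch_id: str
    mode: str  # raw | smooth
    fold_change: float
    t_stat: float
    p_value: float
    fdr: float


@dataclass
class EvalCurve:
    points: list[tuple[float, float]]  # (recall, precision)
    auc: float
    early_precision: float
    n_positives: int
    n_candidates: int
    roc_points: list[tuple[float, float]] = field(default_factory=list)  # (fpr, tpr)
    roc_auc: float = float("nan")


def _welch_row(start: np.ndarray, end: np.ndarray) -> tuple[float, float]:
    if np.ptp(start) == 0 and np.ptp(end) == 0:
        diff = float(end.mean() - start.mean())
        if diff == 0.0:
            return 0.0, 1.0  # identical constants: no evidence by convention
        # perfect separation with zero within-half variance
        return float(np.copysign(np.inf, diff)), float(np.finfo(float).tiny)
    t, p = stats.ttest_ind(end, start, equal_var=False)
    if not np.isfinite(p):
        return 0.0, 1.0
    return float(t), float(p)


def de_ttest(
    values: np.ndarray,
    gene_ids: list[str],
    branch_id: str,
    mode: str,
) -> list[DEResult]:
    """Welch t-test of end-half vs start-half per gene.

    ``values`` is genes x observations, with observations already in
    pseudotime order (focused cells for ``raw`` mode, smoothed bins for
    ``smooth`` mode).  The split is at the median rank with the odd element
    going to the start half.  Fold change is mean(end)/mean(start) with a
    1e-9 pseudo-count; FDR is BH across genes within the branch.
    """
    if mode not in ("raw", "smooth"):
        raise ValueError("mode must be 'raw' or 'smooth'")
    values = np.asarray(values, dtype=float)
    n_obs = values.shape[1]
    n_start = (n_obs + 1) // 2
    if n_start < 3 or n_obs - n_start < 3:
        raise ValueError(
            f"branch {branch_id} untestable in {mode} mode: a half would have < 3 observations"
        )
    start = values[:, :n_start]
    end = values[:, n_start:]
    t_p = [_welch_row(start[i], end[i]) for i in range(values.shape[0])]
    t_stats = np.array([tp[0] for tp in t_p])
    p_vals = np.array([tp[1] for tp in t_p])
    fdrs = bh_adjust(p_vals)
    fold = (end.mean(axis=1) + 1e-9) / (start.mean(axis=1) + 1e-9)
    return [
        DEResult(
            gene=g, branch_id=branch_id, mode=mode,
            fold_change=float(fold[i]), t_stat=float(t_stats[i]),
            p_value=float(p_vals[i]), fdr=float(fdrs[i]),
        )
        for i, g in enumerate(gene_ids)
    ]


def de_ttest_branch(branch: BranchMatrix) -> list[DEResult]:
    """Raw-mode DE on a (focused) branch."""
    return de_ttest(branch.expression, branch.gene_ids, branch.branch_id, "raw")


def de_targets(
    regulon: Regulon,
    de_results: list[DEResult],
    gene_pool: list[str],
    seed: int,
    min_targets: int = 3,
) -> tuple[float, float]:
    """KS test of a regulon's target |t|-statistics against a random background."""
    by_gene = {r.gene: abs(r.t_stat) for r in de_results}
    target_t = [by_gene[g] for g in regulon.target_genes if g in by_gene and g != regulon.tf]
    if len(target_t) < min_targets:
        raise ValueError(f"regulon {regulon.tf}: fewer than {min_targets} targets with DE results")
    bg_genes = sample_background(gene_pool, len(target_t), {regulon.tf}, seed)
    bg_t = [by_gene[g] for g in bg_genes if g in by_gene]
    d, p, _ = ks_compare(np.array(target_t), np.array(bg_t), "mi")
    return d, p


def precision_recall(
    ranked: list[tuple[str, float]], markers: MarkerSet
) -> EvalCurve:
    """Precision-recall sweep of an FDR-ranked TF list against marker TFs.

    Ties (equal FDR) are grouped; positives are markers restricted to the
    candidate TFs.  AUC is the trapezoid over achieved recalls anchored at
    recall 0 with the first group's precision; early precision is the
    precision at the largest achieved recall <= 0.1 (or the first group's
    precision when none is achieved).
    """
    if not ranked:
        raise ValueError("empty ranking")
    if not markers.tf_ids:
        raise ValueError("empty marker set")
    candidates = [tf for tf, _ in ranked]
    # entries are (TF, branch)-style rows: a marker TF may appear once per
    # branch, and each appearance counts as its own positive
    n_pos = sum(tf in markers.tf_ids for tf in candidates)
    if n_pos == 0:
        raise ValueError("no marker TF among the ranked candidates")
    n_neg = len(candidates) - n_pos
    positives = markers.tf_ids
    order = sorted(ranked, key=lambda t: t[1])
    points: list[tuple[float, float]] = []
    roc_points: list[tuple[float, float]] = []
    tp = 0
    seen = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and order[j][1] == order[i][1]:
            j += 1
        for tf, _ in order[i:j]:
            if tf in positives:
                tp += 1
        seen = j
        precision = tp / seen
        recall = tp / n_pos
        points.append((recall, precision))
        fp = seen - tp
        roc_points.append((fp / n_neg if n_neg else 0.0, recall))
        i = j
    recalls = np.array([p[0] for p in points])
    precisions = np.array([p[1] for p in points])
    auc = float(np.trapezoid(np.concatenate([[precisions[0]], precisions]),
                             np.concatenate([[0.0], recalls])))
    early_mask = recalls <= 0.1
    if early_mask.any():
        idx = int(np.flatnonzero(early_mask)[-1])
        early = float(precisions[idx])
    else:
        early = float(precisions[0])
    fprs = np.array([p[0] for p in roc_points])
    tprs = np.array([p[1] for p in roc_points])
    roc_auc = float(np.trapezoid(np.concatenate([[0.0], tprs, [1.0]]),
                                 np.concatenate([[0.0], fprs, [1.0]])))
    return EvalCurve(
        points=points, auc=auc, early_precision=early,
        n_positives=n_pos, n_candidates=len(candidates),
        roc_points=roc_points, roc_auc=roc_auc,
    )


def build_tf_network(
    significant: list[EnsembleResult],
    regulons: list[Regulon],
    alpha: float = 0.05,
) -> list[tuple[str, str, str]]:
    """Directed TF-to-TF edges among significant TFs backed by the regulon table.

    Edge u -> v exists iff both u and v are significant (best FDR < alpha) and
    v is an annotated target of u; self-loops are excluded.
    """
    sig = {e.tf for e in significant if e.best_fdr < alpha}
    edges = []
    for reg in regulons:
        if reg.tf not in sig:
            continue
        for gene, mode in reg.targets:
            if gene != reg.tf and gene in sig:
                edges.append((reg.tf, gene, mode.value))
    return edges


def curve_to_frame(curve: EvalCurve) -> pd.DataFrame:
    df = pd.DataFrame(curve.points, columns=["recall", "precision"])
    df["auc"] = curve.auc
    df["early_precision"] = curve.early_precision
    return df
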