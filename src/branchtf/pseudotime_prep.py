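"""Pseudotime focusing and quantization of a branch into pseudobulk bins.

Focusing drops cells whose pseudotime falls outside the Tukey fence
(1.5 x IQR beyond the quartiles by default) so that stray cells at the far
ends of a branch cannot dominate downstream correlations.  Quantization then
divides the retained pseudotime range into equal increments and averages
expression within each bin, requiring a minimum number of cells per bin
(under-populated bins merge into their better-populated neighbor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import BranchMatrix


class UnbinnableBranch(ValueError):
    """Raised when a branch has too few cells to form two valid bins."""


@dataclass
class BinnedBranch:
    """Pseudobulk form of a branch: per-bin mean expression and cell counts."""

    branch_id: str
    bin_edges: np.ndarray  # length n_bins + 1
    bin_means: np.ndarray  # genes x n_bins
    bin_counts: np.ndarray  # length n_bins

    @property
    def n_bins(self) -> int:
        return len(self.bin_counts)


def focus_pseudotime(pseudotime: np.ndarray, iqr_factor: float = 1.5) -> np.ndarray:
    """Boolean retain-mask keeping cells inside the Tukey pseudotime fence.

    Cell i is retained iff Q1 - iqr_factor*IQR <= pt(i) <= Q3 + iqr_factor*IQR,
    with quartiles under the linear-interpolation convention.  Because the
    fence is an interval, the retained set is contiguous in pseudotime rank.
    """
    pt = np.asarray(pseudotime, dtype=float)
    if pt.size < 1:
        raise ValueError("empty pseudotime vector")
    if not np.all(np.isfinite(pt)):
        raise ValueError("non-finite pseudotime")
    q1, q3 = np.percentile(pt, [25.0, 75.0])
    iqr = q3 - q1
    lo = q1 - iqr_factor * iqr
    hi = q3 + iqr_factor * iqr
    mask = (pt >= lo) & (pt <= hi)
    if not mask.any():
        raise ValueError("pseudotime focusing removed every cell")
    return mask


def focus_branch(branch: BranchMatrix, iqr_factor: float = 1.5) -> tuple[BranchMatrix, int]:
    """Apply pseudotime focusing to a branch; returns (focused, n_removed)."""
    mask = focus_pseudotime(branch.pseudotime, iqr_factor=iqr_factor)
    return branch.subset_cells(mask), int((~mask).sum())


def _assign_bins(pt: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # Half-open [e_k, e_{k+1}) intervals; the final bin is closed on the right.
    idx = np.searchsorted(edges, pt, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)

def _merge_under_populated(
    counts: list[int], members: list[list[int]], min_cells: int
) -> tuple[list[int], list[list[int]]]:
    """Merge bins below the cell floor into the closer-populated neighbor.

    The leftmost under-populated bin merges into whichever adjacent neighbor
    holds fewer cells (left on tie) until every bin meets the floor or one bin
    remains.  Preferring the smaller neighbor keeps the merged bins balanced,
    staying as close to the equal-increment structure as possible.
    """
    counts = list(counts)
    members = [list(m) for m in members]
    while len(counts) > 1:
        under = [i for i, c in enumerate(counts) if c < min_cells]
        if not under:
            break
        i = under[0]
        if i == 0:
            j = 1
        elif i == len(counts) - 1:
            j = i - 1
        else:
            j = i - 1 if counts[i - 1] <= counts[i + 1] else i + 1
        lo, hi = min(i, j), max(i, j)
        counts[lo] = counts[lo] + counts[hi]
        members[lo] = members[lo] + members[hi]
        del counts[hi]
        del members[hi]
    return counts, members


def bin_branch(
    branch: BranchMatrix, n_bins: int, min_cells_per_bin: int = 10
) -> BinnedBranch:
    """Quantize a (focused) branch into equal pseudotime-increment bins.

    Edges divide [min(pt), max(pt)] into ``n_bins`` equal increments; bins
    with fewer than ``min_cells_per_bin`` cells merge into their
    better-populated neighbor, reducing the bin count.  Bin means are the
    arithmetic mean of member cells' expression per gene.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    pt = branch.pseudotime
    if branch.n_cells < 2 * min_cells_per_bin:
        raise UnbinnableBranch(
            f"branch {branch.branch_id}: {branch.n_cells} cells < "
            f"2 x min_cells_per_bin ({2 * min_cells_per_bin})"
        )
    lo, hi = float(pt.min()), float(pt.max())
    if hi <= lo:
        raise UnbinnableBranch(f"branch {branch.branch_id}: degenerate pseudotime range")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = _assign_bins(pt, edges)
    members0 = [list(np.flatnonzero(idx == k)) for k in range(n_bins)]
    counts0 = [len(m) for m in members0]
    counts, members = _merge_under_populated(counts0, members0, min_cells_per_bin)
    if len(counts) < 2 or any(c < min_cells_per_bin for c in counts):
        raise UnbinnableBranch(
            f"branch {branch.branch_id}: cannot form >= 2 bins of "
            f">= {min_cells_per_bin} cells"
        )
    if len(counts) == n_bins:
        new_edges = list(edges)  # no merging: keep equal increments
    else:
        # Rebuild edges for the merged bins from member pseudotime boundaries.
        new_edges = [lo]
        for m in members[:-1]:
            last_cell = max(m)
            next_first = last_cell + 1  # cells are sorted by pseudotime
            new_edges.append(0.5 * (pt[last_cell] + pt[next_first]))
        new_edges.append(hi)
    bin_means = np.stack(
        [branch.expression[:, m].mean(axis=1) for m in members], axis=1
    )
    return BinnedBranch(
        branch_id=branch.branch_id,
        bin_edges=np.asarray(new_edges, dtype=float),
        bin_means=bin_means,
        bin_counts=np.asarray(counts, dtype=int),
    )


def raw_bypass_bins(branch: BranchMatrix) -> BinnedBranch:
    """Treat each cell as a weight-1 pseudo-bin (skip quantization).

    Offered for high-resolution datasets where binning is unnecessary; the
    spline stage consumes the result exactly like a quantized branch.
    """
    pt = branch.pseudotime
    edges = np.concatenate([[pt[0]], 0.5 * (pt[1:] + pt[:-1]), [pt[-1]]])
    return BinnedBranch(
        branch_id=branch.branch_id,
        bin_edges=edges,
        bin_means=branch.expression.copy(),
        bin_counts=np.ones(branch.n_cells, dtype=int),
    )
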