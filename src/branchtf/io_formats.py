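"""Readers and writers for the tool's external formats.

Expression comes in either as a dense genes-by-cells TSV (header row of cell
ids, first column of gene symbols) or as a MatrixMarket-style triplet file
with separate row/column name files.  Cell metadata is a TSV with columns
``cell_id``, ``branch_id``, ``pseudotime``.  Regulator-to-target tables use
the TRRUST four-column dialect (TF, target, mode, reference ids; the fourth
column is ignored).  Gene identity is the bare symbol string, case-sensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "tf",
    "metric",
    "n_targets",
    "n_focused",
    "statistic",
    "p_value",
    "fdr",
    "direction",
    "focused_targets",
    "best_lag",
]


class Mode(str, Enum):
    """Annotated direction of regulation for a TF-target edge."""

    ACTIVATION = "activation"
    REPRESSION = "repression"
    UNKNOWN = "unknown"


def _parse_mode(raw: str) -> Mode:
    low = str(raw).strip().lower()
    if low == "activation":
        return Mode.ACTIVATION
    if low == "repression":
        return Mode.REPRESSION
    return Mode.UNKNOWN


@dataclass(frozen=True)
class CellRecord:
    cell_id: str
    branch_id: str
    pseudotime: float


@dataclass
class Regulon:
    """A transcription factor with its annotated targets.

    Targets are unique within a regulon; duplicates collapse to the first
    annotation seen.
    """

    tf: str
    targets: list[tuple[str, Mode]] = field(default_factory=list)

    @property
    def target_genes(self) -> list[str]:
        return [g for g, _ in self.targets]

    @property
    def modes(self) -> dict[str, Mode]:
        return {g: m for g, m in self.targets}

    def __len__(self) -> int:
        return len(self.targets)


@dataclass
class MarkerSet:
    tissue: str
    tf_ids: set[str]

    def __post_init__(self) -> None:
        self.tf_ids = set(self.tf_ids)


@dataclass
class BranchMatrix:
    """One trajectory branch: genes x cells expression plus pseudotime.

    Cells are kept sorted by ascending pseudotime; expression values are
    non-negative, finite, normalized counts.
    """

    branch_id: str
    gene_ids: list[str]
    cell_ids: list[str]
    expression: np.ndarray  # genes x cells
    pseudotime: np.ndarray  # aligned to cell_ids

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        n_g, n_c = self.expression.shape
        if n_g != len(self.gene_ids) or n_c != len(self.cell_ids):
            raise ValueError(
                f"expression shape {self.expression.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids in BranchMatrix")
        if self.pseudotime.shape != (n_c,):
            raise ValueError("pseudotime length does not match cell count")
        if not np.all(np.isfinite(self.pseudotime)):
            raise ValueError("pseudotime contains non-finite values")
        if not np.all(np.isfinite(self.expression)):
            raise ValueError("expression contains non-finite values")
        if np.any(self.expression < 0):
            raise ValueError("expression contains negative values")
        if np.any(np.diff(self.pseudotime) < 0):
            order = np.argsort(self.pseudotime, kind="stable")
            self.pseudotime = self.pseudotime[order]
            self.expression = self.expression[:, order]
            self.cell_ids = [self.cell_ids[i] for i in order]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_cells(self, mask: np.ndarray) -> "BranchMatrix":
        mask = np.asarray(mask, dtype=bool)
        return BranchMatrix(
            branch_id=self.branch_id,
            gene_ids=list(self.gene_ids),
            cell_ids=[c for c, keep in zip(self.cell_ids, mask) if keep],
            expression=self.expression[:, mask],
            pseudotime=self.pseudotime[mask],
        )


def read_expression(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> pd.DataFrame:
    """Read a genes-by-cells expression matrix.

    Dense TSV (header = cell ids, first column = gene ids) when no name
    files are given; otherwise a MatrixMarket triplet file whose row and
    column names live in ``genes_path`` / ``cells_path`` (one name per line).
    Duplicate gene rows collapse to the first occurrence with a warning;
    negative values are fatal.
    """
    matrix_path = Path(matrix_path)
    if not matrix_path.exists():
        raise FileNotFoundError(matrix_path)
    if genes_path is None and cells_path is None:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    else:
        if genes_path is None or cells_path is None:
            raise ValueError("triplet input needs both genes_path and cells_path")
        genes = [ln.strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
        cells = [ln.strip() for ln in Path(cells_path).read_text().splitlines() if ln.strip()]
        mat = mmread(str(matrix_path))
        mat = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"triplet matrix shape {mat.shape} does not match "
                f"{len(genes)} gene names x {len(cells)} cell names"
            )
        df = pd.DataFrame(mat, index=genes, columns=cells)
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene rows (keeping first)", n_dup)
        df = df[~df.index.duplicated(keep="first")]
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains non-finite values")
    if np.any(values < 0):
        raise ValueError("expression matrix contains negative values")
    return df


def read_cell_metadata(path: str | Path) -> list[CellRecord]:
    """Read the cell metadata TSV (cell_id, branch_id, pseudotime)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "branch_id": str})
    required = {"cell_id", "branch_id", "pseudotime"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cell metadata missing columns: {sorted(missing)}")
    records = [
        CellRecord(str(r.cell_id), str(r.branch_id), float(r.pseudotime))
        for r in df.itertuples(index=False)
    ]
    if not all(np.isfinite(r.pseudotime) for r in records):
        raise ValueError("non-finite pseudotime in metadata")
    pairs = [(r.cell_id, r.branch_id) for r in records]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate (cell_id, branch_id) pairs in metadata")
    return records


def split_branches(
    matrix: pd.DataFrame, cell_records: Sequence[CellRecord]
) -> list[BranchMatrix]:
    """Split a genes-by-cells matrix into per-branch matrices.

    Every referenced cell must exist in the matrix; matrix cells absent from
    the metadata are dropped (count logged).  Branches with fewer than two
    cells are excluded with a warning.  Cells come out sorted by pseudotime.
    """
    columns = set(matrix.columns)
    missing = [r.cell_id for r in cell_records if r.cell_id not in columns]
    if missing:
        raise KeyError(f"metadata references cells absent from the matrix: {missing[:5]}")
    by_branch: dict[str, list[CellRecord]] = {}
    for rec in cell_records:
        by_branch.setdefault(rec.branch_id, []).append(rec)
    n_dropped = len(columns) - len({r.cell_id for r in cell_records})
    if n_dropped:
        logger.info("%d matrix cells absent from metadata were dropped", n_dropped)
    branches = []
    for branch_id in sorted(by_branch):
        recs = sorted(by_branch[branch_id], key=lambda r: r.pseudotime)
        if len(recs) < 2:
            logger.warning("branch %s has < 2 cells; excluded", branch_id)
            continue
        cell_ids = [r.cell_id for r in recs]
        branches.append(
            BranchMatrix(
                branch_id=branch_id,
                gene_ids=list(matrix.index.astype(str)),
                cell_ids=cell_ids,
                expression=matrix[cell_ids].to_numpy(dtype=float),
                pseudotime=np.array([r.pseudotime for r in recs], dtype=float),
            )
        )
    return branches


def read_ortholog_map(path: str | Path) -> dict[str, str]:
    """Two-column source->destination symbol map; duplicate sources keep the
    first mapping with a warning."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("ortholog map needs two columns")
    mapping: dict[str, str] = {}
    dups = 0
    for src, dst in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if src in mapping:
            dups += 1
            continue
        mapping[str(src)] = str(dst)
    if dups:
        logger.warning("ortholog map: %d duplicate source symbols ignored (kept first)", dups)
    return mapping


def read_regulons(
    trrust_path: str | Path,
    species: str = "human",
    ortholog_map: str | Path | dict[str, str] | None = None,
    min_targets: int = 3,
) -> list[Regulon]:
    """Read a TRRUST-dialect TF/target/mode table into regulons.

    Mode strings map case-insensitively (Activation -> activation,
    Repression -> repression, anything else -> unknown).  Regulons with fewer
    than ``min_targets`` targets are dropped.  When an ortholog map is given,
    both TF and target symbols are translated and untranslatable rows dropped.
    """
    if species not in ("human", "mouse"):
        raise ValueError("species must be 'human' or 'mouse'")
    df = pd.read_csv(trrust_path, sep="\t", header=None, dtype=str, comment="#")
    if df.empty:
        raise ValueError(f"empty regulon table: {trrust_path}")
    if df.shape[1] < 3:
        raise ValueError("regulon table needs at least 3 columns (TF, target, mode)")
    mapping: dict[str, str] | None = None
    if ortholog_map is not None:
        mapping = ortholog_map if isinstance(ortholog_map, dict) else read_ortholog_map(ortholog_map)
    regulons: dict[str, Regulon] = {}
    n_untranslated = 0
    for tf, target, mode_raw in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]):
        tf, target = str(tf), str(target)
        if mapping is not None:
            if tf not in mapping or target not in mapping:
                n_untranslated += 1
                continue
            tf, target = mapping[tf], mapping[target]
        reg = regulons.setdefault(tf, Regulon(tf=tf))
        if target not in reg.modes:
            reg.targets.append((target, _parse_mode(mode_raw)))
    if n_untranslated:
        logger.info("%d rows dropped as untranslatable through the ortholog map", n_untranslated)
    kept = []
    for tf in regulons:
        if len(regulons[tf]) >= min_targets:
            kept.append(regulons[tf])
        else:
            logger.info("regulon %s dropped: %d < %d targets", tf, len(regulons[tf]), min_targets)
    return kept


def read_markers(path: str | Path, tissue: str = "") -> MarkerSet:
    """Marker TFs: one symbol per line, or two-column (tissue, TF) TSV."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty marker file: {path}")
    tfs: set[str] = set()
    for ln in lines:
        parts = ln.split("\t")
        if len(parts) >= 2:
            if tissue and parts[0] != tissue:
                continue
            tfs.add(parts[1])
        else:
            tfs.add(parts[0])
    if not tfs:
        raise ValueError("no marker TFs after tissue filtering")
    return MarkerSet(tissue=tissue, tf_ids=tfs)


def write_results(results: Sequence, path: str | Path) -> None:
    """Write RSEA result rows to a TSV (reals at 12 significant digits)."""
    rows = []
    for r in results:
        rows.append(
            {
                "tf": r.tf,
                "metric": r.metric,
                "n_targets": r.n_initial,
                "n_focused": r.n_focused,
                "statistic": r.ks_stat,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "direction": r.direction,
                "focused_targets": ",".join(r.focused_targets),
                "best_lag": "" if r.best_lag is None else str(r.best_lag),
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "metric": str, "direction": str})
    return df
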