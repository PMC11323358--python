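"""Synthetic trajectory branches with known TF-to-target ground truth.

The generator emulates what a trajectory-inference method hands this tool:
a normalized gene-by-cell count matrix for one branch, per-cell pseudotime
(uniform on [0, 1], optionally with planted outlier cells beyond the 1.5xIQR
fence), and a TRRUST-dialect regulon table.  Each planted TF follows a smooth
latent curve (sigmoid, Gaussian bump, or ramp); its targets track the TF
latent with a configurable effect strength, under linear, lagged, nonlinear,
repressed, or null relations.  Observed values are zero-inflated negative
binomial draws around the latent means: NB counts with a given dispersion,
then an independent Bernoulli dropout mask to zero.

Everything is deterministic under the spec seed, down to byte-identical
output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import BranchMatrix, Mode, Regulon
from .pseudotime_prep import focus_pseudotime

RELATIONS = ("linear", "lagged", "nonlinear", "repressed", "null")


@dataclass
class SyntheticSpec:
    n_cells: int = 1000
    n_genes: int = 200
    n_tfs: int = 5
    targets_per_tf: int = 10
    relation: str | list[str] = "linear"  # per-TF or one for all
    lag_bins: int = 3  # lag for 'lagged' relations, in reference-bin units
    reference_bins: int = 20  # pseudotime scale on which lag_bins is defined
    effect: float = 0.9
    mean_scale: float = 20.0
    dispersion: float = 0.3
    dropout_prob: float = 0.1
    outlier_cells: int = 0
    branch_id: str = "branch0"
    seed: int = 0

    def relations(self) -> list[str]:
        rel = self.relation
        rels = [rel] * self.n_tfs if isinstance(rel, str) else list(rel)
        if len(rels) != self.n_tfs:
            raise ValueError("relation list length must equal n_tfs")
        bad = set(rels) - set(RELATIONS)
        if bad:
            raise ValueError(f"unknown relations: {sorted(bad)}")
        return rels

    def validate(self) -> None:
        if self.n_tfs * self.targets_per_tf + self.n_tfs > self.n_genes:
            raise ValueError(
                "infeasible spec: n_tfs * targets_per_tf + n_tfs exceeds n_genes"
            )
        if not (0.0 <= self.effect <= 1.0):
            raise ValueError("effect must be in [0, 1]")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.outlier_cells >= self.n_cells:
            raise ValueError("outlier_cells must be smaller than n_cells")
        self.relations()


def _latent_curve(rng: np.random.Generator, t: np.ndarray) -> np.ndarray:
    """A smooth latent activity curve on [0, 1], scaled to [0.05, 1]."""
    kind = rng.integers(0, 3)
    if kind == 0:  # sigmoid
        center = rng.uniform(0.25, 0.75)
        steep = rng.uniform(6.0, 14.0) * rng.choice([-1.0, 1.0])
        curve = 1.0 / (1.0 + np.exp(-steep * (t - center)))
    elif kind == 1:  # Gaussian bump
        center = rng.uniform(0.2, 0.8)
        width = rng.uniform(0.1, 0.3)
        curve = np.exp(-0.5 * ((t - center) / width) ** 2)
    else:  # ramp
        curve = t if rng.random() < 0.5 else 1.0 - t
    lo, hi = curve.min(), curve.max()
    curve = (curve - lo) / (hi - lo) if hi > lo else np.full_like(curve, 0.5)
    return 0.05 + 0.95 * curve


def _zinb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float, dropout: float
) -> np.ndarray:
    """ZINB sample: NB around ``mean`` then an independent Bernoulli zero-mask."""
    mean = np.maximum(mean, 1e-6)
    if dispersion > 1e-8:
        r = 1.0 / dispersion
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p).astype(float)
    else:
        counts = rng.poisson(mean).astype(float)
    if dropout > 0:
        counts = np.where(rng.random(counts.shape) < dropout, 0.0, counts)
    return counts


def generate_branch(
    spec: SyntheticSpec,
) -> tuple[BranchMatrix, list[Regulon], pd.DataFrame, dict]:
    """Generate a branch, its planted regulons, cell metadata, and truth info.

    The truth dict records each TF's relation label and, for lagged TFs, the
    planted lag in reference-bin units.  Planted outliers are verified to be
    exactly the cells the 1.5xIQR fence removes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_core = spec.n_cells - spec.outlier_cells
    pt_core = np.sort(rng.uniform(0.0, 1.0, n_core))
    # Outliers sit far beyond any Tukey fence of the combined distribution.
    pt_out = 4.0 + np.arange(spec.outlier_cells, dtype=float)
    pt = np.concatenate([pt_core, pt_out])
    cell_ids = [f"cell{i:05d}" for i in range(spec.n_cells)]
    outlier_ids = set(cell_ids[n_core:])
    if spec.outlier_cells:
        mask = focus_pseudotime(pt, iqr_factor=1.5)
        removed = {cell_ids[i] for i in np.flatnonzero(~mask)}
        if removed != outlier_ids:
            raise RuntimeError("planted outliers do not match the IQR fence removal set")

    rels = spec.relations()
    gene_ids: list[str] = []
    latents = np.empty((spec.n_genes, spec.n_cells))
    regulons: list[Regulon] = []
    truth: dict = {"tfs": {}, "outlier_cells": sorted(outlier_ids)}
    lag_shift = spec.lag_bins / spec.reference_bins
    g = 0
    for ti in range(spec.n_tfs):
        tf_name = f"TF{ti:03d}"
        tf_latent = _latent_curve(rng, pt)
        gene_ids.append(tf_name)
        latents[g] = tf_latent
        g += 1
        relation = rels[ti]
        reg = Regulon(tf=tf_name)
        for k in range(spec.targets_per_tf):
            tgt_name = f"T{ti:03d}_{k:03d}"
            indep = _latent_curve(rng, pt)
            mode = Mode.ACTIVATION
            if relation == "null":
                base = indep
            elif relation == "lagged":
                shifted = np.interp(pt - lag_shift, pt, tf_latent,
                                    left=tf_latent[0], right=tf_latent[-1])
                base = spec.effect * shifted + (1.0 - spec.effect) * indep
            elif relation == "repressed":
                base = spec.effect * (1.05 - tf_latent) + (1.0 - spec.effect) * indep
                mode = Mode.REPRESSION
            elif relation == "nonlinear":
                bump = np.exp(-0.5 * ((tf_latent - 0.5) / 0.2) ** 2)
                base = spec.effect * (0.05 + 0.95 * bump) + (1.0 - spec.effect) * indep
            else:  # linear
                base = spec.effect * tf_latent + (1.0 - spec.effect) * indep
            # Rescale to the common [0.05, 1] dynamic range so planted targets
            # are not distinguishable from null genes by range alone (a linear
            # map, so correlation structure is untouched).
            lo, hi = base.min(), base.max()
            if hi > lo:
                base = 0.05 + 0.95 * (base - lo) / (hi - lo)
            gene_ids.append(tgt_name)
            latents[g] = base
            g += 1
            reg.targets.append((tgt_name, mode))
        regulons.append(reg)
        truth["tfs"][tf_name] = {
            "relation": relation,
            "lag_bins": spec.lag_bins if relation == "lagged" else 0,
            "targets": reg.target_genes,
        }
    # Remaining genes are independent null genes.
    while g < spec.n_genes:
        gene_ids.append(f"N{g:04d}")
        latents[g] = _latent_curve(rng, pt)
        g += 1

    means = spec.mean_scale * latents
    expression = _zinb_draw(rng, means, spec.dispersion, spec.dropout_prob)
    branch = BranchMatrix(
        branch_id=spec.branch_id,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        expression=expression,
        pseudotime=pt,
    )
    metadata = pd.DataFrame(
        {
            "cell_id": branch.cell_ids,
            "branch_id": spec.branch_id,
            "pseudotime": branch.pseudotime,
        }
    )
    return branch, regulons, metadata, truth


def generate_decoys(
    branch: BranchMatrix,
    planted: list[Regulon],
    n_decoys: int,
    targets_per_decoy: int,
    seed: int,
) -> list[Regulon]:
    """Decoy regulons: a null gene as the TF, with targets drawn uniformly
    from the full gene pool (minus every TF gene).

    Drawing decoy targets from the same pool the significance test's random
    background uses is what makes a decoy a true null case: its target set is
    itself a random draw, indistinguishable in distribution from the
    background.  Restricting decoy targets to genes with no planted relation
    would instead plant a detectable distribution shift whenever the pool is
    dominated by planted targets.
    """
    planted_targets = {g for reg in planted for g in reg.target_genes}
    planted_tfs = {reg.tf for reg in planted}
    null_genes = [
        gid for gid in branch.gene_ids
        if gid not in planted_targets and gid not in planted_tfs
    ]
    if len(null_genes) < n_decoys:
        raise ValueError(
            f"not enough null genes for decoy TFs: {len(null_genes)} < {n_decoys}"
        )
    rng = np.random.default_rng(seed)
    decoy_tfs = [str(t) for t in rng.choice(null_genes, size=n_decoys, replace=False)]
    pool = [
        gid for gid in branch.gene_ids
        if gid not in planted_tfs and gid not in set(decoy_tfs)
    ]
    if len(pool) < targets_per_decoy:
        raise ValueError(
            f"gene pool too small for decoy targets: {len(pool)} < {targets_per_decoy}"
        )
    mode_cycle = [Mode.ACTIVATION, Mode.REPRESSION, Mode.UNKNOWN]
    decoys = []
    for i, tf in enumerate(decoy_tfs):
        picks = rng.choice(pool, size=targets_per_decoy, replace=False)
        reg = Regulon(tf=tf)
        for j, gid in enumerate(picks):
            reg.targets.append((str(gid), mode_cycle[(i + j) % 3]))
        decoys.append(reg)
    return decoys


_MODE_LABEL = {
    Mode.ACTIVATION: "Activation",
    Mode.REPRESSION: "Repression",
    Mode.UNKNOWN: "Unknown",
}


def generate_regulon_table(regulons: list[Regulon], path: str | Path) -> None:
    """Write regulons as a TRRUST-dialect 4-column TSV (round-trips through
    io_formats.read_regulons)."""
    if not regulons:
        raise ValueError("no regulons to write")
    lines = []
    for reg in regulons:
        for gene, mode in reg.targets:
            lines.append(f"{reg.tf}\t{gene}\t{_MODE_LABEL[mode]}\t0000000")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fixture_bundle(
    spec: SyntheticSpec,
    out_dir: str | Path,
    n_decoys: int = 0,
    targets_per_decoy: int | None = None,
) -> dict[str, Path]:
    """Write the full fixture bundle: matrix, metadata, regulons, markers, truth.

    Markers are the planted (non-null) TFs, emulating a tissue-marker list for
    evaluation.  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    branch, regulons, metadata, truth = generate_branch(spec)
    if targets_per_decoy is None:
        # Decoys emulate regulons of the same character as the planted ones.
        targets_per_decoy = spec.targets_per_tf
    decoys = (
        generate_decoys(branch, regulons, n_decoys, targets_per_decoy, spec.seed + 1)
        if n_decoys
        else []
    )
    paths = {
        "matrix": out / "expression.tsv",
        "cells": out / "cells.tsv",
        "regulons": out / "regulons.tsv",
        "markers": out / "markers.txt",
        "truth": out / "truth.json",
    }
    df = pd.DataFrame(branch.expression, index=branch.gene_ids, columns=branch.cell_ids)
    df.index.name = "gene"
    df.to_csv(paths["matrix"], sep="\t", float_format="%.6g")
    metadata.to_csv(paths["cells"], sep="\t", index=False, float_format="%.12g")
    generate_regulon_table(regulons + decoys, paths["regulons"])
    markers = [reg.tf for reg in regulons if truth["tfs"][reg.tf]["relation"] != "null"]
    paths["markers"].write_text("\n".join(markers) + "\n")
    truth["decoys"] = {d.tf: d.target_genes for d in decoys}
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return paths
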