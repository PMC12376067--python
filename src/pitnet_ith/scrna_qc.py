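"""Single-cell QC filtering and GH1 expression-heterogeneity statistics.

Filtering rules (boundary semantics fixed): cells are removed when they
detect fewer than 100 genes (strict <) or exceed 10% mitochondrial counts
(strict >), both computed on the raw matrix; genes expressed in fewer than
3 of the retained cells are then removed.  Cell filters run before the gene
filter, so the gene rule is well defined.

Expression statistics use counts-per-10k + log1p normalization.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse

from .synthetic_data import CountMatrix

__all__ = [
    "EmptyResultError",
    "qc_filter",
    "cell_qc_metrics",
    "normalize_cp10k_log1p",
    "classify_tumor_cells",
    "gh1_dispersion",
]


class EmptyResultError(ValueError):
    pass


def cell_qc_metrics(m: CountMatrix) -> pd.DataFrame:
    """Per-cell detected-gene counts and mitochondrial count fraction."""
    counts = m.counts
    detected = np.asarray((counts > 0).sum(axis=0)).ravel()
    total = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    mito = np.asarray(counts[m.mito_gene_mask, :].sum(axis=0)).ravel().astype(float)
    frac = np.divide(mito, total, out=np.zeros_like(total), where=total > 0)
    return pd.DataFrame(
        {"cell": m.cell_ids, "detected_genes": detected, "mito_fraction": frac}
    ).set_index("cell")


def qc_filter(
    m: CountMatrix,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 100,
    max_mito_fraction: float = 0.10,
) -> CountMatrix:
    """Apply the three QC rules; returns the filtered matrix.

    Each pass computes the per-cell metrics on the current matrix (the raw
    matrix on the first pass), removes failing cells, then removes genes
    expressed in too few of the retained cells.  Because dropping genes can
    shift a retained cell's detected-gene count or mitochondrial fraction
    across a threshold, the pass is repeated until a fixed point, so the
    output satisfies all three rules with respect to itself and the filter
    is idempotent.  Raises :class:`EmptyResultError` if no cell survives.
    """
    cur = m
    while True:
        metrics = cell_qc_metrics(cur)
        keep_cells = (
            (metrics["detected_genes"] >= min_genes_per_cell)
            & (metrics["mito_fraction"] <= max_mito_fraction)
        ).to_numpy()
        if not keep_cells.any():
            raise EmptyResultError("all cells removed by QC")
        sub = cur.counts[:, keep_cells]
        expressing = np.asarray((sub > 0).sum(axis=1)).ravel()
        keep_genes = expressing >= min_cells_per_gene
        if keep_cells.all() and keep_genes.all():
            return cur
        cur = CountMatrix(
            sub[keep_genes, :],
            tuple(np.array(cur.gene_names)[keep_genes]),
            tuple(np.array(cur.cell_ids)[keep_cells]),
            tuple(np.array(cur.sample_labels)[keep_cells]),
            cur.mito_prefix,
        )


def normalize_cp10k_log1p(m: CountMatrix) -> np.ndarray:
    """Dense genes x cells matrix of log1p(counts-per-10k) values."""
    total = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    total[total == 0] = 1.0
    dense = np.asarray(m.counts.todense(), dtype=float)
    return np.log1p(dense / total[None, :] * 1e4)


def classify_tumor_cells(
    m: CountMatrix, marker_gene: str = "POU1F1", threshold: float = 0.0
) -> np.ndarray:
    """Flag cells whose normalized marker expression exceeds *threshold*.

    The default rule (normalized expression > 0) flags every
    marker-expressing cell; the cutoff is configuration, not a calibrated
    constant.
    """
    if marker_gene not in m.gene_names:
        raise KeyError(f"marker gene {marker_gene!r} absent")
    gi = m.gene_names.index(marker_gene)
    counts = np.asarray(m.counts[gi, :].todense()).ravel().astype(float)
    total = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    total[total == 0] = 1.0
    norm = np.log1p(counts / total * 1e4)
    return norm > threshold


def gh1_dispersion(
    m: CountMatrix, gene: str = "GH1", tumor_flags: Optional[np.ndarray] = None
) -> pd.DataFrame:
    """Per-sample coefficient of variation of normalized *gene* expression
    among tumor-flagged cells.

    CV = sample SD / mean of the log1p CP10K values; samples with fewer
    than 2 tumor cells are reported with CV = NaN.  A sample whose values
    are identical (SD = 0) gets CV = 0 even at mean 0.
    """
    if gene not in m.gene_names:
        raise KeyError(f"gene {gene!r} absent")
    if tumor_flags is None:
        tumor_flags = classify_tumor_cells(m)
    gi = m.gene_names.index(gene)
    counts = np.asarray(m.counts[gi, :].todense()).ravel().astype(float)
    total = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    total[total == 0] = 1.0
    norm = np.log1p(counts / total * 1e4)
    rows = []
    for s in sorted(set(m.sample_labels)):
        sel = (np.array(m.sample_labels) == s) & tumor_flags
        vals = norm[sel]
        if len(vals) < 2:
            rows.append({"sample_id": s, "n_tumor_cells": int(sel.sum()), "cv": np.nan})
            continue
        sd = float(vals.std(ddof=1))
        mean = float(vals.mean())
        cv = 0.0 if sd == 0 else (sd / mean if mean != 0 else np.nan)
        rows.append({"sample_id": s, "n_tumor_cells": int(sel.sum()), "cv": cv})
    return pd.DataFrame(rows)
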