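"""Cell/gene retention filters and log2 normalization.

Retention rules: cells must show between ``min_genes`` and ``max_genes``
detected genes (both ends inclusive) and a mitochondrial UMI fraction
strictly below ``max_mito``; genes must be detected (count > 0) in at
least ``min_cells`` of the retained cells.  Cells are filtered first, on
the unfiltered gene universe, then genes on the retained cells.

Expression values downstream are ``log2(1 + count * scale /
library_size)`` with a single scale factor per matrix (default 10,000
counts per cell).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData


class EmptyFilterError(ValueError):
    """All cells or all genes were removed by the retention rules."""


@dataclass
class RetentionReport:
    """Per-rule accounting of removed cells and genes.

    A cell failing several rules is attributed to the first failing rule
    in the documented order: gene-count bounds, then mitochondrial
    fraction.
    """

    n_cells_in: int
    n_cells_kept: int
    cells_removed_gene_bounds: int
    cells_removed_mito: int
    n_genes_in: int
    n_genes_kept: int
    genes_removed_min_cells: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": [self.n_cells_in, self.n_cells_kept,
                       self.cells_removed_gene_bounds, self.cells_removed_mito,
                       self.n_genes_in, self.n_genes_kept,
                       self.genes_removed_min_cells]},
            index=["cells_in", "cells_kept", "cells_removed_gene_bounds",
                   "cells_removed_mito", "genes_in", "genes_kept",
                   "genes_removed_min_cells"])


def filter_cells_genes(adata: AnnData,
                       min_genes: int = 200,
                       max_genes: int = 6000,
                       max_mito: float = 0.10,
                       min_cells: int = 5,
                       ) -> tuple[AnnData, RetentionReport]:
    """Apply the retention rules; returns a filtered copy and a report."""
    if "mito" not in adata.var:
        raise ValueError("gene metadata must carry a 'mito' flag column")
    counts = np.asarray(adata.X)
    detected = (counts > 0).sum(axis=1)
    total = counts.sum(axis=1)
    mito_cols = adata.var["mito"].to_numpy(dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0,
                             counts[:, mito_cols].sum(axis=1) / np.maximum(total, 1),
                             0.0)

    ok_bounds = (detected >= min_genes) & (detected <= max_genes)
    ok_mito = mito_frac < max_mito
    keep_cells = ok_bounds & ok_mito
    removed_bounds = int((~ok_bounds).sum())
    removed_mito = int((ok_bounds & ~ok_mito).sum())

    sub = counts[keep_cells]
    genes_detected_in = (sub > 0).sum(axis=0)
    keep_genes = genes_detected_in >= min_cells

    report = RetentionReport(
        n_cells_in=adata.n_obs,
        n_cells_kept=int(keep_cells.sum()),
        cells_removed_gene_bounds=removed_bounds,
        cells_removed_mito=removed_mito,
        n_genes_in=adata.n_vars,
        n_genes_kept=int(keep_genes.sum()),
        genes_removed_min_cells=int((~keep_genes).sum()),
    )
    if report.n_cells_kept == 0 or report.n_genes_kept == 0:
        raise EmptyFilterError(
            f"filtering removed everything (cells kept: {report.n_cells_kept},"
            f" genes kept: {report.n_genes_kept})")
    return adata[keep_cells, keep_genes].copy(), report


def normalize_log2(adata: AnnData, scale: float = 10_000.0) -> AnnData:
    """Size-normalize and log2-transform counts.

    ``value(g, c) = log2(1 + count(g, c) * scale / library_size(c))``.
    Cells with zero library size are rejected with a diagnostic listing
    their barcodes.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    counts = np.asarray(adata.X, dtype=float)
    lib = counts.sum(axis=1)
    if np.any(lib == 0):
        bad = list(adata.obs_names[lib == 0][:10])
        raise ValueError(f"cells with zero library size: {bad}")
    values = np.log2(1.0 + counts * (scale / lib[:, None]))
    out = AnnData(X=values, obs=adata.obs.copy(), var=adata.var.copy())
    out.uns["normalization_scale"] = float(scale)
    return out


def select_hvg(expr: AnnData, n: int, n_bins: int = 20) -> list:
    """Top-``n`` highly variable genes.

    Genes are ranked by a binned dispersion statistic: the variance/mean
    dispersion of the log2 values is z-scored within ``n_bins`` equal-size
    bins of mean expression, which removes the mean-dispersion trend.
    Ties (including whole bins with zero dispersion spread, whose z is set
    to 0) are broken lexicographically by gene id.
    """
    if n > expr.n_vars:
        raise ValueError(f"n={n} exceeds the {expr.n_vars} available genes")
    values = np.asarray(expr.X, dtype=float)
    mean = values.mean(axis=0)
    var = values.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(mean, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(order))
    bins = np.minimum((ranks * n_bins) // len(order), n_bins - 1)
    z = np.zeros_like(disp)
    for b in range(n_bins):
        in_bin = bins == b
        if not in_bin.any():
            continue
        mu, sd = disp[in_bin].mean(), disp[in_bin].std()
        if sd > 0:
            z[in_bin] = (disp[in_bin] - mu) / sd
    gene_ids = expr.var_names.to_numpy()
    # descending z, ties broken lexicographically by gene id
    order = np.lexsort((gene_ids, -z))
    if np.allclose(z, z[0]):
        warnings.warn("all genes tie on the dispersion statistic; "
                      "returning the lexicographically first genes")
    return list(gene_ids[order[:n]])
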