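"""Signature scores, cell-cycle scoring with a binned background control,
and the derived quiescence (G1) score.

A plain signature score is the mean of the log2 expression matrix over the
signature genes, per cell.  The module score subtracts an expression-
matched background: genes are binned by average expression, and for each
signature gene a fixed number of control genes is drawn from its bin;
the score is the signature mean minus the control mean.  Cell-cycle phase
follows the positive-score rule: a cell whose S or G2M score is positive
is assigned the arg-max phase (ties to G2M); otherwise it is G1, with

    G1 = -(S + G2M) / 2

so that deeply non-cycling cells get the largest quiescence score.  Cells
in S or G2M have their G1 score fixed at 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from anndata import AnnData


@dataclass
class GeneSignature:
    name: str
    genes: list
    direction: Optional[dict] = None   # optional per-gene sign (+1/-1)

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")


@dataclass
class ScoringConfig:
    nbin: int = 28
    nctrl: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.nbin < 2:
            raise ValueError("nbin must be at least 2")


class SignatureNotPresentError(KeyError):
    pass


def _present(expr: AnnData, sig: GeneSignature) -> list:
    present = [g for g in sig.genes if g in expr.var_names]
    missing = len(sig.genes) - len(present)
    if not present:
        raise SignatureNotPresentError(
            f"no gene of signature {sig.name!r} is present in the matrix")
    if missing:
        warnings.warn(f"signature {sig.name!r}: {missing} gene(s) absent "
                      "from the matrix, dropped")
    return present


def signature_score(expr: AnnData, sig: GeneSignature) -> pd.Series:
    """Mean log2 expression of the signature genes, per cell.

    Per-gene signs from ``sig.direction`` (if set) weight the mean, so a
    signature can mix up- and down-regulated members.
    """
    present = _present(expr, sig)
    idx = expr.var_names.get_indexer(present)
    values = np.asarray(expr.X)[:, idx]
    if sig.direction:
        signs = np.array([sig.direction.get(g, 1.0) for g in present])
        score = values @ signs / len(present)
    else:
        score = values.mean(axis=1)
    return pd.Series(score, index=expr.obs_names, name=sig.name)


def module_score_binned(expr: AnnData, sig: GeneSignature,
                        config: ScoringConfig = ScoringConfig(),
                        control_pool: Optional[dict] = None) -> pd.Series:
    """Signature mean minus an expression-bin-matched control mean.

    Genes are cut into ``config.nbin`` equal-size bins of average
    expression across cells; ``config.nctrl`` control genes per signature
    gene are drawn (seeded, without replacement when the bin allows it,
    otherwise with replacement and a warning) from the signature gene's
    bin.  ``control_pool`` overrides the drawn controls with an explicit
    ``{signature_gene: [control genes]}`` mapping — useful for calibration
    checks where the background is forced to equal the signal.
    """
    present = _present(expr, sig)
    values = np.asarray(expr.X, dtype=float)
    gene_mean = values.mean(axis=0)
    n_nonsig = expr.n_vars - len(present)
    if control_pool is None and n_nonsig < len(present):
        raise ValueError("need more non-signature genes than signature genes")

    # equal-size bins over the rank of average expression
    order = np.argsort(gene_mean, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(expr.n_vars)
    bins = np.minimum((ranks * config.nbin) // expr.n_vars, config.nbin - 1)
    bin_members = {b: expr.var_names[bins == b].to_numpy()
                   for b in range(config.nbin)}

    rng = np.random.default_rng(config.seed)
    sig_set = set(present)
    controls: list = []
    for g in present:
        if control_pool is not None:
            controls.extend(control_pool[g])
            continue
        b = bins[expr.var_names.get_loc(g)]
        pool = np.array([m for m in bin_members[b] if m not in sig_set])
        if len(pool) == 0:
            pool = bin_members[b]
        if len(pool) >= config.nctrl:
            chosen = rng.choice(pool, size=config.nctrl, replace=False)
        else:
            warnings.warn(
                f"bin of gene {g!r} holds {len(pool)} candidate controls "
                f"(< nctrl={config.nctrl}); sampling with replacement")
            chosen = rng.choice(pool, size=config.nctrl, replace=True)
        controls.extend(chosen)

    sig_idx = expr.var_names.get_indexer(present)
    ctrl_idx = expr.var_names.get_indexer(controls)
    score = values[:, sig_idx].mean(axis=1) - values[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=expr.obs_names, name=sig.name)


def g1_score(s, g2m):
    """Quiescence score: 0 for cycling cells, -(S + G2M)/2 otherwise."""
    s = np.asarray(s, dtype=float)
    g2m = np.asarray(g2m, dtype=float)
    cycling = np.maximum(s, g2m) > 0
    return np.where(cycling, 0.0, -(s + g2m) / 2.0)


def cell_cycle_scores(expr: AnnData, s_genes: GeneSignature,
                      g2m_genes: GeneSignature,
                      config: ScoringConfig = ScoringConfig()) -> pd.DataFrame:
    """Per-cell S/G2M/G1 scores and phase label.

    Phase: the arg-max of (S, G2M) when that maximum is positive (an exact
    tie goes to G2M), else G1.
    """
    s = module_score_binned(expr, s_genes, config)
    g2m = module_score_binned(expr, g2m_genes, config)
    phase = np.where(np.maximum(s, g2m) > 0,
                     np.where(s > g2m, "S", "G2M"), "G1")
    return pd.DataFrame({
        "SScore": s,
        "G2MScore": g2m,
        "G1Score": g1_score(s, g2m),
        "phase": phase,
    }, index=expr.obs_names)


def bulk_g1_score(tpm: pd.DataFrame, s_genes: GeneSignature,
                  g2m_genes: GeneSignature) -> pd.DataFrame:
    """Bulk-sample G1 scores from a samples x genes TPM table.

    Per sample, the mean TPM of each cycle signature is z-scored across
    samples (ddof=1) and the two z-scores are combined with the same rule
    as for single cells: G1 = -(z_S + z_G2M) / 2.
    """
    if tpm.shape[0] < 2:
        raise ValueError("bulk G1 scoring needs at least 2 samples")

    def _z(sig: GeneSignature) -> pd.Series:
        present = [g for g in sig.genes if g in tpm.columns]
        if not present:
            raise SignatureNotPresentError(
                f"no gene of signature {sig.name!r} in the TPM table")
        m = tpm[present].mean(axis=1)
        sd = m.std(ddof=1)
        if sd == 0:
            raise ValueError(
                f"zero variance of {sig.name!r} means across samples; "
                "z-score undefined")
        return (m - m.mean()) / sd

    z_s, z_g2m = _z(s_genes), _z(g2m_genes)
    return pd.DataFrame({
        "z_S": z_s,
        "z_G2M": z_g2m,
        "G1Score": -(z_s + z_g2m) / 2.0,
    })
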