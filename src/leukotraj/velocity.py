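"""Steady-state RNA velocity and a directed-flow statistic.

Under the steady-state model each gene has a constant ratio gamma between
unspliced (u) and spliced (s) abundance; gamma is estimated by regressing
u on s over the cells in the extreme quantiles of s (where the gene is
assumed to sit at steady state).  The per-cell, per-gene velocity is the
residual u - (gamma * s + offset): positive for genes being induced,
negative for repressed ones.

Residual vectors are projected onto a 2-D embedding by neighbor
transition weighting: each cell's arrow is the mean of the unit directions
toward its nearest neighbors, weighted by how well the expression change
toward each neighbor matches the cell's velocity pattern.  The directed
flow between two cell groups is the mean cosine of group-A arrows against
the direction toward group B's centroid, minus the converse — a statistic
in [-1, 1], antisymmetric under group swap, with a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors


@dataclass
class VelocityModel:
    gamma: pd.Series            # per gene
    offset: pd.Series           # per gene
    residuals: pd.DataFrame     # cells x genes, u - (gamma*s + offset)
    skipped_genes: list         # degenerate genes left out


@dataclass
class FlowScore:
    source: str
    target: str
    statistic: float
    p_value: float


def pool_counts(values: np.ndarray, embedding: np.ndarray,
                n_neighbors: int = 30) -> np.ndarray:
    """k-nearest-neighbor pooling (mean over each cell's neighborhood in
    the embedding, the cell included); stabilizes per-cell residual signs."""
    k = min(n_neighbors, len(embedding))
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    return values[idx].mean(axis=1)


def fit_steady_state_gamma(spliced: np.ndarray, unspliced: np.ndarray,
                           quantile: float = 0.02,
                           fit_offset: bool = False):
    """Per-gene steady-state ratio from extreme-quantile cells.

    Cells in the lower and upper ``quantile`` tails of s anchor the
    regression of u on s (through the origin unless ``fit_offset``).
    Returns ``(gamma, offset)`` or ``None`` for a degenerate gene (all
    zero, or no spread in s).
    """
    s = np.asarray(spliced, dtype=float)
    u = np.asarray(unspliced, dtype=float)
    nonzero = (s > 0) | (u > 0)
    if nonzero.sum() < 20:
        return None
    lo, hi = np.quantile(s, [quantile, 1.0 - quantile])
    if hi <= lo:
        return None
    tails = (s <= lo) | (s >= hi)
    st, ut = s[tails], u[tails]
    if fit_offset:
        X = np.column_stack([st, np.ones_like(st)])
        coef, *_ = np.linalg.lstsq(X, ut, rcond=None)
        gamma, offset = coef
    else:
        denom = (st * st).sum()
        if denom == 0:
            return None
        gamma, offset = (st * ut).sum() / denom, 0.0
    if gamma <= 0:
        return None
    return float(gamma), float(offset)


def fit_velocity_model(spliced: pd.DataFrame, unspliced: pd.DataFrame,
                       quantile: float = 0.02, fit_offset: bool = False,
                       embedding=None, n_neighbors: int = 30) -> VelocityModel:
    """Fit gamma per gene and compute residual velocities.

    Gamma is always fitted on the raw per-cell values — the extreme
    quantiles of raw s are the cells the steady-state anchoring relies
    on.  When ``embedding`` is given, the *residuals* are computed on
    kNN-pooled s and u instead, which suppresses shot noise in the
    per-cell velocity signs without disturbing the fit.  Degenerate genes
    are skipped and listed on the model.
    """
    s = np.asarray(spliced, dtype=float)
    u = np.asarray(unspliced, dtype=float)
    if embedding is not None:
        emb = np.asarray(embedding, dtype=float)
        s_res = pool_counts(s, emb, n_neighbors)
        u_res = pool_counts(u, emb, n_neighbors)
    else:
        s_res, u_res = s, u
    genes = list(spliced.columns)
    cells = spliced.index
    gamma, offset, resid, skipped = {}, {}, {}, []
    for j, g in enumerate(genes):
        fitres = fit_steady_state_gamma(s[:, j], u[:, j],
                                        quantile=quantile,
                                        fit_offset=fit_offset)
        if fitres is None:
            skipped.append(g)
            continue
        gamma[g], offset[g] = fitres
        resid[g] = u_res[:, j] - (gamma[g] * s_res[:, j] + offset[g])
    return VelocityModel(
        gamma=pd.Series(gamma, name="gamma"),
        offset=pd.Series(offset, name="offset"),
        residuals=pd.DataFrame(resid, index=cells),
        skipped_genes=skipped,
    )


def velocity_vectors(model: VelocityModel, embedding: pd.DataFrame,
                     expression: pd.DataFrame,
                     n_neighbors: int = 30) -> pd.DataFrame:
    """Project residual velocities onto the embedding.

    For each cell, the arrow is the weighted mean of unit directions
    toward its nearest embedding neighbors; the weight of a neighbor is
    the cosine similarity between the cell's residual vector and the
    expression change toward that neighbor, so arrows point where the
    transcriptome is headed.  Cells with (near-)zero residuals get zero
    vectors.  Flipping every residual sign negates every arrow.
    """
    emb = np.asarray(embedding, dtype=float)
    genes = model.residuals.columns
    expr = np.asarray(expression[genes], dtype=float)
    resid = model.residuals.to_numpy()
    n = len(emb)
    k = min(n_neighbors + 1, n)
    nn = NearestNeighbors(n_neighbors=k).fit(emb)
    _, idx = nn.kneighbors(emb)

    vectors = np.zeros((n, emb.shape[1]))
    scale = np.abs(resid).max()
    if scale == 0:
        return pd.DataFrame(vectors, index=embedding.index,
                            columns=["vx", "vy"])
    for i in range(n):
        v = resid[i]
        norm_v = np.linalg.norm(v)
        if norm_v <= 1e-12 * scale:
            continue
        neigh = idx[i][idx[i] != i]
        d_expr = expr[neigh] - expr[i]
        d_emb = emb[neigh] - emb[i]
        emb_norm = np.linalg.norm(d_emb, axis=1)
        expr_norm = np.linalg.norm(d_expr, axis=1)
        ok = (emb_norm > 0) & (expr_norm > 0)
        if not ok.any():
            continue
        w = (d_expr[ok] @ v) / (expr_norm[ok] * norm_v)
        vectors[i] = (w[:, None] * d_emb[ok] / emb_norm[ok][:, None]).mean(axis=0)
    return pd.DataFrame(vectors, index=embedding.index, columns=["vx", "vy"])


def flow_direction_score(vectors: pd.DataFrame, embedding: pd.DataFrame,
                         group_a, group_b,
                         n_permutations: int = 1000,
                         seed: int = 0) -> FlowScore:
    """Directed flow between two cell groups.

    statistic = mean_A cos(arrow_i, centroid_B - x_i)
              - mean_B cos(arrow_j, centroid_A - x_j)

    Zero arrows contribute zero cosine.  The p-value comes from permuting
    the group labels over the pooled cells.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    emb = embedding.loc[group_a + group_b].to_numpy(dtype=float)
    vec = vectors.loc[group_a + group_b].to_numpy(dtype=float)
    na = len(group_a)
    cent_a = emb[:na].mean(axis=0)
    cent_b = emb[na:].mean(axis=0)
    if np.allclose(cent_a, cent_b):
        raise ValueError("group centroids coincide; flow direction undefined")

    def _stat(mask_a: np.ndarray) -> float:
        ca = emb[mask_a].mean(axis=0)
        cb = emb[~mask_a].mean(axis=0)

        def _mean_cos(mask, target):
            x, v = emb[mask], vec[mask]
            toward = target[None, :] - x
            tn = np.linalg.norm(toward, axis=1)
            vn = np.linalg.norm(v, axis=1)
            ok = (tn > 0) & (vn > 0)
            cos = np.zeros(mask.sum())
            cos[ok] = (v[ok] * toward[ok]).sum(axis=1) / (vn[ok] * tn[ok])
            return cos.mean()

        return _mean_cos(mask_a, cb) - _mean_cos(~mask_a, ca)

    mask = np.zeros(len(emb), dtype=bool)
    mask[:na] = True
    observed = _stat(mask)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = _stat(rng.permutation(mask))
    p = (1.0 + (np.abs(null) >= abs(observed)).sum()) / (n_permutations + 1.0)
    return FlowScore(source="A", target="B", statistic=float(observed),
                     p_value=float(p))
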