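"""Two-lineage trajectory fitting, pseudotime-dynamic gene detection and
the tipping-point signature.

The trajectory model: a shared progenitor trunk that bifurcates into a
*differentiation* and a *transformation* lineage.  Each lineage is a
smooth one-dimensional principal curve through the cluster centroids from
the root cluster to that lineage's terminal cluster, discretized to a
fixed number of points (300 by default); a cell's pseudotime is the
normalized arc length of its orthogonal projection onto the curve.

Dynamic genes are detected per lineage by comparing a penalized-spline
regression of expression on pseudotime against a constant model with an
F-type test, with Benjamini-Hochberg correction across genes.  Genes
significantly *down* along differentiation (set 2) and *up* along
transformation (set 4) intersect into the tipping-point signature — the
program that distinguishes commitment to malignant transformation from
normal maturation at the branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.interpolate import BSpline
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from scipy.spatial.distance import cdist
from scipy.stats import f as f_dist
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# principal curve fitting
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryFit:
    """Per-cell lineage assignment and pseudotime plus the fitted curves."""

    lineage: pd.Series                 # per cell: lineage name or "trunk"
    pseudotime: pd.DataFrame           # one column per lineage, NaN off-lineage
    curves: dict                       # lineage -> (n_points, 2) array
    cluster_paths: dict = field(default_factory=dict)

    def members(self, lineage: str) -> pd.Index:
        """Cells on a lineage (its own cells plus the shared trunk)."""
        return self.pseudotime.index[self.pseudotime[lineage].notna()]

    def lineage_pseudotime(self, lineage: str) -> pd.Series:
        return self.pseudotime.loc[self.members(lineage), lineage]


def _arc_length(curve: np.ndarray) -> np.ndarray:
    seg = np.sqrt(((np.diff(curve, axis=0)) ** 2).sum(axis=1))
    return np.concatenate([[0.0], np.cumsum(seg)])


def _resample_uniform(curve: np.ndarray, n_points: int) -> np.ndarray:
    lam = _arc_length(curve)
    if lam[-1] == 0:
        return np.repeat(curve[:1], n_points, axis=0)
    grid = np.linspace(0.0, lam[-1], n_points)
    return np.column_stack([np.interp(grid, lam, curve[:, d])
                            for d in range(curve.shape[1])])


def _fit_principal_curve(points: np.ndarray, init: np.ndarray,
                         n_points: int = 300, max_iter: int = 50,
                         tol: float = 1e-4, frac: float = 0.3
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Iterative projection-smoothing principal curve.

    Starts from ``init`` (the cluster-centroid polyline), alternates
    projecting cells onto the discretized curve with lowess-smoothing each
    coordinate against the projection arc length, and stops when the mean
    projection distance changes by less than ``tol`` (relative) or after
    ``max_iter`` rounds.  Returns the curve (``n_points`` x 2) and each
    cell's arc-length parameter.
    """
    curve = _resample_uniform(init, n_points)
    prev = np.inf
    lam_cells = None
    for _ in range(max_iter):
        d = cdist(points, curve)
        nearest = d.argmin(axis=1)
        lam = _arc_length(curve)
        lam_cells = lam[nearest]
        mean_dist = d[np.arange(len(points)), nearest].mean()
        if prev - mean_dist <= tol * max(prev, 1e-12):
            break
        prev = mean_dist
        grid = np.linspace(lam_cells.min(), lam_cells.max(), n_points)
        new = np.empty((n_points, points.shape[1]))
        for dim in range(points.shape[1]):
            sm = lowess(points[:, dim], lam_cells, frac=frac, it=0,
                        return_sorted=True)
            new[:, dim] = np.interp(grid, sm[:, 0], sm[:, 1])
        curve = _resample_uniform(new, n_points)
    curve = _extend_ends(curve, points, n_points)
    d = cdist(points, curve)
    nearest = d.argmin(axis=1)
    lam_cells = _arc_length(curve)[nearest]
    return curve, lam_cells


def _extend_ends(curve: np.ndarray, points: np.ndarray,
                 n_points: int) -> np.ndarray:
    """Prolong the curve along its end tangents to cover cells projecting
    beyond the endpoints, then re-discretize to ``n_points``."""
    out = curve
    for end in (0, -1):
        tangent = out[end] - (out[1] if end == 0 else out[-2])
        norm = np.linalg.norm(tangent)
        if norm == 0:
            continue
        tangent = tangent / norm
        overshoot = (points - out[end]) @ tangent
        extent = overshoot.max()
        if extent > 0:
            tip = out[end] + tangent * extent
            out = np.vstack([tip, out]) if end == 0 else np.vstack([out, tip])
    return _resample_uniform(out, n_points)


def _cluster_path(centroids: pd.DataFrame, root, terminal) -> list:
    """Root-to-terminal cluster path along the centroid spanning tree."""
    labels = list(centroids.index)
    dist = cdist(centroids.to_numpy(), centroids.to_numpy())
    mst = minimum_spanning_tree(dist)
    _, predecessors = shortest_path(mst, directed=False, return_predecessors=True,
                                    indices=labels.index(root))
    path = [labels.index(terminal)]
    while path[-1] != labels.index(root):
        prev = predecessors[path[-1]]
        if prev < 0:
            raise ValueError(
                f"cluster graph is disconnected: no path from {root!r} "
                f"to {terminal!r}")
        path.append(prev)
    return [labels[i] for i in reversed(path)]


def fit_lineage_curve(embedding: pd.DataFrame,
                      cluster_labels: pd.Series,
                      root,
                      terminals: dict,
                      n_points: int = 300,
                      max_iter: int = 50,
                      tol: float = 1e-4,
                      divergence_scale: float = 1.0) -> TrajectoryFit:
    """Fit one principal curve per lineage through ordered clusters.

    Parameters
    ----------
    embedding:
        Cells x 2 coordinates (index = barcodes).
    cluster_labels:
        Per-cell cluster assignment, aligned with ``embedding``.
    root:
        The shared root cluster.
    terminals:
        ``{lineage_name: terminal cluster}`` — typically
        ``{"differentiation": ..., "transformation": ...}``.

    Cells in clusters shared by every lineage path (the prefix from the
    root) are labeled ``"trunk"``; they receive a pseudotime on each
    lineage.  Pseudotime is normalized arc length in [0, 1] per lineage.
    """
    embedding = pd.DataFrame(embedding)
    cluster_labels = pd.Series(cluster_labels).loc[embedding.index]
    present = set(cluster_labels)
    for c in [root, *terminals.values()]:
        if c not in present:
            raise ValueError(f"cluster {c!r} absent from the labels")

    centroids = embedding.groupby(cluster_labels).mean()
    paths = {lin: _cluster_path(centroids, root, term)
             for lin, term in terminals.items()}
    shared = set.intersection(*(set(p) for p in paths.values())) \
        if len(paths) > 1 else {root}

    coords = embedding.to_numpy(dtype=float)
    curves: dict = {}
    for lin, path in paths.items():
        on_path = cluster_labels.isin(path).to_numpy()
        if on_path.sum() < 50:
            raise ValueError(f"lineage {lin!r} has fewer than 50 cells")
        init = centroids.loc[path].to_numpy(dtype=float)
        curve, _ = _fit_principal_curve(coords[on_path], init,
                                        n_points=n_points,
                                        max_iter=max_iter, tol=tol)
        curves[lin] = curve

    # project every cell of the combined paths onto every curve; cells are
    # assigned to the lineage whose curve they are closest to, and cells
    # whose projection falls before the point where the curves diverge
    # are labeled trunk and shared by all lineages — a hard cluster-based
    # assignment would misplace cells near the branch and distort the
    # early part of each lineage's expression trends
    union = set().union(*paths.values())
    member = cluster_labels.isin(union).to_numpy()
    pt = pd.DataFrame(np.nan, index=embedding.index, columns=list(terminals))
    dist = {}
    for lin, curve in curves.items():
        d = cdist(coords[member], curve)
        nearest = d.argmin(axis=1)
        lam = _arc_length(curve)[nearest]
        total = lam.max()
        pt.loc[embedding.index[member], lin] = \
            lam / (total if total > 0 else 1.0)
        dist[lin] = d[np.arange(member.sum()), nearest]

    lineage = pd.Series("unassigned", index=embedding.index, dtype=object)
    names = list(curves)
    if len(names) > 1:
        branch_frac = _divergence_fractions(curves, coords[member], dist,
                                            divergence_scale)
        closest = np.array(names)[np.argmin(
            np.column_stack([dist[lin] for lin in names]), axis=1)]
        member_index = embedding.index[member]
        lineage[member_index] = closest
        # trunk: projection before the divergence point on the assigned curve
        own_pt = np.array([pt.loc[c, lin]
                           for c, lin in zip(member_index, closest)])
        trunk_mask = own_pt <= np.array([branch_frac[lin] for lin in closest])
        lineage[member_index[trunk_mask]] = "trunk"
        for lin in names:
            off = (lineage.loc[member_index] != lin).to_numpy() & ~trunk_mask
            pt.loc[member_index[off], lin] = np.nan
    else:
        lineage[member] = names[0]      # single lineage: no trunk
    return TrajectoryFit(lineage=lineage, pseudotime=pt, curves=curves,
                         cluster_paths=paths)


def _divergence_fractions(curves: dict, points: np.ndarray,
                          dist: dict, divergence_scale: float = 1.0) -> dict:
    """Arc-length fraction at which each curve separates from the others.

    The separation scale is ``divergence_scale`` times the cells' median
    projection distance: while two curves run within that scale of each
    other they are statistically indistinguishable and the region between
    them is the shared trunk.
    """
    scale = float(np.median(np.min(
        np.column_stack([dist[lin] for lin in curves]), axis=1)))
    scale = max(scale * divergence_scale, 1e-12)
    fracs = {}
    for lin, curve in curves.items():
        lam = _arc_length(curve)
        total = lam[-1] if lam[-1] > 0 else 1.0
        sep = np.full(len(curve), np.inf)
        for other, oc in curves.items():
            if other == lin:
                continue
            sep = np.minimum(sep, cdist(curve, oc).min(axis=1))
        diverged = np.nonzero(sep > scale)[0]
        fracs[lin] = lam[diverged[0]] / total if len(diverged) else 1.0
    return fracs


# ---------------------------------------------------------------------------
# dynamic genes along pseudotime
# ---------------------------------------------------------------------------

def _spline_basis(x: np.ndarray, df: int = 5, degree: int = 3) -> np.ndarray:
    """Cubic B-spline design matrix with ``df`` basis functions (interior
    knots at pseudotime quantiles)."""
    n_inner = df - degree - 1
    lo, hi = x.min(), x.max()
    inner = np.quantile(x, np.linspace(0, 1, n_inner + 2)[1:-1]) \
        if n_inner > 0 else np.array([])
    t = np.r_[[lo] * (degree + 1), inner, [hi] * (degree + 1)]
    return BSpline.design_matrix(x, t, degree, extrapolate=True).toarray()


def pseudotime_dynamic_genes(expr: AnnData, fit: TrajectoryFit,
                             lineage: str, df: int = 5,
                             q_threshold: float = 0.05) -> pd.DataFrame:
    """Per-gene smooth-versus-constant test along one lineage.

    Expression of each gene is regressed on pseudotime with a cubic
    spline basis (``df`` effective degrees of freedom, all genes share the
    design), and compared against the constant model with an F test.
    P-values are Benjamini-Hochberg adjusted across genes.  Direction is
    the sign of the fitted value at the lineage end minus the start; it
    is ``flat`` for genes whose q exceeds ``q_threshold`` (a constant
    gene gets p = 1 and ``flat``), and also for significant genes whose
    end-to-start contrast is itself indistinguishable from zero (|delta|
    below twice its standard error) — a localized wiggle can make the F
    test fire without any monotone end-to-end change, and the gene sets
    downstream are defined by the latter.

    Returns a frame indexed by gene with columns
    ``statistic, p, q, delta, delta_se, direction``.
    """
    members = fit.members(lineage)
    if len(members) < 100:
        raise ValueError(f"lineage {lineage!r} has fewer than 100 cells")
    pt = fit.lineage_pseudotime(lineage).to_numpy(dtype=float)
    Y = np.asarray(expr[members].X, dtype=float)
    n, n_genes = Y.shape

    X = _spline_basis(pt, df=df)
    Q, R = np.linalg.qr(X)
    rank = X.shape[1]
    fitted = Q @ (Q.T @ Y)
    rss1 = ((Y - fitted) ** 2).sum(axis=0)
    rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)

    df_num, df_den = rank - 1, n - rank
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    constant = rss0 <= 1e-12 * np.maximum((Y ** 2).sum(axis=0), 1e-300)
    stat = np.where(constant | ~np.isfinite(stat), 0.0, np.maximum(stat, 0.0))
    p = f_dist.sf(stat, df_num, df_den)
    p = np.where(constant, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]

    # endpoint fitted values at inner pseudotime quantiles: the extreme
    # cells sit in sparse curve ends where the spline is unstable
    i_start = np.abs(pt - np.quantile(pt, 0.025)).argmin()
    i_end = np.abs(pt - np.quantile(pt, 0.975)).argmin()
    delta = fitted[i_end] - fitted[i_start]
    # standard error of the endpoint contrast: h' (X'X)^-1 h * sigma^2
    h = X[i_end] - X[i_start]
    y = np.linalg.solve(R.T, h)         # (X'X)^-1 = R^-1 R^-T
    leverage = float(y @ y)
    sigma2 = rss1 / max(df_den, 1)
    delta_se = np.sqrt(np.maximum(leverage * sigma2, 0.0))
    contrast_ok = np.abs(delta) > 2.0 * delta_se
    direction = np.where((q < q_threshold) & contrast_ok,
                         np.where(delta > 0, "up", "down"), "flat")
    direction = np.where(constant, "flat", direction)
    return pd.DataFrame({"statistic": stat, "p": p, "q": q, "delta": delta,
                         "delta_se": delta_se, "direction": direction},
                        index=expr.var_names)


# ---------------------------------------------------------------------------
# gene sets and the tipping-point signature
# ---------------------------------------------------------------------------

@dataclass
class LineageGeneSets:
    """The four direction-by-lineage gene sets.

    set1/set2: up/down along the differentiation lineage;
    set3/set4: down/up along the transformation lineage.
    """

    set1: set
    set2: set
    set3: set
    set4: set
    q_threshold: float = 0.05


@dataclass
class TippingPointSignature:
    genes: set
    provenance: dict


def classify_gene_sets(diff_results: pd.DataFrame,
                       transf_results: pd.DataFrame,
                       q_threshold: float = 0.05) -> LineageGeneSets:
    """Split dynamic-gene results into the four lineage/direction sets."""
    if set(diff_results.index) != set(transf_results.index):
        raise ValueError("the two result tables cover different gene universes")

    def _sig(res, up: bool) -> set:
        keep = (res["q"] < q_threshold) & \
               ((res["delta"] > 0) if up else (res["delta"] < 0))
        if "delta_se" in res:
            keep &= res["delta"].abs() > 2.0 * res["delta_se"]
        return set(res.index[keep])

    return LineageGeneSets(
        set1=_sig(diff_results, up=True),
        set2=_sig(diff_results, up=False),
        set3=_sig(transf_results, up=False),
        set4=_sig(transf_results, up=True),
        q_threshold=q_threshold,
    )


def tipping_point_signature(sets: LineageGeneSets) -> TippingPointSignature:
    """Intersect set 2 (down along differentiation) with set 4 (up along
    transformation)."""
    genes = sets.set2 & sets.set4
    if not genes:
        warnings.warn("tipping-point signature is empty")
    return TippingPointSignature(
        genes=genes,
        provenance={
            "set2_size": len(sets.set2),
            "set4_size": len(sets.set4),
            "q_threshold": sets.q_threshold,
        },
    )
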