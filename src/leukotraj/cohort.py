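"""Cross-species subtype matching, threshold-based differential-expression
signatures, and signature-score survival stratification.

Subtype centroids (per-subtype mean log2 expression) from two species are
placed in a shared orthologous gene space and clustered hierarchically
(1 - Spearman correlation, average linkage); each subtype's best match is
the most correlated subtype of the other species.  Differential-
expression signatures are threshold-defined gene sets (log2 fold change
above a cutoff at a Benjamini-Hochberg adjusted p below a cutoff, from a
two-group test on normalized log counts).  Survival stratification uses
the maximally selected log-rank cutpoint on a per-patient score, the
Kaplan-Meier product-limit estimator, and the two-group log-rank
chi-square test.  Because a maximally selected cutpoint is
anti-conservative, cutpoint-derived p-values are labeled exploratory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.cluster.hierarchy import average, dendrogram
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr, ttest_ind
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# orthologs and cross-species matching
# ---------------------------------------------------------------------------

def collapse_orthologs(expr: pd.DataFrame, ortholog_map: pd.DataFrame,
                       source_col: str = "human_gene",
                       target_col: str = "mouse_gene") -> pd.DataFrame:
    """Map a samples x genes matrix into the target species' gene space.

    1:1 pairs are renamed; many:1 (several source genes, one target) are
    collapsed by their mean; 1:many are duplicated.  Source genes without
    a mapping are dropped (the count is stored in ``attrs``).
    """
    if ortholog_map.empty:
        raise ValueError("ortholog map is empty")
    pairs = ortholog_map[[source_col, target_col]].drop_duplicates()
    pairs = pairs[pairs[source_col].isin(expr.columns)]
    if pairs.empty:
        raise ValueError("no mapped gene is present in the matrix")
    long = expr[pairs[source_col]].T
    long.index = pd.Index(pairs[target_col].to_numpy(), name=target_col)
    collapsed = long.groupby(level=0, sort=False).mean().T
    collapsed.attrs["n_unmapped_dropped"] = int(
        expr.shape[1] - expr.columns.isin(set(pairs[source_col])).sum())
    return collapsed


@dataclass
class CrossSpeciesMatch:
    linkage: np.ndarray                 # scipy linkage over all subtypes
    labels: list                        # row order matching the linkage
    correlations: pd.DataFrame          # A-subtypes x B-subtypes Spearman
    best_match: pd.DataFrame            # per subtype: best cross-species match


def cross_species_cluster(centroids_a: pd.DataFrame,
                          centroids_b: pd.DataFrame,
                          species_a: str = "mmu",
                          species_b: str = "hsa") -> CrossSpeciesMatch:
    """Hierarchical clustering of combined subtype centroids.

    Inputs are subtype x gene centroid matrices on a shared gene space.
    Distance is 1 - Spearman correlation, average linkage.  Constant
    centroid rows make the correlation undefined and raise.
    """
    shared = centroids_a.columns.intersection(centroids_b.columns)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes across species")
    if len(centroids_a) < 2 or len(centroids_b) < 2:
        raise ValueError("need at least 2 subtypes per species")
    a = centroids_a[shared]
    b = centroids_b[shared]
    for name, frame in ((species_a, a), (species_b, b)):
        flat = frame.std(axis=1) == 0
        if flat.any():
            bad = list(frame.index[flat])
            raise ValueError(f"constant centroid(s) in {name}: {bad}")

    combined = pd.concat([
        a.set_index(pd.Index([f"{species_a}:{s}" for s in a.index])),
        b.set_index(pd.Index([f"{species_b}:{s}" for s in b.index])),
    ])
    rho = spearmanr(combined.to_numpy().T)[0]
    if np.isscalar(rho):       # two subtypes total
        rho = np.array([[1.0, rho], [rho, 1.0]])
    dist = squareform(np.clip(1.0 - rho, 0.0, 2.0), checks=False)
    Z = average(dist)

    cross = pd.DataFrame(rho[:len(a), len(a):], index=a.index,
                         columns=b.index)
    best_rows = []
    for s in a.index:
        j = cross.loc[s].idxmax()
        best_rows.append({"subtype": s, "species": species_a,
                          "best_match": j, "correlation": cross.loc[s, j]})
    for s in b.index:
        i = cross[s].idxmax()
        best_rows.append({"subtype": s, "species": species_b,
                          "best_match": i, "correlation": cross.loc[i, s]})
    return CrossSpeciesMatch(
        linkage=Z, labels=list(combined.index),
        correlations=cross,
        best_match=pd.DataFrame(best_rows).set_index(["species", "subtype"]))


# ---------------------------------------------------------------------------
# threshold-defined DEG signatures
# ---------------------------------------------------------------------------

@dataclass
class DEGSignature:
    genes: list
    lfc_cutoff: float
    padj_cutoff: float
    contrast: str
    table: pd.DataFrame


def deg_signature(counts: pd.DataFrame, groups: pd.Series,
                  case, control,
                  lfc_cutoff: float = 3.0,
                  padj_cutoff: float = 0.05) -> DEGSignature:
    """Genes up in ``case`` versus ``control`` past both thresholds.

    ``counts`` is samples x genes (raw).  Counts are library-size
    normalized to counts per million; the fold change is the log2 ratio
    of group means with a pseudocount of 1, and the p-value comes from a
    two-sample t test on the log2(CPM + 1) values (a deliberately simple
    test — the signature is defined by the thresholds, not by a
    dispersion model).  Benjamini-Hochberg adjustment across genes.
    """
    groups = pd.Series(groups).loc[counts.index]
    idx_case = groups[groups == case].index
    idx_ctrl = groups[groups == control].index
    if len(idx_case) < 2 or len(idx_ctrl) < 2:
        raise ValueError("each group needs at least 2 samples")
    lib = counts.sum(axis=1).to_numpy()
    cpm = counts.to_numpy(dtype=float) / lib[:, None] * 1e6
    logc = np.log2(cpm + 1.0)
    frame = pd.DataFrame(logc, index=counts.index, columns=counts.columns)

    case_m = cpm[counts.index.get_indexer(idx_case)].mean(axis=0)
    ctrl_m = cpm[counts.index.get_indexer(idx_ctrl)].mean(axis=0)
    lfc = np.log2(case_m + 1.0) - np.log2(ctrl_m + 1.0)
    t = ttest_ind(frame.loc[idx_case], frame.loc[idx_ctrl], axis=0)
    p = np.where(np.isfinite(t.pvalue), t.pvalue, 1.0)
    padj = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame({"log2fc": lfc, "p": p, "padj": padj},
                         index=counts.columns)
    keep = (table["log2fc"] > lfc_cutoff) & (table["padj"] < padj_cutoff)
    return DEGSignature(genes=sorted(table.index[keep]),
                        lfc_cutoff=lfc_cutoff, padj_cutoff=padj_cutoff,
                        contrast=f"{case} vs {control}", table=table)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def clean_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Drop patients with unknown follow-up or event status."""
    keep = cohort["time_days"].notna() & cohort["event"].notna() \
        & (cohort["time_days"] > 0)
    return cohort.loc[keep].copy()


def logrank_test(cohort: pd.DataFrame, labels) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p).

    One degree of freedom, chi-square upper tail, no continuity
    correction.
    """
    labels = pd.Series(labels, index=cohort.index) \
        if not isinstance(labels, pd.Series) else labels.loc[cohort.index]
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    a = cohort[labels == groups[0]]
    b = cohort[labels == groups[1]]
    if a.empty or b.empty:
        raise ValueError("a group has zero observations")
    res = _ll_logrank(a["time_days"], b["time_days"],
                      event_observed_A=a["event"], event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def km_estimate(cohort: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns the right-continuous step function as a frame with columns
    ``time`` and ``survival`` (starting from S(0) = 1).
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    km = KaplanMeierFitter()
    km.fit(cohort["time_days"], event_observed=cohort["event"])
    sf = km.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Per-patient log-rank scores a_i = delta_i - Lambda(t_i) with the
    Nelson-Aalen cumulative hazard."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    cumhaz = np.zeros(len(time))
    for tj in np.unique(time[event == 1]):
        at_risk = (time >= tj).sum()
        dj = ((time == tj) & (event == 1)).sum()
        cumhaz[time >= tj] += dj / at_risk
    return event - cumhaz


def survival_cutpoint(cohort: pd.DataFrame, score_col: str = "score",
                      minprop: float = 0.1) -> float:
    """Maximally selected log-rank cutpoint on a per-patient score.

    The standardized log-rank statistic of a split is the centered sum of
    the low-group patients' log-rank scores, scaled by its
    without-replacement sampling variance (the maximally-selected rank
    statistic with log-rank scores).  Every split between consecutive
    distinct score values that leaves at least ``minprop`` of the
    patients on each side is scanned and the cut (midpoint between the
    bracketing scores) with the largest |z| is returned; ties go to the
    split closest to the median score.  The resulting grouping is
    selection-biased: p-values computed after this cut are exploratory.
    """
    if not 0.0 < minprop <= 0.5:
        raise ValueError("minprop must be in (0, 0.5]")
    cohort = clean_cohort(cohort)
    n = len(cohort)
    if n < 10:
        raise ValueError("need at least 10 patients")
    scores = cohort[score_col].to_numpy(dtype=float)
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("all scores are identical; no cutpoint exists")

    a = logrank_scores(cohort["time_days"].to_numpy(),
                       cohort["event"].to_numpy())
    a_bar = a.mean()
    ss = ((a - a_bar) ** 2).sum()
    if ss == 0:
        raise ValueError("no events in the cohort; cutpoint undefined")

    min_side = int(np.ceil(minprop * n))
    median = np.median(scores)
    best = None
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = (lo + hi) / 2.0
        low = scores <= cut
        m = int(low.sum())
        if m < min_side or n - m < min_side:
            continue
        s = a[low].sum()
        var = m * (n - m) * ss / (n * (n - 1))
        z = abs(s - m * a_bar) / np.sqrt(var)
        key = (z, -abs(cut - median))
        if best is None or key > best[0]:
            best = (key, cut)
    if best is None:
        raise ValueError("no admissible split under the minprop constraint")
    return float(best[1])


def stratify_survival(cohort: pd.DataFrame, score_col: str = "score",
                      minprop: float = 0.1) -> dict:
    """Cutpoint grouping + KM curves + log-rank, in one report.

    The log-rank p is labeled exploratory because the cutpoint is
    maximally selected.
    """
    cohort = clean_cohort(cohort)
    cut = survival_cutpoint(cohort, score_col=score_col, minprop=minprop)
    labels = pd.Series(np.where(cohort[score_col] > cut, "high", "low"),
                       index=cohort.index)
    stat, p = logrank_test(cohort, labels)
    return {
        "cutpoint": cut,
        "n_high": int((labels == "high").sum()),
        "n_low": int((labels == "low").sum()),
        "logrank_chi2": stat,
        "logrank_p": p,
        "p_is_exploratory": True,
        "km_high": km_estimate(cohort[labels == "high"]),
        "km_low": km_estimate(cohort[labels == "low"]),
    }
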