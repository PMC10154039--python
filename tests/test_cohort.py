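"""Ortholog collapse, cross-species matching, DEG signatures, survival."""

import numpy as np
import pandas as pd
import pytest

import leukotraj as lt
from leukotraj import synthetic as syn


# ---------------------------------------------------------------------------
# orthologs
# ---------------------------------------------------------------------------

def test_identity_map_preserves_matrix():
    expr = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], columns=["A", "B"],
                        index=["s1", "s2"])
    omap = pd.DataFrame({"human_gene": ["A", "B"], "mouse_gene": ["a", "b"]})
    out = lt.collapse_orthologs(expr, omap)
    np.testing.assert_allclose(out[["a", "b"]].to_numpy(), expr.to_numpy())


def test_many_to_one_collapses_by_mean():
    expr = pd.DataFrame([[2.0, 4.0]], columns=["H1", "H2"], index=["s"])
    omap = pd.DataFrame({"human_gene": ["H1", "H2"],
                         "mouse_gene": ["m", "m"]})
    out = lt.collapse_orthologs(expr, omap)
    assert out.loc["s", "m"] == 3.0


def test_one_to_many_duplicates():
    expr = pd.DataFrame([[5.0]], columns=["H"], index=["s"])
    omap = pd.DataFrame({"human_gene": ["H", "H"],
                         "mouse_gene": ["m1", "m2"]})
    out = lt.collapse_orthologs(expr, omap)
    assert out.loc["s", "m1"] == out.loc["s", "m2"] == 5.0


def test_empty_or_disjoint_map_rejected():
    expr = pd.DataFrame([[1.0]], columns=["A"], index=["s"])
    with pytest.raises(ValueError):
        lt.collapse_orthologs(expr, pd.DataFrame(
            columns=["human_gene", "mouse_gene"]))
    with pytest.raises(ValueError, match="no mapped"):
        lt.collapse_orthologs(expr, pd.DataFrame(
            {"human_gene": ["Z"], "mouse_gene": ["z"]}))


# ---------------------------------------------------------------------------
# cross-species matching
# ---------------------------------------------------------------------------

def _centroids(seed=0, n_subtypes=4, n_genes=60):
    rng = np.random.default_rng(seed)
    base = rng.normal(0, 2.0, size=(n_subtypes, n_genes))
    names = [f"sub{i}" for i in range(n_subtypes)]
    return pd.DataFrame(base, index=names,
                        columns=[f"g{j}" for j in range(n_genes)])


def test_identical_centroids_match_namesakes_with_correlation_one():
    cent = _centroids()
    match = lt.cross_species_cluster(cent, cent.copy())
    for s in cent.index:
        assert match.best_match.loc[("mmu", s), "best_match"] == s
        assert match.best_match.loc[("mmu", s), "correlation"] == \
            pytest.approx(1.0)


def test_noise_perturbed_centroids_all_match_correctly():
    cent = _centroids(seed=1)
    rng = np.random.default_rng(2)
    noisy = cent + rng.normal(0, 0.1, cent.shape)     # noise << spread
    match = lt.cross_species_cluster(cent, noisy)
    for s in cent.index:
        assert match.best_match.loc[("mmu", s), "best_match"] == s
        assert match.best_match.loc[("hsa", s), "best_match"] == s


def test_permuted_labels_recovered():
    cent = _centroids(seed=3)
    perm = ["sub2", "sub0", "sub3", "sub1"]
    renamed = cent.loc[perm]
    renamed.index = ["x0", "x1", "x2", "x3"]
    match = lt.cross_species_cluster(cent, renamed)
    for new, old in zip(["x0", "x1", "x2", "x3"], perm):
        assert match.best_match.loc[("hsa", new), "best_match"] == old


def test_constant_centroid_rejected_by_name():
    cent = _centroids(seed=4)
    bad = cent.copy()
    bad.loc["sub1"] = 7.0
    with pytest.raises(ValueError, match="sub1"):
        lt.cross_species_cluster(bad, cent)


# ---------------------------------------------------------------------------
# DEG signatures
# ---------------------------------------------------------------------------

def _bulk_counts(seed=0, n_per_group=4, n_genes=200, fold_gene=None,
                 fold=16.0):
    rng = np.random.default_rng(seed)
    base = rng.uniform(50, 500, n_genes)
    X = rng.poisson(np.tile(base, (2 * n_per_group, 1)))
    samples = [f"case{i}" for i in range(n_per_group)] + \
              [f"ctrl{i}" for i in range(n_per_group)]
    counts = pd.DataFrame(X, index=samples,
                          columns=[f"g{j:03d}" for j in range(n_genes)])
    if fold_gene is not None:
        assert fold_gene in counts.columns
        counts.loc[counts.index[:n_per_group], fold_gene] = rng.poisson(
            base[int(fold_gene[1:])] * fold, n_per_group)
    groups = pd.Series(["case"] * n_per_group + ["ctrl"] * n_per_group,
                       index=samples)
    return counts, groups


def test_identical_groups_give_empty_signature():
    counts, groups = _bulk_counts(seed=5)
    sig = lt.deg_signature(counts, groups, "case", "ctrl", lfc_cutoff=3.0)
    assert sig.genes == []


def test_sixteen_fold_gene_alone_passes_lfc_three():
    counts, groups = _bulk_counts(seed=6, fold_gene="g010", fold=16.0)
    sig = lt.deg_signature(counts, groups, "case", "ctrl", lfc_cutoff=3.0)
    assert sig.genes == ["g010"]
    assert (sig.table.loc["g010", "log2fc"] > 3.0)


def test_single_sample_group_rejected():
    counts, groups = _bulk_counts()
    groups.iloc[1:4] = "other"
    with pytest.raises(ValueError, match="2 samples"):
        lt.deg_signature(counts, groups, "case", "ctrl")


# ---------------------------------------------------------------------------
# survival: KM, log-rank, cutpoint
# ---------------------------------------------------------------------------

def cohort_frame(times, events, scores=None):
    n = len(times)
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "time_days": times, "event": events,
        "score": scores if scores is not None else np.zeros(n)})


def test_km_no_events_stays_at_one():
    c = cohort_frame([5, 8, 12], [0, 0, 0])
    km = lt.km_estimate(c)
    assert (km["survival"] == 1.0).all()


def test_km_single_event_drops_to_zero():
    km = lt.km_estimate(cohort_frame([5.0], [1]))
    assert km.loc[km["time"] == 5.0, "survival"].iloc[0] == 0.0
    assert km["survival"].iloc[0] == 1.0


def test_km_matches_hand_computed_four_patient_product():
    """Events at t=2 (4 at risk) and t=5 (2 at risk), censor at t=3:
    S(2) = 3/4, S(5) = 3/4 * 1/2 = 3/8."""
    c = cohort_frame([2.0, 3.0, 5.0, 6.0], [1, 0, 1, 0])
    km = lt.km_estimate(c)
    lookup = dict(zip(km["time"], km["survival"]))
    assert lookup[2.0] == pytest.approx(0.75)
    assert lookup[5.0] == pytest.approx(0.375)


def test_km_non_increasing_and_matches_empirical_without_censoring():
    rng = np.random.default_rng(7)
    times = rng.exponential(100, 40).round(1)
    c = cohort_frame(times, np.ones(40, dtype=int))
    km = lt.km_estimate(c)
    assert (np.diff(km["survival"]) <= 1e-12).all()
    for t, s in zip(km["time"], km["survival"]):
        assert s == pytest.approx((times > t).mean(), abs=1e-9)


def brute_force_logrank(cohort, labels):
    """Risk-table oracle: O-E and hypergeometric variance summed over
    event times."""
    t = cohort["time_days"].to_numpy()
    d = cohort["event"].to_numpy()
    g = (labels == labels.unique()[0]).to_numpy()
    obs_minus_exp, var = 0.0, 0.0
    for tj in np.unique(t[d == 1]):
        at_risk = t >= tj
        n = at_risk.sum()
        n1 = (at_risk & g).sum()
        dj = ((t == tj) & (d == 1)).sum()
        d1 = ((t == tj) & (d == 1) & g).sum()
        obs_minus_exp += d1 - dj * n1 / n
        if n > 1:
            var += dj * (n1 / n) * (1 - n1 / n) * (n - dj) / (n - 1)
    return obs_minus_exp ** 2 / var


def test_logrank_duplicated_cohort_is_null():
    c = cohort_frame([3, 6, 9, 12], [1, 1, 0, 1])
    doubled = pd.concat([c, c], ignore_index=True)
    labels = pd.Series(["a"] * 4 + ["b"] * 4)
    stat, p = lt.logrank_test(doubled, labels)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_risk_table_oracle():
    c = cohort_frame([6, 7, 10, 15, 19, 25], [1, 1, 0, 1, 1, 1])
    labels = pd.Series(["a", "b", "a", "b", "a", "b"])
    stat, p = lt.logrank_test(c, labels)
    assert stat == pytest.approx(brute_force_logrank(c, labels), rel=1e-9)


def test_logrank_invariant_under_monotone_time_transform():
    rng = np.random.default_rng(8)
    c = cohort_frame(rng.exponential(50, 30).round(2),
                     rng.integers(0, 2, 30))
    labels = pd.Series(np.where(np.arange(30) % 2 == 0, "a", "b"))
    s1, _ = lt.logrank_test(c, labels)
    c2 = c.copy()
    c2["time_days"] = np.sqrt(c2["time_days"])      # strictly monotone
    s2, _ = lt.logrank_test(c2, labels)
    assert s1 == pytest.approx(s2, rel=1e-9)


def test_logrank_empty_group_rejected():
    c = cohort_frame([1, 2], [1, 1])
    with pytest.raises(ValueError):
        lt.logrank_test(c, pd.Series(["a", "a"]))


def test_cutpoint_separating_fixture_lands_between_ranges():
    """Low scores: early events.  High scores: late censoring.  The cut
    must fall strictly between the two score ranges."""
    times = [5, 6, 7, 8, 9, 200, 210, 220, 230, 240]
    events = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
    scores = [0.1, 0.2, 0.3, 0.35, 0.4, 2.0, 2.1, 2.2, 2.3, 2.4]
    c = cohort_frame(times, events, scores)
    cut = lt.survival_cutpoint(c, minprop=0.2)
    assert 0.4 < cut < 2.0


def test_cutpoint_minprop_half_allows_only_median_split():
    rng = np.random.default_rng(9)
    scores = np.arange(20) / 10.0
    c = cohort_frame(rng.exponential(100, 20).round(1),
                     rng.integers(0, 2, 20), scores)
    cut = lt.survival_cutpoint(c, minprop=0.5)
    assert cut == pytest.approx((scores[9] + scores[10]) / 2)


def test_cutpoint_identical_scores_rejected():
    c = cohort_frame(np.arange(1, 13), [1] * 12, np.ones(12))
    with pytest.raises(ValueError, match="identical"):
        lt.survival_cutpoint(c)


def test_stratify_survival_flags_exploratory_p():
    spec = syn.SurvivalSpec(n_patients=80, log_hazard_ratio=1.5,
                            censoring_rate=0.2)
    cohort = lt.simulate_survival_cohort(spec, seed=3)
    strat = lt.stratify_survival(cohort)
    assert strat["p_is_exploratory"] is True
    assert strat["logrank_p"] < 0.05
    assert strat["n_high"] + strat["n_low"] == len(cohort)
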