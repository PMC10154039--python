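"""Principal-curve pseudotime, dynamic-gene test, gene sets and TPS."""

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from scipy.stats import spearmanr

import leukotraj as lt
from leukotraj import trajectory as tj


def line_embedding(n=300, noise=0.0, seed=0, n_clusters=5):
    """Cells along a straight segment with ordered cluster labels."""
    rng = np.random.default_rng(seed)
    t = np.sort(rng.random(n))
    pts = np.column_stack([t * 10.0, np.zeros(n)])
    pts += rng.normal(0, noise, pts.shape)
    emb = pd.DataFrame(pts, index=[f"c{i}" for i in range(n)],
                       columns=["d1", "d2"])
    clusters = pd.Series(np.minimum((t * n_clusters).astype(int),
                                    n_clusters - 1),
                         index=emb.index)
    return emb, clusters, t


def test_straight_line_pseudotime_matches_position():
    emb, clusters, t = line_embedding()
    fit = lt.fit_lineage_curve(emb, clusters, root=0, terminals={"lin": 4})
    pt = fit.lineage_pseudotime("lin")
    rho = spearmanr(pt.to_numpy(), t).statistic
    assert rho > 0.99          # ties from the 300-point discretization
    np.testing.assert_allclose(pt.to_numpy(), t, atol=0.02)
    assert fit.curves["lin"].shape == (300, 2)


def test_reversed_ends_reverse_pseudotime():
    emb, clusters, _ = line_embedding()
    fw = lt.fit_lineage_curve(emb, clusters, root=0, terminals={"lin": 4})
    bw = lt.fit_lineage_curve(emb, clusters, root=4, terminals={"lin": 0})
    np.testing.assert_allclose(fw.lineage_pseudotime("lin").to_numpy(),
                               1.0 - bw.lineage_pseudotime("lin").to_numpy(),
                               atol=0.02)


def test_pseudotime_invariant_to_rotation():
    emb, clusters, _ = line_embedding(noise=0.3, seed=2)
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    rotated = pd.DataFrame(emb.to_numpy() @ R.T, index=emb.index,
                           columns=emb.columns)
    f1 = lt.fit_lineage_curve(emb, clusters, root=0, terminals={"lin": 4})
    f2 = lt.fit_lineage_curve(rotated, clusters, root=0, terminals={"lin": 4})
    np.testing.assert_allclose(f1.lineage_pseudotime("lin").to_numpy(),
                               f2.lineage_pseudotime("lin").to_numpy(),
                               atol=1e-6)


def test_disconnected_or_missing_cluster_rejected():
    emb, clusters, _ = line_embedding()
    with pytest.raises(ValueError, match="absent"):
        lt.fit_lineage_curve(emb, clusters, root=0, terminals={"lin": 99})


def test_bifurcation_recovers_latent_pseudotime():
    """On the full-scale synthetic bifurcation, fitted and latent
    pseudotime agree (Spearman >= 0.9 per lineage)."""
    adata, truth = lt.simulate_bifurcation(lt.SimulationConfig(seed=1))
    filtered, _ = lt.filter_cells_genes(adata)
    expr = lt.normalize_log2(filtered)
    from leukotraj.pipeline import embed_and_cluster, identify_anchor_clusters
    embedding, clusters = embed_and_cluster(expr, n_hvg=1000, n_clusters=8,
                                            seed=0)
    root, terminals = identify_anchor_clusters(
        expr, embedding, clusters,
        root_marker=(expr.obs["time_point"] == "T0").astype(float),
        diff_markers=[g for g in truth.program_genes("differentiation")
                      if g in expr.var_names],
        transf_markers=[g for g in truth.program_genes("leukemia")
                        if g in expr.var_names])
    fit = lt.fit_lineage_curve(embedding, clusters, root, terminals)
    for lin in ("differentiation", "transformation"):
        members = fit.members(lin)
        # compare against latent time on cells truly on this lineage
        truly = [c for c in members
                 if truth.lineage[c] in (lin, "trunk")]
        rho = spearmanr(fit.pseudotime.loc[truly, lin],
                        truth.pseudotime.loc[truly]).statistic
        assert rho >= 0.9, f"{lin}: rho={rho:.3f}"


# ---------------------------------------------------------------------------
# dynamic genes
# ---------------------------------------------------------------------------

def fit_from_pseudotime(pt: pd.Series, lineage="lin") -> tj.TrajectoryFit:
    frame = pd.DataFrame({lineage: pt})
    return tj.TrajectoryFit(
        lineage=pd.Series(lineage, index=pt.index),
        pseudotime=frame, curves={})


def test_constant_gene_is_flat_with_p_one():
    rng = np.random.default_rng(0)
    n = 150
    pt = pd.Series(np.sort(rng.random(n)),
                   index=[f"c{i}" for i in range(n)])
    X = np.column_stack([np.full(n, 3.0),
                         pt.to_numpy() + rng.normal(0, 0.05, n)])
    expr = AnnData(X=X, obs=pd.DataFrame(index=pt.index),
                   var=pd.DataFrame(index=["const", "rising"]))
    res = lt.pseudotime_dynamic_genes(expr, fit_from_pseudotime(pt), "lin")
    assert res.loc["const", "p"] == 1.0
    assert res.loc["const", "direction"] == "flat"
    assert res.loc["rising", "q"] < 0.05
    assert res.loc["rising", "direction"] == "up"


def test_descending_gene_detected_as_down():
    rng = np.random.default_rng(1)
    n = 200
    pt = pd.Series(np.sort(rng.random(n)),
                   index=[f"c{i}" for i in range(n)])
    noise = rng.normal(1.0, 0.1, size=(n, 20))
    X = np.column_stack([2.0 - 1.5 * pt.to_numpy() + rng.normal(0, 0.1, n),
                         noise])
    expr = AnnData(X=X, obs=pd.DataFrame(index=pt.index),
                   var=pd.DataFrame(index=["falling"]
                                    + [f"noise{j}" for j in range(20)]))
    res = lt.pseudotime_dynamic_genes(expr, fit_from_pseudotime(pt), "lin")
    assert res.loc["falling", "direction"] == "down"
    assert (res.loc[res.index != "falling", "direction"] == "flat").sum() >= 19


def test_permuted_pseudotime_keeps_null_calibrated():
    """With pseudotime shuffled against expression, at most ~5% of truly
    flat genes reach q < 0.05."""
    rng = np.random.default_rng(2)
    n, g = 200, 300
    pt = pd.Series(rng.permutation(np.linspace(0, 1, n)),
                   index=[f"c{i}" for i in range(n)])
    X = rng.normal(1.0, 0.3, size=(n, g))
    expr = AnnData(X=X, obs=pd.DataFrame(index=pt.index),
                   var=pd.DataFrame(index=[f"g{j}" for j in range(g)]))
    res = lt.pseudotime_dynamic_genes(expr, fit_from_pseudotime(pt), "lin")
    assert (res["q"] < 0.05).mean() <= 0.05


def test_too_few_cells_rejected():
    pt = pd.Series(np.linspace(0, 1, 50), index=[f"c{i}" for i in range(50)])
    expr = AnnData(X=np.ones((50, 2)), obs=pd.DataFrame(index=pt.index),
                   var=pd.DataFrame(index=["a", "b"]))
    with pytest.raises(ValueError, match="fewer than 100"):
        lt.pseudotime_dynamic_genes(expr, fit_from_pseudotime(pt), "lin")


# ---------------------------------------------------------------------------
# gene sets and the tipping-point signature
# ---------------------------------------------------------------------------

def result_frame(directions: dict, q_sig=0.01, q_flat=0.9) -> pd.DataFrame:
    rows = []
    for gene, d in directions.items():
        sig = d != "flat"
        rows.append({"gene": gene, "statistic": 5.0 if sig else 0.1,
                     "p": 0.001 if sig else 0.9,
                     "q": q_sig if sig else q_flat,
                     "delta": {"up": 1.0, "down": -1.0, "flat": 0.0}[d],
                     "direction": d})
    return pd.DataFrame(rows).set_index("gene")


def test_classify_gene_sets_definitions():
    diff = result_frame({"a": "up", "b": "down", "c": "flat", "d": "up"})
    transf = result_frame({"a": "up", "b": "up", "c": "down", "d": "flat"})
    sets = lt.classify_gene_sets(diff, transf, q_threshold=0.05)
    assert sets.set1 == {"a", "d"}
    assert sets.set2 == {"b"}
    assert sets.set3 == {"c"}
    assert sets.set4 == {"a", "b"}
    # a gene up in both lineages sits in set1 and set4, nowhere else
    assert "a" in sets.set1 and "a" in sets.set4
    assert "a" not in sets.set2 and "a" not in sets.set3


def test_no_significant_genes_gives_empty_sets():
    diff = result_frame({"a": "flat", "b": "flat"})
    transf = result_frame({"a": "flat", "b": "flat"})
    sets = lt.classify_gene_sets(diff, transf)
    assert sets.set1 == sets.set2 == sets.set3 == sets.set4 == set()


def test_mismatched_gene_universe_rejected():
    diff = result_frame({"a": "up"})
    transf = result_frame({"b": "up"})
    with pytest.raises(ValueError, match="universe"):
        lt.classify_gene_sets(diff, transf)


def test_tps_is_set2_intersect_set4():
    sets = tj.LineageGeneSets(set1=set(), set2={"a", "b", "c"},
                              set3=set(), set4={"b", "c", "d"})
    tps = lt.tipping_point_signature(sets)
    assert tps.genes == {"b", "c"}
    assert tps.genes <= sets.set2 and tps.genes <= sets.set4


def test_disjoint_sets_give_empty_tps_with_warning():
    sets = tj.LineageGeneSets(set1=set(), set2={"a"}, set3=set(), set4={"b"})
    with pytest.warns(UserWarning, match="empty"):
        tps = lt.tipping_point_signature(sets)
    assert tps.genes == set()
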