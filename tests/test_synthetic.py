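"""Generator contracts: determinism, validity, planted structure."""

import numpy as np
import pandas as pd
import pytest

import leukotraj as lt
from leukotraj import io as io_mod
from leukotraj import synthetic as syn


def test_same_seed_is_byte_identical(small_config):
    a1, t1 = lt.simulate_bifurcation(small_config)
    a2, t2 = lt.simulate_bifurcation(small_config)
    np.testing.assert_array_equal(np.asarray(a1.X), np.asarray(a2.X))
    pd.testing.assert_series_equal(t1.pseudotime, t2.pseudotime)
    pd.testing.assert_series_equal(t1.lineage, t2.lineage)


def test_counts_are_nonnegative_integers(small_dataset):
    adata, _ = small_dataset
    X = np.asarray(adata.X)
    assert X.min() >= 0
    assert np.issubdtype(X.dtype, np.integer)


def test_truth_tps_is_planted_down_diff_and_up_transf(small_dataset):
    _, truth = small_dataset
    assert set(truth.tps_genes) == set(truth.program_genes("tps"))
    for g in truth.tps_genes:
        info = next(v for v in truth.programs.values() if g in v["genes"])
        assert info["directions"] == {"differentiation": "down",
                                      "transformation": "up"}


def test_trunk_cells_precede_branch_point(small_dataset, small_config):
    _, truth = small_dataset
    trunk = truth.lineage == "trunk"
    assert (truth.pseudotime[trunk] <= small_config.branch_point).all()
    assert (truth.pseudotime[~trunk] > small_config.branch_point).all()


def test_planted_trend_moves_group_means(small_dataset):
    """Tipping genes fall along differentiation and rise along
    transformation between early and late pseudotime."""
    adata, truth = small_dataset
    expr = lt.normalize_log2(adata)
    tps = [g for g in truth.tps_genes if g in expr.var_names]
    vals = pd.DataFrame(np.asarray(expr[:, tps].X), index=expr.obs_names)
    pt = truth.pseudotime
    for lin, rising in (("transformation", True), ("differentiation", False)):
        cells = truth.lineage[truth.lineage == lin].index
        late = vals.loc[[c for c in cells if pt[c] > 0.8]].mean().mean()
        early = vals.loc[truth.lineage[truth.lineage == "trunk"].index].mean().mean()
        assert (late > early) == rising


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.4])
def test_branch_point_outside_unit_interval_rejected(bad):
    cfg = lt.SimulationConfig(branch_point=bad)
    with pytest.raises(ValueError):
        cfg.validate()


def test_empty_program_list_rejected():
    cfg = lt.SimulationConfig(program_specs=[])
    with pytest.raises(ValueError):
        cfg.validate()


# ---------------------------------------------------------------------------
# spliced / unspliced
# ---------------------------------------------------------------------------

def test_overlapping_induced_repressed_sets_rejected(small_dataset):
    adata, _ = small_dataset
    g = list(adata.var_names[:3])
    with pytest.raises(ValueError, match="overlap"):
        lt.simulate_spliced_unspliced(adata, g, g[:1], 1.0)


def test_steady_state_layers_track_gamma(small_dataset):
    adata, _ = small_dataset
    out = lt.simulate_spliced_unspliced(adata, [], [], gamma_true=0.5, seed=3)
    s = out.layers["spliced"].sum()
    u = out.layers["unspliced"].sum()
    assert u / s == pytest.approx(0.5, rel=0.02)
    assert out.layers["unspliced"].min() >= 0


def test_induced_genes_have_unspliced_excess(small_dataset):
    adata, _ = small_dataset
    induced = list(adata.var_names[:10])
    out = lt.simulate_spliced_unspliced(adata, induced, [], gamma_true=0.5,
                                        lead=0.5, seed=3)
    idx = out.var_names.get_indexer(induced)
    s = out.layers["spliced"][:, idx].sum()
    u = out.layers["unspliced"][:, idx].sum()
    assert u > 0.5 * s


# ---------------------------------------------------------------------------
# CNV planting
# ---------------------------------------------------------------------------

def test_copy_ratio_one_is_identity(small_dataset):
    adata, _ = small_dataset
    seg = syn.CNVSegmentSpec("chr1", 0, 20, 1.0, 0.5)
    out, malignant = lt.simulate_cnv_cells(adata, [seg], seed=1)
    np.testing.assert_array_equal(np.asarray(out.X), np.asarray(adata.X))
    assert len(malignant) == round(0.5 * adata.n_obs)


def test_copy_ratio_scales_segment_mean(small_dataset):
    adata, _ = small_dataset
    n_chr1 = int((adata.var["chromosome"] == "chr1").sum())
    seg = syn.CNVSegmentSpec("chr1", 0, n_chr1, 2.0, 0.3)
    out, malignant = lt.simulate_cnv_cells(adata, [seg], seed=1)
    chr1 = adata.var_names[adata.var["chromosome"] == "chr1"]
    aff = out.obs_names.isin(malignant)
    before = np.asarray(adata[aff, chr1].X).mean()
    after = np.asarray(out[aff, chr1].X).mean()
    assert after / before == pytest.approx(2.0, rel=0.05)
    unaff_after = np.asarray(out[~aff, chr1].X)
    np.testing.assert_array_equal(unaff_after, np.asarray(adata[~aff, chr1].X))


def test_two_disjoint_segments_elevate_independently(small_dataset):
    adata, _ = small_dataset
    segs = [syn.CNVSegmentSpec("chr1", 0, 20, 2.0, 0.2),
            syn.CNVSegmentSpec("chr2", 0, 20, 3.0, 0.2)]
    out, _ = lt.simulate_cnv_cells(adata, segs, seed=1)
    for seg, ratio in zip(segs, (2.0, 3.0)):
        genes = adata.var_names[adata.var["chromosome"] == seg.chromosome][:20]
        aff = out.obs["cnv_truth"].to_numpy()
        # pooled over both segments' cells; elevation shows in the union
        before = np.asarray(adata[:, genes].X)[aff].mean()
        after = np.asarray(out[:, genes].X)[aff].mean()
        assert after > before


def test_nonpositive_copy_ratio_rejected():
    with pytest.raises(ValueError):
        syn.CNVSegmentSpec("chr1", 0, 10, 0.0, 0.1).validate()


# ---------------------------------------------------------------------------
# junction counts
# ---------------------------------------------------------------------------

def test_psi_one_gives_zero_exclusion():
    spec = [syn.SpliceEventSpec(f"e{i}", 1.0, 50) for i in range(20)]
    tab = lt.simulate_junction_counts(spec, ["a"], seed=0)
    assert (tab["E"] == 0).all()


def test_psi_zero_gives_zero_inclusion():
    spec = [syn.SpliceEventSpec(f"e{i}", 0.0, 50) for i in range(20)]
    tab = lt.simulate_junction_counts(spec, ["a"], seed=0)
    assert (tab["I"] == 0).all()


def test_psi_out_of_range_rejected():
    with pytest.raises(ValueError):
        syn.SpliceEventSpec("e", 1.2, 50).validate()


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

def test_full_censoring_censors_everyone():
    spec = syn.SurvivalSpec(n_patients=50, censoring_rate=1.0)
    cohort = lt.simulate_survival_cohort(spec, seed=0)
    assert (cohort["event"] == 0).all()


def test_negative_baseline_hazard_rejected():
    with pytest.raises(ValueError):
        syn.SurvivalSpec(baseline_hazard=-1.0).validate()


def test_positive_beta_shortens_high_score_survival():
    spec = syn.SurvivalSpec(n_patients=400, log_hazard_ratio=1.5,
                            censoring_rate=0.0)
    cohort = lt.simulate_survival_cohort(spec, seed=1)
    high = cohort["score"] > cohort["score"].median()
    assert cohort.loc[high, "time_days"].median() < \
        cohort.loc[~high, "time_days"].median()


# ---------------------------------------------------------------------------
# disk round trip
# ---------------------------------------------------------------------------

def test_mtx_roundtrip(tmp_path, small_dataset):
    adata, _ = small_dataset
    out = lt.simulate_spliced_unspliced(adata, [], [], 1.0, seed=0)
    io_mod.write_10x_mtx(out, tmp_path / "d")
    back = io_mod.read_10x_mtx(tmp_path / "d")
    np.testing.assert_array_equal(np.asarray(back.X), np.asarray(out.X))
    np.testing.assert_array_equal(back.layers["unspliced"],
                                  out.layers["unspliced"])
    assert list(back.obs_names) == list(out.obs_names)
    assert list(back.var_names) == list(out.var_names)


def test_gmt_roundtrip(tmp_path):
    sigs = {"a": ["g1", "g2"], "b": ["g3"]}
    io_mod.write_gmt(sigs, tmp_path / "s.gmt")
    assert io_mod.read_gmt(tmp_path / "s.gmt") == sigs
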