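"""End-to-end orchestration: simulate -> QC -> scoring -> trajectory/TPS
-> velocity -> CNV -> splicing -> survival, from a single seeded config.

Each stage is a library call; the pipeline wires their inputs together,
logs stage parameters, and collects a JSON-serializable report:
the recovered tipping-point signature, the splicing-factor score trend
across time points, the malignant-call confusion against the planted
truth, the differential-splicing table summary, and the survival
stratification.  Stage toggles skip stages and their report blocks.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from . import cnv as cnv_mod
from . import cohort as cohort_mod
from . import qc as qc_mod
from . import scoring as scoring_mod
from . import splicing as splicing_mod
from . import synthetic as syn
from . import trajectory as traj_mod
from . import velocity as vel_mod


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str | None = None
    stages: dict = field(default_factory=lambda: {
        "qc": True, "scoring": True, "trajectory": True, "velocity": True,
        "cnv": True, "splicing": True, "survival": True})
    simulate: dict = field(default_factory=dict)   # SimulationConfig overrides
    qc: dict = field(default_factory=dict)
    scoring: dict = field(default_factory=lambda: {"nbin": 28, "nctrl": 100})
    trajectory: dict = field(default_factory=lambda: {
        "n_hvg": 1000, "n_clusters": 8, "q_threshold": 0.05})
    velocity: dict = field(default_factory=lambda: {
        "gamma": 0.5, "lead": 0.5, "quantile": 0.02, "n_neighbors": 30})
    # the planted event is chromosome-scale by default: the large CNVs
    # this approach detects in practice span whole arms, not short blocks
    cnv: dict = field(default_factory=lambda: {
        "w": 101, "clip": 3.0, "copy_ratio": 2.0, "segment_genes": 190,
        "cell_fraction": 0.1, "burden_margin": 1.5})
    # junction coverage is pseudobulk (reads pooled over a cell group)
    splicing: dict = field(default_factory=lambda: {
        "n_events": 200, "n_differential": 10, "coverage": 200,
        "delta_psi": 0.3})
    survival: dict = field(default_factory=lambda: {"minprop": 0.1})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(value, dict):
                getattr(cfg, key).update(value)
            else:
                setattr(cfg, key, value)
        return cfg


REPORT_REQUIRED = {
    "trajectory": ["tps_genes", "n_set2", "n_set4"],
    "scoring": ["sf_score_by_time"],
    "velocity": ["flow_statistic", "flow_p"],
    "cnv": ["confusion"],
    "splicing": ["n_significant_by_type"],
    "survival": ["logrank_p", "cutpoint"],
}


def validate_report(report: dict, config: PipelineConfig) -> None:
    """Check the report carries every block its enabled stages promise."""
    for stage, keys in REPORT_REQUIRED.items():
        if not config.stages.get(stage, True):
            if stage in report:
                raise ValueError(f"disabled stage {stage!r} left a block")
            continue
        block = report.get(stage)
        if block is None:
            raise ValueError(f"missing report block for stage {stage!r}")
        for k in keys:
            if k not in block:
                raise ValueError(f"report block {stage!r} misses {k!r}")


def embed_and_cluster(expr, n_hvg: int, n_clusters: int, seed: int,
                      diff_markers=None, transf_markers=None):
    """2-D embedding on highly variable genes plus k-means clusters.

    With marker gene sets for the two terminal states, the embedding is
    (z-scored PC1, z-scored marker-score contrast): the first axis tracks
    global progression, the second separates the lineages by the
    difference between the differentiation-marker and transformation-
    marker signature scores — the same marker contrast used to annotate
    the terminal populations.  Without markers it falls back to plain
    2-component PCA.
    """
    hvg = qc_mod.select_hvg(expr, n=min(n_hvg, expr.n_vars))
    X = np.asarray(expr[:, hvg].X, dtype=float)
    if diff_markers and transf_markers:
        pc1 = PCA(n_components=1, random_state=seed).fit_transform(X)[:, 0]
        contrast = (
            scoring_mod.signature_score(
                expr, scoring_mod.GeneSignature("diff_markers",
                                                list(diff_markers)))
            - scoring_mod.signature_score(
                expr, scoring_mod.GeneSignature("transf_markers",
                                                list(transf_markers)))
        ).to_numpy()

        def _z(v):
            sd = v.std()
            return (v - v.mean()) / (sd if sd > 0 else 1.0)

        emb = np.column_stack([_z(pc1), _z(contrast)])
    else:
        emb = PCA(n_components=2, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit(emb)
    embedding = pd.DataFrame(emb, index=expr.obs_names, columns=["dim1", "dim2"])
    clusters = pd.Series(km.labels_, index=expr.obs_names, name="cluster")
    return embedding, clusters


def identify_anchor_clusters(expr, embedding, clusters,
                             root_marker: pd.Series,
                             diff_markers: list, transf_markers: list):
    """Pick the root and the two terminal clusters from observable labels.

    The root is the cluster most populated by the earliest time point;
    terminals maximize the mean marker-signature score of each lineage's
    known terminal cell state (e.g. mature myeloid markers vs the
    malignant progenitor program).
    """
    t0_frac = root_marker.groupby(clusters).mean()
    root = t0_frac.idxmax()

    def _terminal(markers, taken):
        sig = scoring_mod.GeneSignature("terminal", list(markers))
        score = scoring_mod.signature_score(expr, sig)
        by_cluster = score.groupby(clusters).mean().drop(index=list(taken))
        return by_cluster.idxmax()

    diff_term = _terminal(diff_markers, {root})
    transf_term = _terminal(transf_markers, {root, diff_term})
    return root, {"differentiation": diff_term, "transformation": transf_term}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage on a synthetic dataset; return the report."""
    report: dict = {"seed": config.seed, "stages_run": []}
    sim_cfg = syn.SimulationConfig(**config.simulate, seed=config.seed)
    adata, truth = syn.simulate_bifurcation(sim_cfg)
    report["simulate"] = {
        "n_cells": int(adata.n_obs), "n_genes": int(adata.n_vars),
        "n_tps_truth": len(truth.tps_genes),
    }

    stage = "simulate"
    try:
        # ----- QC + normalization -----
        expr = None
        if config.stages.get("qc", True):
            stage = "qc"
            filtered, retention = qc_mod.filter_cells_genes(adata, **config.qc)
            expr = qc_mod.normalize_log2(filtered)
            report["qc"] = {k: int(v) for k, v in
                            retention.to_frame()["count"].items()}
        else:
            filtered = adata
            expr = qc_mod.normalize_log2(adata)

        # ----- scoring: splicing-factor trend over time -----
        if config.stages.get("scoring", True):
            stage = "scoring"
            sf_sig = scoring_mod.GeneSignature(
                "splicing_factors",
                [g for g in truth.program_genes("splicing_factors")
                 if g in expr.var_names])
            sf = scoring_mod.signature_score(expr, sf_sig)
            trend = sf.groupby(expr.obs["time_point"]).mean()
            report["scoring"] = {
                "sf_score_by_time": {k: float(v) for k, v in trend.items()},
                "sf_trend_strictly_increasing": bool(
                    np.all(np.diff(trend.loc[list(syn.TIME_POINTS)]) > 0)),
            }

        # ----- trajectory + TPS -----
        fit = None
        embedding = clusters = None
        if config.stages.get("trajectory", True):
            stage = "trajectory"
            tcfg = config.trajectory
            diff_markers = [g for g in truth.program_genes("differentiation")
                            if g in expr.var_names]
            transf_markers = [g for g in truth.program_genes("leukemia")
                              if g in expr.var_names]
            embedding, clusters = embed_and_cluster(
                expr, tcfg["n_hvg"], tcfg["n_clusters"], config.seed,
                diff_markers=diff_markers, transf_markers=transf_markers)
            root, terminals = identify_anchor_clusters(
                expr, embedding, clusters,
                root_marker=(expr.obs["time_point"] == "T0").astype(float),
                diff_markers=diff_markers,
                transf_markers=transf_markers)
            fit = traj_mod.fit_lineage_curve(embedding, clusters, root,
                                             terminals)
            res_d = traj_mod.pseudotime_dynamic_genes(
                expr, fit, "differentiation", q_threshold=tcfg["q_threshold"])
            res_t = traj_mod.pseudotime_dynamic_genes(
                expr, fit, "transformation", q_threshold=tcfg["q_threshold"])
            sets = traj_mod.classify_gene_sets(res_d, res_t,
                                               tcfg["q_threshold"])
            tps = traj_mod.tipping_point_signature(sets)
            truth_set = set(truth.tps_genes) & set(expr.var_names)
            recovered = tps.genes & truth_set
            report["trajectory"] = {
                "root_cluster": int(root),
                "tps_genes": sorted(tps.genes),
                "n_set1": len(sets.set1), "n_set2": len(sets.set2),
                "n_set3": len(sets.set3), "n_set4": len(sets.set4),
                "tps_sensitivity": (len(recovered) / len(truth_set)
                                    if truth_set else float("nan")),
                "tps_false_discoveries": len(tps.genes - truth_set),
            }

        # ----- RNA velocity -----
        if config.stages.get("velocity", True):
            stage = "velocity"
            vcfg = config.velocity
            if embedding is None:
                embedding, clusters = embed_and_cluster(
                    expr, 1000, 8, config.seed)
            induced = [g for g in truth.program_genes("leukemia")
                       if g in filtered.var_names]
            with_layers = syn.simulate_spliced_unspliced(
                filtered, induced, [], vcfg["gamma"], lead=vcfg["lead"],
                seed=config.seed + 1)
            s = pd.DataFrame(with_layers.layers["spliced"],
                             index=filtered.obs_names,
                             columns=filtered.var_names)
            u = pd.DataFrame(with_layers.layers["unspliced"],
                             index=filtered.obs_names,
                             columns=filtered.var_names)
            model = vel_mod.fit_velocity_model(
                s[induced], u[induced], quantile=vcfg["quantile"],
                embedding=embedding, n_neighbors=vcfg["n_neighbors"])
            vectors = vel_mod.velocity_vectors(
                model, embedding, np.log1p(s[model.residuals.columns]),
                n_neighbors=vcfg["n_neighbors"])
            if fit is not None:
                grp_a = [c for c in expr.obs_names
                         if fit.lineage[c] == "transformation"]
                grp_b = [c for c in expr.obs_names
                         if fit.lineage[c] == "trunk"]
            else:
                half = expr.n_obs // 2
                grp_a = list(expr.obs_names[:half])
                grp_b = list(expr.obs_names[half:])
            flow = vel_mod.flow_direction_score(
                vectors, embedding, grp_a, grp_b, n_permutations=200,
                seed=config.seed)
            report["velocity"] = {
                "n_genes_fit": int(len(model.gamma)),
                "mean_gamma": float(model.gamma.mean()),
                "flow_statistic": flow.statistic,
                "flow_p": flow.p_value,
            }

        # ----- CNV / malignant calling -----
        if config.stages.get("cnv", True):
            stage = "cnv"
            ccfg = config.cnv
            late = filtered.obs_names[filtered.obs["time_point"] == "T3"]
            early = filtered.obs_names[filtered.obs["time_point"] == "T0"]
            chrom = filtered.var["chromosome"].value_counts().idxmax()
            seg = syn.CNVSegmentSpec(
                chromosome=chrom, start_gene=10,
                n_genes=min(ccfg["segment_genes"],
                            (filtered.var["chromosome"] == chrom).sum() - 10),
                copy_ratio=ccfg["copy_ratio"],
                cell_fraction=ccfg["cell_fraction"])
            with_cnv, malignant = syn.simulate_cnv_cells(
                filtered, [seg], seed=config.seed + 2, eligible_cells=late,
                truth=truth)
            cnv_expr = qc_mod.normalize_log2(with_cnv)
            # shrink the window if no chromosome can host the default
            largest = int(filtered.var["chromosome"].value_counts().max())
            w = min(ccfg["w"], largest if largest % 2 else largest - 1)
            profile = cnv_mod.infer_cnv_profile(
                cnv_expr, reference_cells=list(early),
                w=w, clip=ccfg["clip"])
            calls = cnv_mod.call_malignant(
                profile, burden_margin=ccfg["burden_margin"])
            truth_mask = cnv_expr.obs_names.isin(malignant)
            called = calls["malignant"].to_numpy()
            tp = int((called & truth_mask).sum())
            fp = int((called & ~truth_mask).sum())
            fn = int((~called & truth_mask).sum())
            tn = int((~called & ~truth_mask).sum())
            report["cnv"] = {
                "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
                "sensitivity": tp / max(tp + fn, 1),
                "specificity": tn / max(tn + fp, 1),
            }

        # ----- splicing -----
        if config.stages.get("splicing", True):
            stage = "splicing"
            scfg = config.splicing
            rng = np.random.default_rng(config.seed + 3)
            specs = []
            for i in range(scfg["n_events"]):
                base = float(rng.uniform(0.2, 0.8))
                if i < scfg["n_differential"]:
                    hi = min(base + scfg["delta_psi"], 1.0)
                    psi = {"lo": base, "hi": hi}
                else:
                    psi = base
                specs.append(syn.SpliceEventSpec(
                    f"EV{i:04d}", psi, scfg["coverage"],
                    event_type=splicing_mod.EVENT_TYPES[i % 5]))
            table = syn.simulate_junction_counts(
                specs, ["lo", "hi"], seed=config.seed + 3, truth=truth)
            res = splicing_mod.differential_psi(
                table[table["group"] == "lo"], table[table["group"] == "hi"],
                label_a="lo", label_b="hi")
            tally = splicing_mod.count_event_types(res, 0.05, 0.1)
            report["splicing"] = {
                "n_events": int(len(res)),
                "n_significant_by_type": {k: int(v) for k, v in tally.items()},
                "n_true_differential": scfg["n_differential"],
            }

        # ----- survival -----
        if config.stages.get("survival", True):
            stage = "survival"
            cohort = syn.simulate_survival_cohort(
                sim_cfg.survival_spec, seed=config.seed + 4, truth=truth)
            strat = cohort_mod.stratify_survival(
                cohort, minprop=config.survival["minprop"])
            report["survival"] = {
                "cutpoint": float(strat["cutpoint"]),
                "n_high": strat["n_high"], "n_low": strat["n_low"],
                "logrank_chi2": float(strat["logrank_chi2"]),
                "logrank_p": float(strat["logrank_p"]),
                "p_is_exploratory": True,
            }
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    report["stages_run"] = [s for s in REPORT_REQUIRED if s in report]
    validate_report(report, config)
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1, default=str)
    return report
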