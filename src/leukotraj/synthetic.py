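"""Seeded synthetic single-cell datasets with known ground truth.

The generator emulates a serial single-cell experiment over a leukemic
transformation time course: progenitor cells sampled at four time points
(T0..T3) move along a latent pseudotime axis and, past a branch point,
commit to one of two lineages — normal *differentiation* or malignant
*transformation*.  Gene "programs" (coherent gene sets with a planted
monotone log-linear trend along one or both lineages) create the structure
that the downstream trajectory, scoring, velocity, CNV, splicing and
survival stages are expected to recover.

Everything is driven by :class:`SimulationConfig` and a single integer
seed; the same config and seed reproduce byte-identical output.  The
:class:`GroundTruth` record carries all latent quantities (pseudotime,
lineage, program membership, malignant cells, true PSI, cell-cycle phase,
survival effect) so that every downstream stage can be scored without
re-deriving anything.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from anndata import AnnData

TIME_POINTS = ("T0", "T1", "T2", "T3")
LINEAGES = ("differentiation", "transformation")


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass
class ProgramSpec:
    """A planted gene program.

    Parameters
    ----------
    name:
        Program label; gene membership is recorded under this name in the
        ground truth.
    n_genes:
        Number of member genes (assigned disjointly, in config order).
    log2_fc:
        Full-range effect size: the log2 fold change of the mean between
        the start and the end of the ramp.
    directions:
        Trend per lineage, ``{"differentiation": "up"|"down"|"flat",
        "transformation": ...}``.  Omitted lineages are flat.
    ramp:
        ``"branch"`` — the trend starts at the branch point (both lineages
        share identical means on the trunk, so the bifurcation is only
        identifiable after the branch); ``"time"`` — the trend spans the
        whole pseudotime axis (requires the same direction on both
        lineages, e.g. a splicing-factor program rising T0 to T3).
    """

    name: str
    n_genes: int
    log2_fc: float
    directions: dict = field(default_factory=dict)
    ramp: str = "branch"

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError(f"program {self.name!r}: n_genes must be positive")
        if self.ramp not in ("branch", "time"):
            raise ValueError(f"program {self.name!r}: unknown ramp {self.ramp!r}")
        for lin, d in self.directions.items():
            if lin not in LINEAGES:
                raise ValueError(f"program {self.name!r}: unknown lineage {lin!r}")
            if d not in ("up", "down", "flat"):
                raise ValueError(f"program {self.name!r}: unknown direction {d!r}")
        if self.ramp == "time":
            dirs = {d for d in self.directions.values() if d != "flat"}
            if len(dirs) > 1:
                raise ValueError(
                    f"program {self.name!r}: a time-ramp program must trend the "
                    "same way on both lineages (the trunk is shared)"
                )


@dataclass
class CNVSegmentSpec:
    """One contiguous copy-number segment planted into a fraction of cells."""

    chromosome: str
    start_gene: int          # index within the chromosome's gene list
    n_genes: int
    copy_ratio: float        # multiplicative change of the mean, > 0
    cell_fraction: float     # fraction of eligible cells affected

    def validate(self) -> None:
        if self.copy_ratio <= 0:
            raise ValueError("copy_ratio must be > 0")
        if not 0 < self.cell_fraction <= 1:
            raise ValueError("cell_fraction must be in (0, 1]")
        if self.n_genes <= 0 or self.start_gene < 0:
            raise ValueError("segment indices must be nonnegative / positive")


@dataclass
class SpliceEventSpec:
    """One alternative-splicing event with a known inclusion level.

    ``psi`` is either a single value in [0, 1] (shared by all groups) or a
    mapping from group label to PSI.  ``coverage`` is the mean number of
    junction-spanning reads per event; effective junction lengths default
    to the skipped-exon convention (two inclusion junctions, one skipping
    junction).
    """

    event_id: str
    psi: object
    coverage: float
    event_type: str = "SE"
    inclusion_length: int = 2
    exclusion_length: int = 1

    def psi_for(self, group: str) -> float:
        value = self.psi[group] if isinstance(self.psi, dict) else self.psi
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"event {self.event_id!r}: PSI {value} outside [0, 1]")
        return float(value)

    def validate(self) -> None:
        if self.coverage < 0:
            raise ValueError("coverage must be nonnegative")
        if self.inclusion_length <= 0 or self.exclusion_length <= 0:
            raise ValueError("effective lengths must be positive")
        values = self.psi.values() if isinstance(self.psi, dict) else [self.psi]
        for v in values:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"event {self.event_id!r}: PSI {v} outside [0, 1]")


@dataclass
class SurvivalSpec:
    """Exponential survival cohort with a score-dependent hazard."""

    n_patients: int = 200
    baseline_hazard: float = 1.0 / 500.0   # per day
    log_hazard_ratio: float = 1.0          # per score unit
    censoring_rate: float = 0.3

    def validate(self) -> None:
        if self.n_patients < 10:
            raise ValueError("n_patients must be at least 10")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0, 1]")


def default_programs() -> list[ProgramSpec]:
    """The default planted program set.

    * ``tps`` — the tipping-point program: down along differentiation and
      up along transformation, four-fold range.  These genes are the
      ground-truth tipping-point signature.
    * ``differentiation`` / ``stemness`` — myeloid maturation markers up,
      stem markers down, along the differentiation lineage only.
    * ``leukemia`` — malignancy program up along transformation only.
    * ``anti_tps`` — genes repressed along transformation (populates the
      "down in transformation" gene set).
    * ``splicing_factors`` — spliceosome program rising along the whole
      course on both lineages, emulating the progressive increase of
      splicing-factor expression from T0 to T3.
    """
    return [
        ProgramSpec("tps", 40, 2.0,
                    {"differentiation": "down", "transformation": "up"}),
        ProgramSpec("differentiation", 60, 1.5, {"differentiation": "up"}),
        ProgramSpec("stemness", 50, 1.5, {"differentiation": "down"}),
        ProgramSpec("leukemia", 50, 1.5, {"transformation": "up"}),
        ProgramSpec("anti_tps", 30, 1.5, {"transformation": "down"}),
        ProgramSpec("splicing_factors", 40, 1.2,
                    {"differentiation": "up", "transformation": "up"},
                    ramp="time"),
    ]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic bifurcating time course."""

    n_genes: int = 2000
    n_cells_per_stage: dict = field(
        default_factory=lambda: {"T0": 300, "T1": 400, "T2": 400, "T3": 400})
    branch_point: float = 0.25
    program_specs: list = field(default_factory=default_programs)
    nb_dispersion: float = 0.1
    library_size_mean: float = 5000.0
    library_size_sigma: float = 0.25      # lognormal sigma of library sizes
    baseline_log_mean_sigma: float = 1.0  # spread of baseline gene abundances
    mito_gene_fraction: float = 0.02
    n_chromosomes: int = 10
    # cell cycle: phase probabilities and planted phase-program strength
    phase_probs: dict = field(
        default_factory=lambda: {"G1": 0.6, "S": 0.25, "G2M": 0.15})
    n_s_genes: int = 30
    n_g2m_genes: int = 30
    cycle_log2_fc: float = 2.0
    # replicate samples per time point
    n_replicates: int = 2
    cnv_spec: list = field(default_factory=list)
    splice_spec: list = field(default_factory=list)
    survival_spec: SurvivalSpec = field(default_factory=SurvivalSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for tp, n in self.n_cells_per_stage.items():
            if tp not in TIME_POINTS:
                raise ValueError(f"unknown time point {tp!r}")
            if n <= 0:
                raise ValueError("cell counts must be positive")
        if not 0.0 < self.branch_point < 1.0:
            raise ValueError("branch_point must lie strictly inside (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive")
        if not self.program_specs:
            raise ValueError("at least one program must be specified")
        for p in self.program_specs:
            p.validate()
        # at least two programs touching each lineage keeps the branch
        # geometrically identifiable
        for lin in LINEAGES:
            n = sum(1 for p in self.program_specs
                    if p.directions.get(lin, "flat") != "flat")
            if n < 2:
                raise ValueError(
                    f"need at least 2 non-flat programs on the {lin} lineage")
        total = sum(p.n_genes for p in self.program_specs)
        total += self.n_s_genes + self.n_g2m_genes
        total += int(round(self.mito_gene_fraction * self.n_genes))
        if total > self.n_genes:
            raise ValueError("program + cycle + mito genes exceed n_genes")
        for seg in self.cnv_spec:
            seg.validate()
        for ev in self.splice_spec:
            ev.validate()
        self.survival_spec.validate()


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Latent quantities of a simulated dataset, sufficient to score every
    downstream stage."""

    pseudotime: pd.Series                  # per cell, [0, 1]
    lineage: pd.Series                     # per cell: lineage or "trunk"
    phase: pd.Series                       # per cell: G1 / S / G2M
    programs: dict                         # name -> {"genes", "directions", "ramp", "log2_fc"}
    tps_genes: list                        # planted down-diff AND up-transf genes
    malignant_cells: list = field(default_factory=list)
    cnv_segments: list = field(default_factory=list)
    psi: dict = field(default_factory=dict)        # event -> {group: psi}
    survival_beta: Optional[float] = None

    def program_genes(self, name: str) -> list:
        return list(self.programs[name]["genes"])

    def to_json(self, path) -> None:
        payload = {
            "pseudotime": self.pseudotime.to_dict(),
            "lineage": self.lineage.to_dict(),
            "phase": self.phase.to_dict(),
            "programs": self.programs,
            "tps_genes": self.tps_genes,
            "malignant_cells": self.malignant_cells,
            "cnv_segments": [asdict(s) for s in self.cnv_segments],
            "psi": self.psi,
            "survival_beta": self.survival_beta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _tps_truth(programs: dict) -> list:
    """Genes planted down along differentiation AND up along transformation."""
    down_diff, up_transf = set(), set()
    for info in programs.values():
        dirs = info["directions"]
        if dirs.get("differentiation") == "down":
            down_diff.update(info["genes"])
        if dirs.get("transformation") == "up":
            up_transf.update(info["genes"])
    return sorted(down_diff & up_transf)


# ---------------------------------------------------------------------------
# count sampling
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative binomial draw parameterized by mean and dispersion.

    var = mu + dispersion * mu^2; implemented as a gamma-Poisson mixture
    with shape r = 1/dispersion.  dispersion -> 0 degenerates to Poisson.
    """
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    lam = rng.gamma(shape=r, scale=np.maximum(mean, 1e-12) / r)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate_bifurcation(config: SimulationConfig) -> tuple[AnnData, GroundTruth]:
    """Simulate a bifurcating single-cell time course.

    Cells carry a latent pseudotime in [0, 1] tied to their time point
    (stage k occupies the k-th quarter of the axis) and a lineage label:
    cells before ``branch_point`` are trunk cells shared by both lineages;
    cells past it commit to differentiation or transformation with equal
    probability.  Program genes follow monotone log-linear mean trends
    along their lineage; counts are negative binomial on top of
    per-cell lognormal library sizes.

    Returns an :class:`anndata.AnnData` (cells x genes, raw counts in
    ``.X``) and the :class:`GroundTruth` record.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # ----- gene universe -----
    n_genes = config.n_genes
    n_mito = int(round(config.mito_gene_fraction * n_genes))
    gene_names = [f"G{i:04d}" for i in range(n_genes - n_mito)]
    gene_names += [f"mt-G{i:04d}" for i in range(n_mito)]
    mito_flag = np.array([g.startswith("mt-") for g in gene_names])

    # genomic positions: contiguous blocks per chromosome, 100 kb spacing
    per_chrom = int(np.ceil(n_genes / config.n_chromosomes))
    chrom = np.array([f"chr{i // per_chrom + 1}" for i in range(n_genes)])
    start = np.array([(i % per_chrom) * 100_000 for i in range(n_genes)])

    # program gene assignment: disjoint, scattered across the genome (a
    # regulatory program has no reason to be positionally contiguous, and
    # contiguous blocks would masquerade as copy-number segments)
    assignable = rng.permutation(n_genes - n_mito)
    cursor = 0
    programs: dict = {}
    for spec in config.program_specs:
        genes = [gene_names[i] for i in
                 np.sort(assignable[cursor:cursor + spec.n_genes])]
        cursor += spec.n_genes
        programs[spec.name] = {
            "genes": genes,
            "directions": dict(spec.directions),
            "ramp": spec.ramp,
            "log2_fc": spec.log2_fc,
        }
    s_genes = [gene_names[i] for i in
               np.sort(assignable[cursor:cursor + config.n_s_genes])]
    cursor += config.n_s_genes
    g2m_genes = [gene_names[i] for i in
                 np.sort(assignable[cursor:cursor + config.n_g2m_genes])]
    cursor += config.n_g2m_genes
    programs["cycle_s"] = {"genes": s_genes, "directions": {}, "ramp": "phase",
                           "log2_fc": config.cycle_log2_fc}
    programs["cycle_g2m"] = {"genes": g2m_genes, "directions": {},
                             "ramp": "phase", "log2_fc": config.cycle_log2_fc}

    # ----- cells -----
    stages, barcodes, samples = [], [], []
    for tp in TIME_POINTS:
        n = config.n_cells_per_stage.get(tp, 0)
        for i in range(n):
            stages.append(tp)
            rep = i % config.n_replicates
            samples.append(f"{tp}{'ab'[rep] if config.n_replicates == 2 else rep}")
    n_cells = len(stages)
    barcodes = [f"cell{i:05d}" for i in range(n_cells)]
    stage_idx = np.array([TIME_POINTS.index(tp) for tp in stages])

    # latent pseudotime: stage k uniform on [k/4, (k+1)/4]
    pt = (stage_idx + rng.random(n_cells)) / len(TIME_POINTS)
    post_branch = pt > config.branch_point
    lineage = np.where(post_branch,
                       rng.choice(LINEAGES, size=n_cells),
                       "trunk").astype(object)

    phase_names = list(config.phase_probs)
    phase_p = np.array([config.phase_probs[p] for p in phase_names])
    phase = rng.choice(phase_names, size=n_cells, p=phase_p / phase_p.sum())

    # ----- mean model -----
    base = rng.lognormal(mean=0.0, sigma=config.baseline_log_mean_sigma,
                         size=n_genes)
    log2_shift = np.zeros((n_cells, n_genes))
    gene_index = {g: i for i, g in enumerate(gene_names)}
    bp = config.branch_point
    ramp_branch = np.clip((pt - bp) / (1.0 - bp), 0.0, 1.0)
    ramp_time = pt

    for spec in config.program_specs:
        cols = [gene_index[g] for g in programs[spec.name]["genes"]]
        if spec.ramp == "time":
            # shared trend over the whole axis, applied once to every cell
            dirs = {d for d in spec.directions.values() if d != "flat"}
            if not dirs:
                continue
            sign = 1.0 if dirs.pop() == "up" else -1.0
            log2_shift[:, cols] += (sign * spec.log2_fc * ramp_time)[:, None]
            continue
        for lin, direction in spec.directions.items():
            if direction == "flat":
                continue
            sign = 1.0 if direction == "up" else -1.0
            on_lineage = (lineage == lin) | (lineage == "trunk")
            shift = sign * spec.log2_fc * ramp_branch[on_lineage]
            log2_shift[np.ix_(on_lineage, cols)] += shift[:, None]

    for prog, genes in (("cycle_s", s_genes), ("cycle_g2m", g2m_genes)):
        cols = [gene_index[g] for g in genes]
        in_phase = phase == ("S" if prog == "cycle_s" else "G2M")
        log2_shift[np.ix_(in_phase, cols)] += config.cycle_log2_fc

    weights = base[None, :] * np.exp2(log2_shift)
    weights /= weights.sum(axis=1, keepdims=True)
    lib = rng.lognormal(mean=np.log(config.library_size_mean),
                        sigma=config.library_size_sigma, size=n_cells)
    mean = weights * lib[:, None]
    counts = _nb_sample(rng, mean, config.nb_dispersion)

    obs = pd.DataFrame({
        "sample": samples,
        "time_point": stages,
        "reporter": "pos",
    }, index=pd.Index(barcodes, name="barcode"))
    var = pd.DataFrame({
        "chromosome": chrom,
        "start": start,
        "mito": mito_flag,
    }, index=pd.Index(gene_names, name="gene"))
    adata = AnnData(X=counts.astype(np.int64), obs=obs, var=var)

    truth = GroundTruth(
        pseudotime=pd.Series(pt, index=barcodes, name="pseudotime"),
        lineage=pd.Series(lineage, index=barcodes, name="lineage"),
        phase=pd.Series(phase, index=barcodes, name="phase"),
        programs=programs,
        tps_genes=_tps_truth(programs),
        survival_beta=None,
    )
    return adata, truth


# ---------------------------------------------------------------------------
# spliced / unspliced layers
# ---------------------------------------------------------------------------

def simulate_spliced_unspliced(adata: AnnData,
                               induced_genes,
                               repressed_genes,
                               gamma_true,
                               lead: float = 0.5,
                               seed: int = 0) -> AnnData:
    """Attach ``spliced`` and ``unspliced`` layers to a count matrix.

    Steady-state genes satisfy E[u] = gamma * E[s].  Induced and repressed
    genes deviate the way a transcriptional burst does in the u-s phase
    portrait: cells at the extremes of spliced expression (those just
    starting or just completing the transition — the cells an extreme-
    quantile fit anchors on) sit on the steady-state line, while cells in
    between carry an unspliced excess (induction) or deficit (repression)
    that peaks at mid expression:

        E[u | s] = gamma * s * (1 +/- lead * sin(pi * q_s))

    with q_s the cell's quantile of s for that gene.  ``lead`` in [0, 1]
    scales the peak fractional deviation.

    ``gamma_true`` is a scalar or a per-gene mapping/array of positive
    steady-state ratios.
    """
    induced = set(induced_genes)
    repressed = set(repressed_genes)
    if induced & repressed:
        raise ValueError("induced and repressed gene sets overlap")
    unknown = (induced | repressed) - set(adata.var_names)
    if unknown:
        raise ValueError(f"genes not in matrix: {sorted(unknown)[:5]}")
    if not 0.0 <= lead <= 1.0:
        raise ValueError("lead must be in [0, 1]")

    rng = np.random.default_rng(seed)
    s = np.asarray(adata.X, dtype=float)
    n_cells, n_genes = s.shape
    gamma = np.empty(n_genes)
    if np.isscalar(gamma_true):
        gamma[:] = float(gamma_true)
    elif isinstance(gamma_true, dict):
        gamma[:] = np.nan
        for g, v in gamma_true.items():
            gamma[adata.var_names.get_loc(g)] = v
    else:
        gamma[:] = np.asarray(gamma_true, dtype=float)
    if np.any(~(gamma > 0)):
        raise ValueError("gamma_true must be positive for every gene")

    u_mean = gamma[None, :] * s

    def _bump(j: int) -> np.ndarray:
        # quantile of s within the gene, mid-ranked cells get the peak
        order = np.argsort(np.argsort(s[:, j], kind="stable"))
        q = (order + 0.5) / n_cells
        return np.sin(np.pi * q)

    for g in induced:
        j = adata.var_names.get_loc(g)
        u_mean[:, j] = gamma[j] * s[:, j] * (1.0 + lead * _bump(j))
    for g in repressed:
        j = adata.var_names.get_loc(g)
        u_mean[:, j] = gamma[j] * s[:, j] * np.maximum(1.0 - lead * _bump(j), 0.0)

    out = adata.copy()
    out.layers["spliced"] = s.astype(np.int64)
    out.layers["unspliced"] = rng.poisson(u_mean).astype(np.int64)
    out.var["velocity_state"] = [
        "induced" if g in induced else "repressed" if g in repressed
        else "steady" for g in adata.var_names]
    out.var["gamma_true"] = gamma
    return out


# ---------------------------------------------------------------------------
# CNV planting
# ---------------------------------------------------------------------------

def simulate_cnv_cells(adata: AnnData,
                       cnv_spec: list,
                       seed: int = 0,
                       eligible_cells=None,
                       truth: Optional[GroundTruth] = None
                       ) -> tuple[AnnData, list]:
    """Plant copy-number segments into a random subset of cells.

    For each segment, ``cell_fraction`` of the eligible cells have their
    counts over the segment genes rescaled by ``copy_ratio`` and
    re-sampled (Poisson around the scaled value, so the mean scales
    exactly).  A ratio of 1 leaves counts untouched.  Returns the modified
    matrix and the list of affected cell barcodes (union over segments);
    the list is also appended to ``truth`` when given.
    """
    out = adata.copy()
    counts = np.asarray(out.X, dtype=float)
    rng = np.random.default_rng(seed)
    eligible = list(eligible_cells) if eligible_cells is not None \
        else list(adata.obs_names)
    affected_all: set = set()

    for seg in cnv_spec:
        seg.validate()
        on_chrom = out.var.index[out.var["chromosome"] == seg.chromosome]
        if len(on_chrom) == 0:
            raise ValueError(f"no genes on chromosome {seg.chromosome!r}")
        order = np.argsort(out.var.loc[on_chrom, "start"].to_numpy())
        ordered = on_chrom[order]
        if seg.start_gene + seg.n_genes > len(ordered):
            raise ValueError(
                f"segment exceeds {seg.chromosome}: "
                f"{seg.start_gene}+{seg.n_genes} > {len(ordered)} genes")
        seg_genes = ordered[seg.start_gene:seg.start_gene + seg.n_genes]
        n_aff = int(round(seg.cell_fraction * len(eligible)))
        affected = rng.choice(eligible, size=n_aff, replace=False)
        affected_all.update(affected)
        if seg.copy_ratio == 1.0:
            continue
        rows = out.obs_names.get_indexer(affected)
        cols = out.var_names.get_indexer(seg_genes)
        block = counts[np.ix_(rows, cols)] * seg.copy_ratio
        counts[np.ix_(rows, cols)] = rng.poisson(block)

    out.X = counts.astype(np.int64)
    malignant = sorted(affected_all)
    out.obs["cnv_truth"] = out.obs_names.isin(malignant)
    if truth is not None:
        truth.malignant_cells = malignant
        truth.cnv_segments = list(cnv_spec)
    return out, malignant


# ---------------------------------------------------------------------------
# junction counts
# ---------------------------------------------------------------------------

def simulate_junction_counts(splice_spec: list,
                             group_labels,
                             seed: int = 0,
                             truth: Optional[GroundTruth] = None
                             ) -> pd.DataFrame:
    """Simulate per-group junction count tables for splice events.

    For each event and group, the number of junction-spanning reads is
    Poisson around the event's mean coverage; each read supports inclusion
    with probability ``psi*lI / (psi*lI + (1-psi)*lE)`` — inclusion is
    favoured in proportion to both the true PSI and the number of
    inclusion junctions.  Returns a tidy table with columns
    ``event_id, type, group, I, E, lI, lE``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    psi_truth: dict = {}
    for ev in splice_spec:
        ev.validate()
        psi_truth[ev.event_id] = {}
        for group in group_labels:
            psi = ev.psi_for(group)
            psi_truth[ev.event_id][group] = psi
            n_reads = rng.poisson(ev.coverage)
            li, le = ev.inclusion_length, ev.exclusion_length
            denom = psi * li + (1.0 - psi) * le
            q = (psi * li / denom) if denom > 0 else 0.0
            inc = rng.binomial(n_reads, q) if n_reads > 0 else 0
            rows.append({"event_id": ev.event_id, "type": ev.event_type,
                         "group": group, "I": inc, "E": n_reads - inc,
                         "lI": li, "lE": le})
    if truth is not None:
        truth.psi = psi_truth
    table = pd.DataFrame(rows)
    table.attrs["psi_truth"] = psi_truth
    return table


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

def simulate_survival_cohort(survival_spec: SurvivalSpec,
                             scores=None,
                             seed: int = 0,
                             truth: Optional[GroundTruth] = None
                             ) -> pd.DataFrame:
    """Simulate a survival cohort with a score-proportional hazard.

    Event times are exponential with hazard ``baseline * exp(beta *
    score)``.  Censoring is independent of the score: each patient is
    censored with probability ``censoring_rate``, at a time uniform on
    (0, T).  ``scores`` defaults to standard-normal draws.

    Returns a table with columns ``patient_id, time_days, event, score``.
    """
    survival_spec.validate()
    rng = np.random.default_rng(seed)
    n = survival_spec.n_patients
    if scores is None:
        scores = rng.standard_normal(n)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (n,):
        raise ValueError(f"scores must have length {n}")
    hazard = survival_spec.baseline_hazard * np.exp(
        survival_spec.log_hazard_ratio * scores)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < survival_spec.censoring_rate
    time = np.where(censored, rng.random(n) * t_event, t_event)
    cohort = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "time_days": np.maximum(time, 1e-6),
        "event": (~censored).astype(int),
        "score": scores,
    })
    if truth is not None:
        truth.survival_beta = survival_spec.log_hazard_ratio
    cohort.attrs["beta_true"] = survival_spec.log_hazard_ratio
    return cohort
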