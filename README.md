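# leukotraj

Analysis toolkit for studying **stepwise leukemogenesis** in single-cell
transcriptomes: the gradual transformation of hematopoietic stem and
progenitor cells (HSPCs) into leukemic cells across a sampled time course
(T0–T3), with a fate-determining *tipping point* at which progenitors
either differentiate normally (toward granulocyte–monocyte progenitors,
GMPs) or commit to a malignant GMP-like state.

The package is aimed at computational biologists who want to run — and
*validate* — this style of analysis end to end. Every stage can be
exercised on seeded synthetic data with a full ground-truth record, so
sensitivity, false-discovery rates and calibration are measurable rather
than assumed.

## What it does

- **Synthetic data with ground truth** (`leukotraj.synthetic`) — a
  negative-binomial single-cell count simulator with a shared trunk that
  bifurcates into a differentiation and a transformation lineage, planted
  monotone gene programs, cell-cycle phase programs, spliced/unspliced
  layers, copy-number segments, binomial junction counts, and a survival
  cohort with a score-dependent hazard.
- **QC and normalization** (`leukotraj.qc`) — cell retention by detected
  genes (200–6,000, inclusive) and mitochondrial UMI fraction (strictly
  < 10%), gene retention by detection in ≥ 5 cells; `log2(1 + count ·
  scale / library)` expression; binned-dispersion highly variable gene
  selection.
- **Scoring** (`leukotraj.scoring`) — mean-log2 signature scores;
  cell-cycle S/G2M module scores against expression-matched control genes
  (28 bins, 100 controls per gene); phase assignment; and the derived
  quiescence score `G1 = −(S + G2M)/2` for non-cycling cells (0
  otherwise), with a bulk-sample z-score analogue.
- **Trajectory and tipping-point signature** (`leukotraj.trajectory`) —
  principal curves with 300 fixed points per lineage, arc-length
  pseudotime, a spline-versus-constant F test for pseudotime-dynamic
  genes with BH correction, the four direction-by-lineage gene sets, and
  the tipping-point signature **TPS = set2 ∩ set4** (down along
  differentiation *and* up along transformation).
- **RNA velocity** (`leukotraj.velocity`) — steady-state per-gene ratio
  γ from extreme-quantile regression of unspliced on spliced counts,
  residual velocities (kNN-pooled), embedding arrows, and a directed
  flow statistic between cell groups with a permutation p-value.
- **CNV and malignant calling** (`leukotraj.cnv`) — moving-average
  (101-gene window) chromosomal profiles relative to reference cells,
  hierarchical clustering, and burden-margin malignant calls.
- **Splicing** (`leukotraj.splicing`) — length-normalized percent
  spliced in, `PSI = (I/lI) / (I/lI + E/lE)`, pseudobulk differential
  inclusion between groups, and per-type tallies of SE / A3SS / A5SS /
  RI / MXE events.
- **Cohort analyses** (`leukotraj.cohort`) — ortholog collapse,
  cross-species subtype matching by Spearman-correlation clustering,
  threshold-defined DEG signatures (log2FC > 3/4/1.5 at adjusted
  p < 0.05), Kaplan–Meier curves, the chi-squared log-rank test, and the
  maximally selected survival cutpoint (whose downstream p-values are
  flagged exploratory).
- **Pipeline + CLI** (`leukotraj.pipeline`, `leukotraj` command) — one
  seeded config runs simulate → QC → scoring → trajectory/TPS →
  velocity → CNV → splicing → survival and emits a JSON report.

## Worked example

```python
import leukotraj as lt
from leukotraj.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1))
print(len(report["trajectory"]["tps_genes"]))      # 41
print(round(report["trajectory"]["tps_sensitivity"], 3))   # 0.975
print(report["scoring"]["sf_score_by_time"])
# {'T0': 1.914, 'T1': 2.133, 'T2': 2.338, 'T3': 2.548}
print(report["cnv"]["confusion"])
# {'tp': 38, 'fp': 4, 'fn': 2, 'tn': 1456}   planted vs called cells
print(f'{report["survival"]["logrank_p"]:.2e}')    # 7.85e-13 (exploratory)
```

At the default scale (2,000 genes, 1,500 cells over four time points, 40
planted tipping genes at a 4-fold range) the pipeline recovers 39 of the
40 planted tipping-point genes (sensitivity 0.975) with 2 false
discoveries; the planted splicing-factor program's signature score
rises strictly from T0 (1.91) to T3 (2.55) — the qualitative trend the
transformation course is built around; and 38 of the 40 cells carrying
the planted chromosome-scale copy-number gain are called malignant. The
full run takes well under a minute on one CPU.

The same stages run from the shell:

```bash
leukotraj simulate --out data/ --seed 1
leukotraj qc --in data/ --out filtered/
leukotraj run --seed 1 --out results/
leukotraj survival --cohort cohort.tsv --score-col score
```

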