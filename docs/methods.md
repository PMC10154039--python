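# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## The synthetic time course

The generator emulates a serial single-cell experiment over a leukemic
transformation: cells sampled at four time points (T0–T3, two replicate
samples each) carry a latent pseudotime in [0, 1], with stage *k*
occupying the *k*-th quarter of the axis. Cells past the branch point
(default 0.25, the end of T0) commit with equal probability to a
*differentiation* or a *transformation* lineage; cells before it form a
shared trunk with identical means in both lineages, so the bifurcation
is identifiable only after the branch.

Expression is a relative-abundance model: each gene has a lognormal
baseline weight (σ = 1), gene programs multiply the weight by
`2^(±log2_fc · ramp)`, weights are renormalized per cell, scaled by a
lognormal library size (default mean 5,000 UMI, σ = 0.25), and counts
drawn negative-binomial (variance `μ + φμ²`, shared dispersion
φ = 0.1). Two ramp shapes exist: *branch* ramps rise linearly from the
branch point to the lineage end (trunk flat), and *time* ramps span the
whole axis on both lineages (used for the splicing-factor program that
rises T0 → T3). Program trends are monotone log-linear — the simplest
shape consistent with monotone up/down expression along the observed
course; sigmoid alternatives would only soften the ends.

The default program set plants: a 40-gene tipping-point program (down
along differentiation, up along transformation, 4-fold range) — the
ground-truth TPS; myeloid differentiation (60 genes up) and stemness (50
genes down) programs along differentiation; a 50-gene malignancy program
and a 30-gene repressed program along transformation; and a 40-gene
splicing-factor program rising over the whole course. Cell-cycle phases
are drawn per cell (G1 0.60 / S 0.25 / G2M 0.15) and the 30-gene S and
G2M programs are elevated 4-fold in cells of their phase — cycle genes
are strongly periodic, so a strong planted effect is the realistic
condition. Program genes are scattered across the synthetic genome by a
seeded permutation: expression programs have no reason to be
positionally contiguous, and contiguous blocks would masquerade as
copy-number segments. A configurable 2% of genes are labeled
mitochondrial so the QC rules are exercisable.

What the generator does **not** emulate: ambient RNA, doublets,
batch effects beyond replicate labels, UMI saturation, discrete
transcriptional bursting, or lineage-proportion drift over time. Tests
passing on this data show the pipeline recovers planted structure under
idealized noise; they do not certify performance on real data with these
additional artifacts.

### Spliced/unspliced layers

Steady-state genes satisfy `E[u] = γ·E[s]`. Induced and repressed genes
deviate the way a transcriptional transition does in the u–s phase
portrait: the unspliced excess (or deficit) peaks at mid expression and
vanishes at both expression extremes, `E[u|s] = γ·s·(1 ± lead·sin(π·q_s))`
with `q_s` the cell's within-gene quantile of s. Cells at the extremes —
the ones an extreme-quantile fit anchors on — sit on the steady-state
line, which is exactly the geometry the estimator assumes.

### Copy-number segments, junction counts, survival cohorts

CNV segments multiply the counts of a contiguous gene block by the copy
ratio in a seeded subset of eligible cells and re-sample Poisson (a
ratio of 1 is the identity). Junction reads per event are Poisson around
the mean coverage; each read supports inclusion with probability
`ψ·lI / (ψ·lI + (1−ψ)·lE)`. Survival times are exponential with hazard
`h0 · exp(β·score)`; censoring hits each patient with the stated
probability, at a time uniform on (0, T).

## QC and normalization

Cells are filtered first (on the unfiltered gene universe), then genes
on the retained cells. The bounds on detected genes (200–6,000) are
inclusive at both ends; the mitochondrial rule is strictly `< 10%`; a
cell failing several rules is attributed to the first in the order
gene-bounds, then mito. Normalization is `log2(1 + count·scale/library)`
with scale 10,000 — the standard per-cell target for droplet data. HVG
ranking z-scores the variance/mean dispersion of log2 values within 20
equal-size bins of mean expression (removing the mean–dispersion
trend); ties break lexicographically so the ranking is deterministic.

## Scoring

The plain signature score is the mean of the log2 matrix over the
signature genes. The module score subtracts an expression-matched
background: genes are cut into `nbin = 28` equal-size bins of average
expression, and 100 control genes per signature gene are drawn (seeded)
from the signature gene's bin, excluding signature members; bins smaller
than the request are sampled with replacement and warned about. Phase is
the arg-max of (S, G2M) when positive — an exact tie goes to G2M, an
arbitrary but fixed choice — else G1, and the quiescence score is
`G1 = −(S + G2M)/2` for non-cycling cells, 0 otherwise. The printed form
of that formula renders ambiguously in some sources; the averaging of
the two scores is the only reading consistent with its use. Bulk
samples use the same combination rule on z-scores (ddof = 1) of
signature-mean TPM across samples; with fewer than two samples, or zero
variance, the z-score is undefined and the call errors.

## Trajectory, dynamic genes, and the tipping-point signature

Each lineage is a principal curve in a 2-D embedding: initialized on the
cluster-centroid path from the root cluster to the lineage's terminal
(ordered along the minimum spanning tree of centroid distances), then
iterated projection → lowess smoothing (frac 0.3) until the mean
projection distance changes by < 1e-4 relative, at most 50 rounds,
discretized to 300 fixed points. The curve is extended along its end
tangents so extreme cells project orthogonally rather than piling onto
the endpoints. Pseudotime is normalized arc length.

Cells are assigned to the lineage whose curve is nearest; cells whose
projection falls before the curves diverge (separation below the median
projection distance) are trunk, shared by all lineages. Cluster-based
assignment was tried first and rejected: clusters straddling the branch
placed hundreds of committed cells on the wrong lineage, and their
programs contaminated the other lineage's trend tests.

The pipeline's embedding is (z-scored PC1, z-scored marker contrast):
the first axis tracks global progression, the second is the difference
between the differentiation-marker and transformation-marker signature
scores — the same marker logic used to annotate the terminal
populations. A plain 2-component PCA is the fallback when no markers
are supplied, but it overlaps the branches near the bifurcation and
substantially degrades lineage assignment.

Dynamic genes: expression is regressed on pseudotime with a cubic
B-spline basis (5 degrees of freedom, interior knots at pseudotime
quantiles, one shared design for all genes) and compared to the
constant model with an F test; BH adjustment across genes. Direction is
the sign of the fitted value at the 97.5th minus the 2.5th pseudotime
percentile (the extreme cells sit in sparse curve ends), and a gene is
called directional only when that end-to-start contrast also exceeds
twice its standard error — a localized wiggle can make the F test fire
without any monotone end-to-end change, and the gene sets are defined
by the latter. Sets: set1/set2 = up/down along differentiation,
set3/set4 = down/up along transformation, at q < 0.05 (default);
**TPS = set2 ∩ set4**. The null calibration of the F test is checked
against a pseudotime independent of the expression noise; regressing on
a pseudotime derived from the same matrix is circular for any method
and is not a test of the regression's size.

Known limitation: cells just past the branch are genuinely ambiguous in
any 2-D embedding, and a minority assigned to the wrong side biases the
early part of a lineage's trend. At the default scale this keeps TPS
sensitivity ≥ 95% but lets the false-discovery proportion fluctuate
with the seed (≈ 5% typically, up to ≈ 25% in unlucky embeddings); the
false positives are almost always genes of the *other* lineage's
planted programs, not background noise.

## RNA velocity

γ per gene is fitted by regression of u on s through the origin (an
intercept is optional), restricted to cells in the lower and upper 2%
tails of s — the extreme-quantile convention of the steady-state model.
The fit always uses raw per-cell values (the anchoring depends on the
raw extremes); residual velocities `u − γs` are computed on kNN-pooled
counts (30 neighbors in the embedding) to suppress shot noise in
per-cell signs. All-zero or spread-less genes are skipped with a
diagnostic. Embedding arrows weight unit directions toward neighbors by
the cosine between the cell's residual vector and the expression change
toward that neighbor; the directed flow between groups A and B is the
mean cosine of A's arrows against the direction to B's centroid minus
the converse (antisymmetric by construction), with a label-permutation
p-value.

## CNV profiles and malignant calls

Per cell: log2 expression minus the reference-cell mean per gene,
clipped to ±3, averaged over a 101-gene moving window ordered along
each chromosome (windows never span chromosomes; chromosomes shorter
than the window are excluded with a warning), then centered at the
cell's genome-wide mean. Burden is the mean squared window value.
Cells are clustered on their profiles — Ward linkage on euclidean
distance by default — and every cluster whose mean burden exceeds 1.5×
the reference burden is called malignant; with no CNV signal no cluster
clears the margin. Average linkage with correlation distance (the more
common convention for CNV heatmaps) is available but not the default:
on noisy profiles the tight CNV-bearing group's *average* distance to
any single cell undercuts the noise-to-noise distances, so average
linkage chains it into a mixed cluster and the cut never isolates it;
Ward's variance criterion does not have this failure mode. The CNV
evaluation fixture uses 10,000-UMI libraries (a mid-depth droplet
experiment): a 100-gene 2× segment is depth-limited, and at very
shallow coverage no windowed method separates it. Inside the full
pipeline — where the profiled cells also carry trajectory-program drift
relative to the early-time reference — the planted event is
chromosome-scale by default (190 genes), matching the arm-level CNVs
the approach detects in practice; a 100-gene sub-segment at the
trajectory's 5,000-UMI depth is below its in-context detection limit.

## Splicing

`PSI = (I/lI) / (I/lI + E/lE)` with junction-count effective lengths
(lI = 2, lE = 1 for a skipped exon); missing when no reads. Rows are
pooled per event within each group (pseudobulk) and groups compared
with the chi-squared score test on the raw pooled junction counts, no
continuity correction: with effective lengths shared across groups,
equality of the raw inclusion proportion is equivalent to equality of
PSI, and the raw-count test keeps its nominal size, which a
pseudo-binomial test on non-integer normalized counts does not
guarantee. This is a deliberate simplification of the hierarchical
models used by full splicing pipelines — same null, no per-replicate
dispersion. ΔPSI is reported on the PSI scale; `skip_ratio = 1 − PSI`
is exposed for exon-skipping readouts. Event tallies count events with
q < 0.05 and |ΔPSI| ≥ 0.1 per type (SE, A3SS, A5SS, RI, MXE).

## Cohort analyses

Ortholog collapse renames 1:1 pairs, averages many:1, duplicates
1:many, and drops unmapped genes with a count. Cross-species matching
clusters the combined subtype-centroid matrix with average linkage on
1 − Spearman correlation; each subtype's best match is the most
correlated subtype of the other species; constant centroids make the
correlation undefined and error by name.

DEG signatures are threshold-defined: log2 fold change of group CPM
means (pseudocount 1) above the cutoff at BH-adjusted p below 0.05,
with p from a two-sample t test on log2(CPM+1) — a documented simple
test rather than a dispersion-shrinkage model; the reproducible part of
such signatures is the thresholds, not the test refinement.

Survival: patients with unknown follow-up or non-positive times are
removed before any fit. The Kaplan–Meier estimator and two-group
log-rank test (1 df, chi-squared upper tail, no continuity correction)
come from lifelines. The score cutpoint is the maximally selected rank
statistic with Nelson–Aalen log-rank scores: every split leaving at
least `minprop = 0.1` of patients per side is scanned, the standardized
centered low-group score sum is maximized, and ties go to the split
nearest the median score. Maximizing the plain two-sample log-rank
chi-square instead was tried and rejected — on a perfectly separated
cohort it selects an interior split. Because the cutpoint is maximally
selected, the subsequent log-rank p-value is anti-conservative; every
report carrying it sets `p_is_exploratory = true`.

## Pipeline

One seeded config drives all stages in dependency order; each stage's
block in the JSON report carries only numbers computed by that stage,
and a failed stage halts with its name. Defaults are desk-scale: 2,000
genes × 1,500 cells, 200 splice events at pseudobulk coverage 200, a
200-patient cohort; the full run takes ~15 s on one CPU. Stage seeds
are small fixed offsets from the config seed so toggling one stage off
never changes another stage's draws.
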