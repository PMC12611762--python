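# Methods

nichescope analyzes imaging-based spatial transcriptomics at single-cell
resolution: given cell centroids, cell-type labels and a gene x cell UMI
matrix, it infers which cell types preferentially colocalize and whether the
gene-program activity of a cell type covaries with that of its physical
neighbors. Because these inferences are only trustworthy if they recover
known structure, the package ships a tissue simulator with planted ground
truth, and all validation is phrased as recovery and calibration studies on
that simulator.

## Synthetic tissue model

**Placement.** Cells are placed uniformly in a disc with a minimum
pairwise separation of 8 µm (dart throwing on a background grid). The
8 µm floor reflects typical cardiac cell-packing scales and prevents
degenerate triangulations. Unless set explicitly, the tissue radius is
derived from the cell count at a density of one cell per 225 µm².

**Zones.** Concentric radial bands model the lesion anatomy: an ischemic
zone (IZ) inside the first radius, a border zone (BZ) up to the second, and
remote tissue (RZ) beyond. Defaults are 200 µm and 350 µm.

**Cell types.** Types are drawn by chromatic Gibbs sampling of a Potts-like
model on the contact graph. The conditional log-probability of type *t* for
a cell is

    log pi_z(t) + sum_u J[t, u] * f_u,

where `pi_z` is the zone's composition prior, `J` the symmetric pairwise
affinity matrix (log-odds units), and `f_u` the fraction of the cell's
contacts currently of type *u*. The affinity term is deliberately
normalized by degree: it is the inner product of `J` with the niche
composition rather than a sum over neighbors. With the unnormalized sum,
moderate affinities (|J| around 1) at contact degrees of ~6 drive the Potts
model deep into its ordered phase — simulated tissues collapse into one or
two types and rare types disappear, which no longer resembles a tissue with
a planted mixing preference. Degree normalization keeps the marginal
composition near the priors while still planting contact enrichment, and
makes the effect size independent of local packing. Updates run
color-class-by-color-class over a proper coloring of the contact graph (a
chromatic Gibbs sweep: all cells of one color update simultaneously given
fixed neighbors), 50 sweeps by default, and the final state is the sample.
This is adequate for recovery experiments; no burn-in diagnostics are
performed.

**Counts.** Gene means combine (i) a per-type base profile (flat baseline
0.5 with two 5.0 marker genes per type by default), (ii) multiplicative
gene-program contributions, and (iii) optional planted fold changes on a
gene set in a zone or type. Each type owns `n_programs_per_type` disjoint
blocks of 8 genes (base mean 1.5). A cell's contribution on its program's
genes is `0.25 + activity`, with activities drawn Gamma(shape 2, scale 1) —
non-negative and right-skewed, like NMF activities of real programs. The
small activity-independent floor makes program genes program-dominant
modules: their variance is driven by the program, which is what makes them
identifiable to factor analysis (a program that modulates its genes by a
few percent around a large constant baseline is not a recoverable program
at panel-scale counts). Planted coupling is realized before emission: for
each coupling `(central type, program i, niche type, program j, c)`, a
central cell's activity on program *i* is increased by `c` times the mean
pre-coupling activity of program *j* over its niche-type contacts. Counts
are negative binomial per gene with variance `m + phi m^2` (default
`phi = 0.2`). `reference_mode` redraws counts ignoring positions and
coupling, giving a matched dissociated reference for label-transfer tests.

What the simulator does *not* emulate: segmentation errors, cell-size and
detection-efficiency variation, spatially smooth expression gradients,
doublets, and transcript-level (sub-cellular) noise. Passing recovery tests
therefore demonstrates correctness of the inference machinery under the
stated generative model, not robustness to those artifacts.

## Contact graph and niche composition

Immediate contact (the radius R = 0 niche) is approximated by Delaunay
triangulation of centroids with edges longer than `prune_factor` (default
2.0) times the median Delaunay edge removed — the standard centroid-based
surrogate for membrane contact when segmentation masks are unavailable.
Degenerate inputs (collinear points) fall back to a mutual-nearest-neighbor
rule; duplicate coordinates are jittered by 1e-6 µm with a warning.

Niche composition is the neighbor-type frequency vector per cell (center
cell excluded). Enrichment mode divides by the global type frequencies over
all mapped cells, so a value of 1 means "as expected from the tissue".
No pseudo-count is used; types with zero global frequency are dropped with
a warning. Isolated cells get all-zero rows and are excluded downstream.

## Interaction map

A multinomial (softmax) logistic regression predicts each cell's type from
its enrichment-mode niche composition. Multinomial rather than one-vs-rest
keeps a single coherent coefficient matrix. Features are not re-standardized
(enrichment is already scale-normalized), so coefficient magnitudes remain
comparable to the conventional 0.14 edge-weight threshold used to draw the
interaction network. Class imbalance is handled with balanced (inverse
per-fit frequency) sample weights so rare types remain predictable.
Stratified 5-fold cross-validation yields held-out per-class accuracies and
a confusion matrix; reported coefficients are fold averages, never a
refit-on-all. L2 strength defaults to 1.0 (sklearn `C = 1`); the binary
two-type case is expanded to the symmetric softmax form so that the
coefficient matrix stays square. The network is the set of coefficients
strictly above the threshold, drawn niche type -> central type.

## Latent factors and covariation

**Factors.** For one cell type, the normalized (min-total) and
log1p-transformed expression of its cells is factorized with
NNDSVD-initialized coordinate-descent NMF. One component beyond the
requested `k` is always fitted and set aside as the *baseline*: the
component with the flattest loading over genes (maximum entropy of the
normalized loading). The remaining `k` factor loadings are L2-normalized
with scale pushed into the activities. The baseline component matters: a
cell's log-expression profile is dominated by a dense common mode (baseline
expression scaled by the per-cell normalization factor), and if the `k`
program factors must also carry that mode, their activities become strongly
anti-correlated through explaining-away, which poisons downstream
regression inference. `k` defaults to 3 — small panels support few factors.

**Covariation regression.** For an ordered pair (central, niche), every
central-type cell with at least one contacting niche-type cell contributes
a row: response = its own factor activities, predictors = the unweighted
mean activities over its niche-type contacts (all R = 0 contacts are
equivalent, so no distance weighting). The central cell's baseline activity
and the mean niche baseline activity enter as nuisance covariates: they
absorb the residual depth/common mode that normalization and NMF leave in
the activities. Each central factor is regressed on all niche factors by
ridge (default strength 1.0 on z-scored predictors, intercept by
centering); coefficients are reported on the raw predictor scale.
Significance uses the sandwich form Var = s² A⁻¹X'X A⁻¹ with
A = X'X + λI, residual degrees of freedom n − p − 1, two-tailed t
p-values, and BH correction over the k x k grid of one type pair (per-pair
families, matching how per-pair grids are read). Shrinkage bias is treated
as negligible at the default ridge; a Monte-Carlo null study (independent
predictors and responses, n = 200, 1,000 replicates) checks the type-I
error stays near 0.05. The grid is directional: swapping central and niche
roles is a different regression, and equality is not expected.

**Known limitation.** When a planted coupling is very strong (saturating
t-statistics), a few percent of residual factor impurity leaks detectable
dependence into the coupled factor's row and column of the grid: in the
recovery study the uncoupled-cell significance rate is ~9–11% rather than
the 5%-level nominal rate, even though the test itself is calibrated under
the null. This is a property of estimating activities by NMF from
normalized counts, not of the regression; the baseline-component design
above already reduces it threefold. Interpret isolated weak hits adjacent
to a dominant covariation signal with care.

**Ligand-receptor nomination.** Genes are ranked per factor by Spearman
correlation of normalized log expression with factor activity (constant
genes are flagged at 0). For every factor pair with BH-adjusted p below
0.05, pairs from the bundled curated ligand-receptor table are reported
when the ligand lies in the niche factor's top-200 positively correlated
genes and the receptor in the central factor's top-200. The table and the
S/G2M cell-cycle lists are editable one-record-per-line text fixtures with
mouse gene symbols.

## Expression statistics

**Filtering and normalization.** Cells with total UMI count strictly above
1,000 are kept by default for dissociated data (the pipeline default for
panel-style synthetic data is 0 — a 160-gene panel never reaches
whole-transcriptome totals). Normalization divides each cell by its total
and multiplies by the minimum total across cells; it preserves zeros, makes
all column sums equal, and is idempotent.

**Differential expression.** A background model `v(m) = m + a m²` is fitted
by least squares across genes of the pooled groups (`a >= 0` enforced;
`v` floored at 1.001 m so NB sizes stay finite). Under this model each
cell's count is NB with size `r = m²/(v−m)`, group sums are NB with sizes
`n_A r` and `n_B r`, and the exact conditional null of the group-A sum
given the pooled total is beta-binomial(total, n_A r, n_B r). The reported
p-value is the doubled smaller tail of that conditional distribution,
capped at 1, BH-corrected across tested genes; zero-count genes are skipped
and listed. The conditional construction is what makes the test calibrated:
testing a group sum against an NB centered on the *estimated* pooled mean
is structurally conservative (for equal groups the nominal 5% level
realizes at ~0.6%), because the null mean is built from the very sums being
tested. As `a -> 0` the test reduces to the classic conditional binomial
comparison of two Poisson rates. DE runs on normalized counts — with equal
per-cell totals the conditional test's assumptions are cleanest — and this
choice is deliberate and documented rather than inferred.

**Gene-set scores.** Per cell, the sum of normalized expression over a gene
set (missing genes dropped with a warning); per group, the sum over member
cells; `log2(x+1)` on request (pseudo-count 1 keeps empty cells at 0).

## Label transfer

Shared genes are intersected, both matrices normalized and log1p'd. Spatial
cells are clustered by Leiden (RBConfiguration, default resolution 0.8,
seeded) on an expression kNN graph (k = 15). Each cluster is anchored to
the reference type whose expression centroid best matches the cluster
centroid by Spearman correlation — Spearman rather than Pearson for
robustness across modality and depth differences — and every cell inherits
its cluster's label. Per-cell confidence is the margin between the best and
second-best centroid correlation of the cell itself; cells whose best
correlation is negative are flagged unassigned and excluded downstream.
Reference types with fewer than 3 cells are dropped with a warning. This
cluster-anchored design is a deliberate reconstruction of spatially guided
label transfer; only the clustering resolution is treated as a published
convention (0.35 or 0.8).

## Pipeline, formats, determinism

All artifacts are plain text: cell tables as CSV (micrometer floats, names
not indices), counts as integer Matrix Market plus `genes.tsv`/`cells.tsv`
(bit-exact round trip), ground truth and configuration as strict JSON
(unknown keys rejected). `run_pipeline` executes the toggled stages
simulate -> transfer -> graph -> niche -> interact -> covary -> de -> score,
validates stage dependencies up front, writes the resolved configuration
beside the outputs, and emits a manifest of SHA-256 checksums. Every source
of randomness is a `numpy` Generator seeded from the configured seed with
fixed substreams (placement/typing, spatial counts, reference counts), so a
rerun with the same (config, seed) is byte-identical — the determinism
study asserts equality of manifest checksums.

## Study sizes

The validation studies use 3,000-cell tissues (interaction), 2,000-cell
two-type tissues (covariation), 1,000–2,000-gene simulations (DE), and
1,500 cells (label transfer), with 20 seeds for recovery rates and 1,000
replicates for Monte-Carlo calibration. These sizes give stable rates while
keeping the full validation suite in the low minutes on a single core.
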