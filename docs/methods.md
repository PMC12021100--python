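# Methods

`stratomics` reimplements, as a tested pipeline over synthetic data, the
computational chain used to stratify a cohort of 158 treated people with HIV
into an "HC-like" and an immunometabolically "at-risk" group and to
characterize the at-risk phenotype: similarity network fusion (SNF) over
three omics layers, moderated differential protein abundance, shadow-feature
consensus selection, Gaussian Bayesian-network driver scoring, a resampled
Spearman consensus association network with Leiden communities and a
senescence overlay, and context-constrained flux balance analysis on a toy
stoichiometric model. The original cohort matrices are access-restricted, so
every stage runs against a synthetic cohort generator with planted ground
truth, plus the worked examples whose inputs (clinical contingency tables,
algorithm parameters) are public.

## Synthetic cohort generator

`synthetic.generate_cohort` draws a cohort of 88 + 70 samples with three
layers:

- **Proteins** (2500): standard normal on a log-like scale; 500 "affected"
  features receive a standardized group shift δ_p = 1.0. This makes the
  protein layer the dominant carrier of cluster signal, as in the study
  cohort, where the proteome drove the stratification.
- **Metabolites** (900): standard normal; 300 affected features shifted by
  δ_m = 0.3. The count was chosen so the layer is weakly informative — its
  single-layer clustering agrees with the fused clustering far less than the
  proteome's but consistently more than the transcriptome's, matching the
  published layer-concordance ordering (NMI 0.4 / 0.07 / 0.008). A smaller
  affected set at this effect size leaves the layer indistinguishable from
  noise, which would contradict the intended "weak but present" condition.
- **Transcripts** (2000): negative-binomial counts (dispersion 0.2, a typical
  bulk RNA-seq value; log-means uniform over log 5..log 500) with δ_t = 0,
  so the layer carries no cluster information at all.

Planted structure, disjoint by construction so recovery tests are
unambiguous:

- **Driver DAG**: 5 driver proteins, each with 3 children generated as
  `child = 0.8 * driver + sqrt(1 - 0.64) * noise` (unit marginal variance).
  Drivers also receive the protein group shift so the selection → driver
  chain can find them end to end.
- **Cross-layer modules**: 2 modules of 30 features (10 per layer) driven by
  one latent factor per module with loading λ = 0.8; Gaussian features use
  the `λ f + sqrt(1 − λ²) ε` construction (unit marginals), transcript module
  members put `0.7 λ f` into the log-mean (a rank-correlation analogue for
  counts).
- **Covariates**: categorical/ordinal clinical variables drawn at
  group-specific rates mirroring the published cohort table (hypertension
  0.40 vs 0.61, central obesity 0.57 vs 0.73, three-level smoking, fruit
  intake, transmission mode, CAD category, plus continuous age and
  Poisson-like beef intake).
- **Senescence sets**: three protein annotation sets sized 126/50/8 (a 1:10
  scale of the CellAge / CSgene / Reactome-SASP databases), sampled with 60%
  of members from signal-carrying proteins so the overlay stage has
  structure to find.

What the generator does **not** emulate: assay chemistry (NPX units, LC-MS
peak artifacts), missingness mechanisms, library-size or batch effects,
feature-feature correlation beyond the planted modules/DAG, or any real
biological annotation. Passing recovery tests therefore demonstrates that
the algorithms recover the statistical structure they target at realistic
sample sizes — not that they would produce the cohort's specific biological
findings.

## Stratification (SNF)

Features with variance < 0.2 are removed (strict inequality); each layer is
z-scored. Affinities use the locally scaled kernel
`W(i,j) = exp(−d²(i,j) / (α ε(i,j)))` with squared Euclidean distances and
`ε(i,j) = (mean d² over i's K nearest neighbours + mean over j's + d²(i,j))/3`
(K = 30, α = 0.7), so `W(i,i) = 1`. Fusion is standard cross-diffusion:
full kernels are normalized to transition matrices with half the mass on the
diagonal, sparse kernels keep each row's K nearest neighbours renormalized,
and `P_v ← S_v · mean_{u≠v}(P_u) · S_vᵀ` iterates T = 20 rounds with
symmetrization. The final average is brought to a simultaneously symmetric,
nonnegative and row-stochastic form by symmetric Sinkhorn scaling — diagonal
scaling preserves the spectral cluster structure while satisfying both
normalization conventions exactly.

Cluster number: the eigengap of the normalized Laplacian (difference of
consecutive sorted eigenvalues at each candidate C) and, as the second
criterion, a rotation cost — the Yu–Shi SVD discretisation of the first C
eigenvectors followed by the self-tuning alignment cost
`Σ_i Σ_j Z²_ij / max_j Z²_ij`, minimal (= n) when rows are one-hot. The
toolchain the study used reports a rotation cost without citing a formula;
this variant is isolated behind the diagnostics interface and only its
argmin is consumed. Spectral clustering uses the normalized Laplacian
embedding with row normalization and seeded k-means (20 restarts, best
inertia). Concordance is NMI with arithmetic-mean normalization. Ties in
neighbor selection break by sample order.

Cluster validation is a deliberately simplified patient-similarity
classifier (the published analysis used netDx, whose pathway-level feature
scoring is out of scope): 20 random 80/20 splits; each held-out sample is
scored per cluster by mean Pearson similarity to that cluster's training
members (omics views) and negative normalized absolute difference
(continuous clinical views), averaged over views; argmax predicts, ROC/PR
use the two-cluster score margin, and confusion matrices are averaged over
splits.

## Differential abundance

Per-feature OLS against a design of intercept + cluster contrast + encoded
covariates, then empirical-Bayes variance moderation: prior (d0, s0²) by
method of moments on log s² (trigamma inversion by Newton iteration),
posterior `s̃² = (d0 s0² + d s²)/(d0 + d)`, moderated t on d0 + d degrees of
freedom, BH adjustment. A test cross-checks t, p, d0 and s0² against the
reference Bioconductor implementation via Rscript. Three model tiers mirror
the study design (unadjusted; between clusters; clusters + ethnicity,
smoking, fruit and beef intake). Fruit intake is ordinal and encoded as
ordered numeric 0/1/2 (the study does not state its encoding); other
categoricals are reference-coded against the first observed level.
Transcript counts pass through log2-CPM (+0.5 prior) before fitting — an
approximation to a dedicated count model, acceptable here because the
transcript layer carries no planted signal. Over-representation uses the
upper-tail hypergeometric; directional set enrichment compares each set's
mean signed t with a feature-label permutation null (two-sided empirical p
with the +1 correction).

## Consensus feature selection

Shadow-feature (Boruta-style) relevance testing: each candidate column gets
a permuted shadow copy; a random forest (25 trees) is fitted per round and a
feature scores a hit when its importance exceeds the round's maximum shadow
importance; confirm/reject by a two-sided binomial test at α = 0.05 against
hit probability 0.5 over up to 20 rounds. Confirmed features stay in the
design (they keep competing against a full shadow block); rejected features
are dropped; undecided features end unconfirmed. Importance is the forest's
impurity importance (mean decrease in impurity): only the comparison against
the shadow maximum matters, and impurity importance is both sensitive and
cheap at these sizes, whereas permutation importance computed on the
training matrix is insensitive for an interpolating forest and an
out-of-bag variant is disproportionately expensive in pure Python.

Consensus voting samples `subset_size` features per iteration without
replacement; a feature's frequency is confirmations over the iterations in
which it was *sampled* (with subset ≪ total features no feature could reach
a 70% vote otherwise), with a minimum-support floor (20 sampled iterations
at full scale) to stabilize the ratio. The final panel is evaluated with a
700-tree random forest, 3 × 10-fold stratified CV over an mtry grid of
1..15, pooled CV predictions for the confusion matrix, and OOB error from a
full fit; "at-risk" is the positive class for sensitivity.

## Bayesian-network drivers

Structures are scored with the decomposable Gaussian BIC: per node,
log-likelihood of the linear-Gaussian regression on its parents (MLE
variance) minus `(k/2) log n`, `k = |parents| + 2`. Data are z-scored first
so node terms are comparable. Hill climbing is greedy best-improvement over
add/delete/reverse moves with acyclicity and a max-parents cap (default 5,
for tractability at ~190 nodes), with node-score caching keyed on
(node, parent set). The consensus DAG aggregates 150 restarts from random
starting DAGs: an edge is kept iff its direction wins more than half of the
runs and the reverse direction does not (direction-conflicted "undirected"
edges are removed; the retention threshold is a documented choice — the
source analysis names no threshold); residual cycles are broken by removing
the lowest-support edge per cycle. Refinement applies 1000 random
single-edge perturbations, accepting only score improvements, so the score
is monotone by construction.

A node's driver score is `ΔBIC_g = Σ_{j≠g} [score_j(G) − score_j(G−g)]` —
only g's children change, and g's own term is excluded from both sides so
totals are comparable. Validation draws 5 random non-candidate nodes per
iteration for 1000 iterations; the empirical p is
`(1 + #{max random ΔBIC ≥ ΔBIC_g}) / (iterations + 1)`.

## Consensus association network

Spearman correlation is computed as Pearson on average ranks, with p-values
from the t approximation. Per iteration, 400 features per layer (desk-scale
runs use less) are pooled; all pairs are tested and BH-adjusted within the
iteration at FDR < 1e-6. A pair's consensus frequency divides by the
iterations in which both members were co-sampled — a pair that was never
drawn cannot be "found" — and pairs at ≥ 90% enter the consensus set, whose
correlations are re-tested on the full data with a global BH at
FDR < 5e-5 and split by sign into positive/negative networks. Nodes carry
differential-abundance up/down flags. Networks are compared to 100
Erdős–Rényi graphs with identical node and edge counts (density matches by
construction; the clustering coefficient gets a z-score). Leiden runs on
modularity at resolution 1 with |rho| edge weights; only communities with
strictly more than 30 members (desk scale: configurable) are reported;
community centrality is the within-community mean degree and the most
central community maximizes it. The senescence overlay intersects the union
of the three annotation sets with measured proteins, keeps those at DPA
FDR < 0.05, and reports the fraction inside the most central community. The
retention check z-scores the significant senescence proteins, Ward-clusters
the samples, cuts at 2 and reports ARI against the stratification labels.

## Toy flux balance analysis

Genome-scale reconstruction is out of scope; the packaged `toy_cell_model`
is a ~25-reaction network (glucose uptake and glycolysis, pyruvate
dehydrogenase and a lumped TCA, oxidative phosphorylation with P/O = 2, a
lactate overflow branch, a tryptophan → kynurenine transport block, ATP
maintenance, and a biomass reaction consuming g6p + pyr + 2 atp + 0.1 trp).
FBA maximizes biomass via `scipy.optimize.linprog` (HiGHS) subject to
S v = 0 and bounds; an unbounded problem raises an error naming the
infinite-bound reaction set; the returned flux vector is one optimal vertex,
so only the objective and activity/direction classifications are
contract-level. Contextualization gates reactions whose AND/OR gene rule
(AND = min, OR = max) evaluates below a threshold and scales finite positive
exchange bounds by `bound_scale × level / reference`; the contextualized
model must still pass a 3-task list (biomass on glucose, ATP production,
kynurenine secretion) — a toy stand-in for full task checking — or it is
rejected with the failed task names. Fluxes below 1e-7 mmol·gDCW⁻¹·h⁻¹ are
inactive; |v| ≥ 250 flags the display set and transport reactions carry
log2|v|. Group-specific reactions are target-only (active only in the
target context), direction-flipped (active everywhere, target sign opposite
to every other), or shared; individual-level activity differences use
two-sided Fisher tests with BH across reactions. The analysis driver bridges
cohort transcripts onto toy gene ids by deterministic index mapping with
group-mean log-CPM rescaled to [0, 1] — a synthetic stand-in for TPM
integration, labelled as such.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` seeds; identical
  seed + config + inputs give byte-identical written outputs (tested).
- Missing values in delimited input are minimum-imputed per feature before
  analysis (the metabolomics pipeline's convention, applied uniformly since
  the upstream handling for the other layers is unstated); imputation counts
  are recorded on the layer.
- Delimited text is tab-separated by default (comma via flag), decimal
  point only; alignment is always by sample identifier, never position.
- Chi-square applies the Yates correction exactly on 2×2 tables — the
  published central-obesity p (0.055) matches only the corrected value
  (uncorrected ≈ 0.037). Mann-Whitney uses exact enumeration when both
  n ≤ 8 and no ties, else the tie-corrected normal approximation with
  continuity correction. For sparse categorical tables larger than 2×2 the
  chi-square is retained with a note (Fisher on r×c tables is not
  implemented).
- Zero pooled variance in the t-test: p = 1 when means agree, error
  otherwise. Zero-variance features cannot be z-scored and must be removed
  by the variance filter first (error otherwise).
- The analysis drivers run desk-scale settings (e.g. selection 300 × 250,
  BN 30 restarts, network 300 × 150) — the package's own choice of problem
  sizes for a complete narrative run; the full-scale study settings remain
  the config defaults.
- The command-line surface is the set of numbered scripts under `analysis/`
  plus `pipeline.run_pipeline`, which chains the stages with dependency
  checking and provenance; no separate console-script CLI is shipped.

## Known limitations

- The rotation-cost formula and the netDx-style validator are simplified
  stand-ins; their absolute values are not comparable to the published
  cohort-specific numbers (eigengap 0.06, rotation cost 117, accuracy 0.84),
  which require the restricted data.
- The consensus-DAG retention rule and permutation refinement are
  under-specified in the source analysis; both are config-isolated.
- Directional enrichment permutes feature labels (competitive null), not
  sample labels; p-values are bounded below by 1/(n_perm + 1).
- The moderated model treats log-CPM counts as Gaussian; no voom-style
  precision weights.
- FBA solutions are degenerate; per-reaction flux values other than
  activity/direction should not be over-interpreted.
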