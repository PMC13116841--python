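# Methods

`ionbridge` implements a hub-gene → ion-channel drug-repurposing pipeline
for tumor/normal cohorts: differential expression, weighted co-expression
hub scoring, drug-evidence scoring, PPI bridge-path discovery, and two
single-cell perturbation validation layers (a variational-graph-autoencoder
virtual knockout and a seven-strategy CRISPRi evidence matrix). This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic-data tests do and do not establish.

## Bulk differential expression

Counts are normalized to counts-per-million per sample and transformed as
log2(CPM + 1). Batch correction is a deterministic per-gene location/scale
adjustment: a two-group mean model removes the condition effect, each
batch's residual mean is subtracted and its residual standard deviation
rescaled to the pooled value, and the condition means are added back. This
satisfies the contract "remove batch-specific location and scale while
preserving biological variation" without empirical-Bayes shrinkage; an
EB-style backend could be slotted in behind the same signature. A design
fully confounded with condition is left uncorrected with a warning, since
no location adjustment can separate the two effects.

Differential genes come from two-sided Welch's t-tests per gene on the log
scale with Benjamini–Hochberg adjustment. log2FC is the tumor-minus-normal
difference of group means on the log2(CPM + 1) scale — the scale is a
package choice; it matches the normalization chain. A gene is a DEG iff
padj < 0.05 **and** |log2FC| > log2(1.5) ≈ 0.585, both inequalities strict,
so boundary values are not DEGs. Genes with zero variance in both groups
and equal means get p = 1.

Calibration: on a fully effect-free synthetic cohort the Welch p-values are
uniform (KS test at 5000 genes). With the generator's default batch
effects, correction leaves the test slightly *conservative* (empirical
type-I ≈ 4–5% at nominal 5%, with a deficit of very small p-values); the
test's size never exceeds nominal in our simulations.

## Co-expression network and hub scoring

The network is unsigned: a_ij = |Pearson r_ij|^β over the top-V
most-variable genes (V = 5000 by default at cohort scale; β = 6 — the
standard unsigned default; a scale-free-fit picker can replace it). The
topological overlap matrix is

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

with self-weights zeroed internally and TOM_ii = 1. Modules come from
average-linkage clustering on 1 − TOM with a *static* height cut (default
0.99), minimum module size 30, and iterative merging of modules whose
eigengenes correlate above 0.75. The static cut is a deterministic,
desk-scale stand-in for dynamic tree cutting; labels are size-ordered and
the partition is invariant to gene order.

Module eigengenes are the first principal component of the standardized
module submatrix, unit variance, with the sign fixed toward positive
correlation with mean module expression. Module–trait association uses a
one-tailed permutation test on Pearson r against the 0/1 trait:
p = (1 + #{r* ≥ r}) / (B + 1) with B = 10,000 by default; ties count toward
the numerator, so p > 0 always and the test is valid. BH is applied across
modules.

Hub scores combine gene significance (GS, gene–trait correlation), module
membership (MM, gene–eigengene correlation) and intramodular connectivity
(kWithin, same-module TOM row sum). GS and MM are min–max normalized
globally over the candidate set; kWithin within each module so large
modules cannot dominate. Degenerate cases: a singleton module's kWithinnorm
is 0; min = max maps to the midpoint 0.5. The composite is the unweighted
mean of the three normalized components, hence always in [0, 1]. Hub
selection keeps genes with GS > 0 from selected modules — either modules
with BH q < 0.05 (default) or the top-K by correlation strength
(`top_k_modules`), since both selection rules are defensible — ranks by
composite score with lexicographic tie-breaks, and supports an explicit
include-list for externally validated genes.

## Drug-evidence scoring

Four component scores in [0, 1]:
S_phase = 1 with any approved drug, else max_phase/4;
S_tract = the maximum over tractability labels of a case-insensitive
substring match with precedence approved/clinical (1.0) > phase (0.8) >
structure/high (0.6) > medium/predicted (0.4) > low (0.2);
S_DGIdb = log(1+n_drugs)/log(31) capped at 1 (30 interacting drugs is the
"highly druggable" cap); S_ChEMBL applies the same transform to the larger
of the mechanism and molecule counts. The total is the fixed weighted sum
0.50·S_phase + 0.25·S_tract + 0.15·S_DGIdb + 0.10·S_ChEMBL. Target tiers
are assigned by first match: ApprovedTarget > LateClinicalTarget
(max_phase ≥ 3) > EarlyClinicalTarget (max_phase ∈ {1,2}) > Tractable
(Structure/High) (S_tract ≥ 0.6) > Tractable (Predicted) (S_tract > 0) >
Unknown. A gene is druggable if it has approved drugs or DGIdb candidate
compounds. Repurposing exclusions (immunosuppressive agents; promotion of a
tumor-suppressor ion channel) are curated annotations supplied as config —
they come from literature, not computation — and every exclusion is logged
with its reason.

## Bridge paths

The PPI graph is first restricted to edges with combined score ≥ 400 (on
the 0–1000 scale). For each hub × up-regulated channel pair the shortest
path with at most two intermediates (≤ 4 nodes) is found; among equal-length
paths the largest geometric mean of edge scores (combined/1000) wins, with
lexicographic tie-breaks, so exactly one path is reported per pair (an
`all_paths` flag enumerates the rest). Channel eligibility requires
log2FC strictly positive: a zero-change channel is not a rational inhibitor
target. A path is graded *strong* if any edge carries experimental or
database channel evidence (> 0 by default; `channel_floor` configurable),
else *moderate*.

## Virtual knockout (VGAE)

The gene regulatory network is a k-nearest-neighbor |Pearson| graph over
the top-2000 variable genes plus all bridge-path genes, symmetrized by
union; node features are row-standardized log1p library-scaled expression
over at most `max_cells` cells (default 500, subsampled) to bound the
encoder width. The encoder is a two-layer graph convolution
(Â = D^-1/2(A+I)D^-1/2; hidden 32 → heads μ and logσ, latent 16), the
decoder an inner product σ(z_i·z_j) reconstructing edges, and the loss is
binary cross-entropy over positive plus equally many sampled negative pairs
plus a β-weighted KL to the standard normal prior (β = 1). Training runs
Adam (lr 0.01, 200 epochs) with a fixed seed and is bit-reproducible; logσ
is clipped at ±6 for stability. The network is implemented directly on
numpy arrays with hand-derived gradients — at the graph sizes this package
targets (hundreds to a few thousand nodes) training takes seconds on one
CPU. The model is trained once on the wild-type graph and then frozen; a
weight hash verifies immutability across all knockout inferences.

A knockout zeroes the target's feature row and removes its incident edges;
the frozen encoder maps the perturbed graph to knockout posteriors. The
per-gene signal is the closed-form KL divergence between the knockout and
wild-type diagonal Gaussians, summed over latent dimensions. Because KL
values are extremely right-skewed, genes are ranked non-parametrically:
rank 1 is the largest KL, ties share the best rank, and percentile =
(1 − rank/total) × 100. KL is reported raw; log10(KL + 1e-10) is only a
display transform.

**Bagging consistency.** Each of 100 permutations draws 80% of the training
cells without replacement and bootstrap-expands the draw (with replacement)
back to the encoder's fixed feature width — a frozen GCN's first-layer
weight matrix fixes the input dimension, so the subsample cannot simply
shrink. Edges stay fixed at wild type, isolating feature-noise sensitivity.
The bootstrap percentage is the fraction of permutations with the target in
the top 5% of the KL ranking; the validation criterion is ≥ 95% (i.e. ≥ 95
of 100 permutations).

**Negative controls.** Random non-hub genes (default 50) are knocked out
with the same frozen model. Per pair, the target gene's KL under the hub
knockout is placed at a percentile within that gene's KL across control
knockouts; at the dataset level a one-sided Mann–Whitney U compares total
(summed) KL per knockout between hubs and controls, with the hub/control
median fold change reported. Control gene lists and seeds are recorded in
the output. A pair is VALIDATED if the channel itself meets the bagging
criterion in at least one dataset, PARTIAL if only a path intermediate
does, else unvalidated.

## Perturb-seq evidence matrix

Seven strategies each score 0–3 (pair maximum 21). All breakpoints are
strict; a statistic exactly at a breakpoint takes the lower score.

- **S1 pseudobulk DE** — cells summed per (condition, batch); Welch's
  t-test on log2(CPM+1) pseudobulk profiles with BH (deterministic
  default; a pydeseq2 negative-binomial backend is available). Rubric:
  padj < 0.05 → 3, < 0.1 → 2, < 0.2 → 1.
- **S2 preranked GSEA** — weighted Kolmogorov–Smirnov running sum (weight
  exponent 1) on the knockout log2FC signature; null from gene-set
  permutations; NES = ES / mean |null ES| of matching sign; add-one
  empirical p. Rubric: |NES| > 1.5 and p < 0.05 → 3, |NES| > 1.3 → 2,
  |NES| > 1.0 → 1. Only the 3-point grade requires significance.
- **S3 transcriptome rank** — target's |log2FC| rank among all genes as a
  top-percentage, ties broken by gene id. top 5% → 3, 10% → 2, 20% → 1.
- **S4 hurdle test** — logistic detection ~ condition + CDR plus linear
  expression-among-detected ~ condition + CDR; likelihood-ratio
  chi-squares summed with their degrees of freedom; a degenerate part
  (all/none detected) drops out; BH across the tested gene family. Same
  rubric as S1.
- **S5 mediator network** — genes with padj < 0.05 and a PPI edge to the
  target: *validated* (3) if any above-threshold edge has experimental or
  database evidence, *predicted* (2) for other above-threshold edges,
  *weak* (1) below threshold, *none* (0).
- **S6 global perturbation** — mean |z| across expressed genes, where z is
  the KO-minus-control difference of normalized means divided by the
  pooled per-gene SD, floored at the 10th percentile of positive SDs. This
  standardized-mean-difference z is a package definition: dividing by the
  *standard error* instead would pin the null statistic near E|N(0,1)| ≈
  0.8 at any sample size and saturate the rubric, whereas the pooled-SD
  form calibrates the null below the 0.1 breakpoint once each condition
  has ≳200 cells. Rubric: > 0.5 → 3, > 0.3 → 2, > 0.1 → 1.
- **S7 co-expression disruption** — Δρ = Spearman(KO cells) −
  Spearman(control cells) on normalized expression, mid-ranked ties; a
  constant gene in either condition flags the statistic missing (score 0).
  |Δρ| > 0.2 → 3, > 0.15 → 2, > 0.1 → 1.

The pair total is the plain sum; strength classes are ≥ 15 / [10, 15) /
[5, 10) / < 5. Fractional component scores (0.3, 1.5) appearing in
published-style tables are accepted as inputs to the total; the rubrics
themselves only emit {0, 1, 2, 3}.

## Integration

Composite validation score = 0.6·(evidence total/21) + 0.4·(mean virtual-KO
percentile/100), averaging percentiles over available datasets; with no
percentile the Perturb-seq term is reported alone and flagged partial.
Pairs are placed in a validation (x) × druggability (y) plane with
configurable thresholds (default 0.5/0.5, strict >): high/high = Discovery
Opportunity, high/low = Target Development, low/high = Need Further
Validation, low/low = Low Priority.

The `ionbridge run` pipeline executes the stages in order (DE → hub →
drugscore → bridges → evidence → vgae-ko → integrate) on a self-generated
synthetic study, writing a TSV/JSON artifact per stage plus a manifest with
the config hash and per-stage seeds; any contiguous suffix of stages can be
rerun from cached artifacts. The PPI snapshot and the knockout experiment
are generated *after* hub discovery, for the hubs actually found — the same
order in which a real study queries its interaction database and designs
its knockout panel.

## Synthetic data: what it emulates, and what it does not

**Bulk cohorts** are negative-binomial (var = μ + αμ², α = 0.05) with
log-normal gene means; module co-expression comes from shared per-sample
Gaussian factors with unit loading on the log2-mean scale; the disease
effect shifts a module's factor mean in tumor samples. Batches add
per-(gene, batch) location shifts and residual-scale factors. Defaults
mirror the targeted cohort design: 42 tumor / 43 normal samples, two
batches, 13 modules with the two disease modules sized 718 and 194 genes.

**Single-cell knockout datasets** are zero-inflated NB (α = 0.4, 5%
independent Bernoulli dropout) with per-cell log-normal depth (sd 0.3).
The knockout multiplies the target's mean by (1 − knockdown fraction) in
its cells; mediator shifts are condition-specific mean multipliers;
co-expression pairs are planted through a Gaussian copula on the NB
quantile function, with the latent correlation set so the copula's Spearman
equals the requested value. Defaults are desk-scale — six KO genes plus
controls, 300 cells per group, 1500 genes, eight batches — a deliberately
scaled-down emulation of a pooled CRISPRi screen.

Known fidelity limits, which bound what passing tests show about real
data:

- The planted rank correlation is realized on raw counts; library-size
  normalization and independent dropout attenuate it (a planted ρ = 0.52
  measures ≈ 0.35–0.45 on log-CPM), so recovered Δρ values sit slightly
  below the planted difference. Real dropout is expression-dependent, not
  independent, which the generator does not model.
- CPM induces a mild negative compositional correlation between a strongly
  varying module and the remaining genes.
- Because independent dropout dominates log-scale Pearson for moderately
  coupled pairs, the virtual-knockout *consistency* tests use an
  overwhelming-signal scenario (planted ρ = 0.9, dropout-free) in which
  the knocked-out gene's channel is a reliable graph neighbor — the regime
  the bagging criterion is about — while evidence-matrix comparisons use
  the moderate planted effects (knockdown 0.9, mediator log2FC 2,
  Δρ ≈ −0.27).
- Guide-level CRISPRi efficiency, batch models beyond location/scale, and
  realistic gene symbols are out of scope.

**Problem sizes in the test suite** (package choices at desk scale): bulk
null calibration at 5000 genes × 85 samples; module recovery on two
30-gene blocks; knockout datasets of 300–400 genes × 750–1250 cells; GRNs
of ≤ 400 nodes with k = 4; VGAE training 100 epochs; bagging 20
permutations; GSEA 100–300 permutations; hurdle tests on 40–150-gene
panels. One global seed expands into per-generator substreams, so adding a
generator never perturbs another's draws.

## Numerical choices and degenerate inputs

- Strict inequalities at every rubric and DEG breakpoint, as a single
  consistent convention.
- Permutation p-values use the add-one estimator with ties counted as ≥.
- Tie-breaks in every ranking are lexicographic by gene id.
- Zero-variance genes: correlations set to 0 (warned) in the adjacency;
  isolated nodes in the GRN; excluded from DE direction calls only through
  the p = 1 rule.
- All-zero pseudobulk genes are excluded with a log entry; a hurdle target
  never detected is an error; a constant gene in a Spearman condition
  flags Δρ missing rather than guessing.
- The VGAE clips logσ at ±6 and the clip mask zeroes the corresponding
  gradients; training aborts with the epoch number if the loss goes
  non-finite.

## Known limitations

The batch adjustment is location/scale only — no empirical-Bayes shrinkage,
so very small batches are corrected noisily. The static tree cut can split
or merge modules that dynamic cutting would resolve. The hurdle test is a
two-part LRT, not a full zero-inflated mixture likelihood. The VGAE's
bagging resamples cells only (edges fixed); resampling edges would probe a
different robustness axis. Negative-control percentiles are computed
per-gene against 50 controls, so their resolution is 2 percentage points.
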