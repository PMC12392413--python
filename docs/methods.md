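# Methods

`annogs` predicts quantitative phenotypes from genome-wide SNP dosages and
asks which parts of a multiomics annotation graph carry the signal.  This
note records the models implemented, the choices made where the design was
genuinely open, and what the bundled synthetic cohorts can and cannot show.

## Data model and conventions

Genotypes are allele-dosage codes in {0, 1, 2}; 0 is homozygous for the
cohort's **major** allele, so a code counts minor-allele copies.  When
loading a VCF the orientation is recomputed from the loaded cohort's allele
frequency, with frequency ties broken toward REF.  Missing genotypes are a
hard load error: imputation belongs upstream.  SNP positions are 1-based
internally; interval files (BED) are 0-based half-open, and a SNP at 1-based
position `pos` lies in `[start, end)` iff `start <= pos-1 < end`.

The annotation bundle is a five-level graph: noncoding SNPs sit inside
cis-regulatory elements (open-chromatin intervals); elements link to genes
within a ±1 Mb cis window; coding SNPs map directly to genes; a gene × term
matrix scores each gene against functional terms; a term × metaterm matrix
groups terms into regulatory-module metaterms.  Allele-level impact scores
accompany the SNPs: predicted chromatin accessibility per allele for
noncoding SNPs and normalized RNA minimum-free-energy per allele for coding
SNPs, both in [0, 1], with a peak threshold (default 0.147) above which an
allele is treated as lying in an open-chromatin peak.

## The annotation-structured network

The network maps a genotype vector to a predicted phenotype through six
trainable internal layers plus a scalar output affine.  Internal widths are
`base_unit × unit_ratio[i]`; the canonical configuration (base unit 110,
ratio 1:2:4:5:6:7) gives widths 110, 220, 440, 550, 660, 770.  The first
two affine maps are masked by the biology:

* input → H1: every H1 node is assigned (round-robin) to one cis-regulatory
  element or, for the coding path, to one gene proxy; a SNP connects only to
  the nodes of its own element/gene.  A SNP with no assignment has zero
  fan-out, so the output's derivative with respect to it is exactly zero —
  tested by finite perturbation.
* H1 → H2: every H2 node carries one gene; an element node connects only to
  the genes its element regulates.

Deeper layers are dense.  This single-entity-per-node wiring is what makes
backward tracing possible; where a layer has more nodes than entities, an
entity simply owns several nodes and their importances are summed.

Annotation *injections* are deterministic per-sample features concatenated
to a layer's input (they have trainable fan-out weights but are not
themselves trained).  The annotation level controls which are active:

1. genotype only (a masked MLP);
2. + per-SNP impact features at H1: dosage × (alt − ref) score;
3. + per-term features at H2: gene signals (mean impact feature per gene)
   propagated through the gene × term matrix;
4. + per-metaterm features at H3: term features propagated through the
   term × metaterm matrix.

Each injected block is centered per feature and scaled by a **single
block-wide** standard deviation from the training set.  Per-feature scaling
would erase exactly the information the annotations add — the magnitude
contrast between large (functional) and near-zero allelic deltas — reducing
a causal SNP's impact feature to a copy of its standardized dosage.
Injection fan-out weights are initialized at zero, so annotations enter as
silent additive corrections and their trained weight magnitudes reflect
learned relevance rather than initialization noise; this matters for
interpretability (below).

Training is full-batch gradient descent with momentum, batch normalization
(running statistics updated with `bn_momentum`) and inverted dropout on the
internal layers.  The loss is

    loss = (1/n) Σ (y − ŷ)² + c · α_k · Σ_i |w_i|^k ,

with k = 1 or 2 (L1/L2), α_k the regularizer rate, and the binding
coefficient c fixed at 10⁻⁵.  The penalty runs over every affine weight
tensor, not biases or batch-norm parameters.  The loss trace recorded per
step is the deterministic full-batch loss (dropout off, batch statistics)
evaluated after the update, so a zero learning rate yields a constant trace
and a fixed seed reproduces the trace bit for bit.  The *optimal step* is
the first step attaining the trace's global minimum — the point after which
the minimum never decreases — and is the step count recommended for final
cross-validation runs.  Inference uses running batch-norm statistics and no
dropout, so predictions are deterministic and row-order equivariant.

Defaults follow the tuned configuration (learning rate 0.1, L2 with rate
0.01, momentum 0.9, dropout 0.1, base unit 110, ratio 1:2:4:5:6:7);
activation (ReLU), optimizer family (SGD with momentum), full-batch updates
and scaled-uniform initialization are this package's own documented
choices and are configurable.  The unit-ratio tuple may be shorter than six
entries, which shortens the network correspondingly; the six-layer form is
canonical.

## Linear baselines

GBLUP fits `y = μ + g + ε` with `g ~ N(0, K σg²)`, `K = ZZ′/p` on
column-centered codes.  REML profiles the likelihood on the eigendecomposition
of K and optimizes the variance ratio φ = σg²/σε² by bounded scalar search
(tolerance 10⁻⁸ on the log-likelihood; the φ = 0 boundary is checked
explicitly and negative components are reported as 0).  Marker effects are
back-solved as `û = (σg²/p) Z′V⁻¹(y − μ̂)`, so new samples are predicted
through `μ̂ + Z_new û`.  Because `K = ZZ′/p` is not normalized to unit
diagonal, reported heritability uses the phenotypic-scale genetic variance
`σg² · tr(K)/n`.

Ridge-regression BLUP solves `û = (Z′Z + λI)⁻¹Z′(y − μ̂)` with
`λ = σε²/σu²`, `σu² = σg²/p` taken from the same REML fit; its predictions
are algebraically identical to GBLUP's (verified to 10⁻⁶ on random
instances).  MultiBLUP fits one variance component per disjoint SNP class
(`V = Σ σm² K^m + σε² I`) by REML on log variance ratios with L-BFGS-B;
a single class reduces exactly to GBLUP, and empty classes are dropped with
a warning.  Fixed effects are the intercept only.

The heritability of a SNP subset is `σ̂g²·tr(K_S)/n / (… + σ̂ε²)` from a
REML fit on the GRM restricted to the subset.

## Bayesian baselines

BayesR models SNP effects with a four-component zero-mean normal mixture
with variances (0, 10⁻⁴, 10⁻³, 10⁻²) × σg² and a flat Dirichlet(1,1,1,1)
prior on the proportions; default chain settings are burn-in 5000 of 10000
iterations, thinning 1.  The Gibbs cycle samples the intercept, then each
SNP's component indicator from its exact conditional (effect marginalized)
followed by the effect from its conditional normal, then the proportions
from Dirichlet(1 + counts), then σg² and σε² from scaled-inverse-χ²
conditionals (ν = 4, prior scales set so each prior mean equals half the
phenotypic variance).  The class-specific variant gives every disjoint SNP
class its own proportion vector; a class with no SNPs keeps its prior
(reported as exactly 0.25 per component).  Genotype columns are centered
before sampling.

A caveat found while validating: when the true architecture is null, the
small and medium components are likelihood-indistinguishable from the point
mass at these sample sizes, so the posterior over the mixing proportions
stays close to its prior and the chain mean of π₁ is not a reliable
read-out.  The identifiable consequences — effects shrunk to ~0, near-flat
predictions, posterior concentration on truly causal SNPs when they exist,
and class-enrichment ordering — are what the test-suite asserts.

Disjoint SNP classes I–V are built from three annotations: (a)
nonsynonymous SNPs, (c) conserved genes, (d) metaterm signature genes.
I = (a) inside a (c) gene; II = (a) inside a (d) gene; III = other SNPs
within ±50 kb of a (c) gene; IV = within ±50 kb of a (d) gene; V = the
rest; precedence I > II > III > IV > V makes the partition disjoint.
Windows are measured from gene interval boundaries with the half-open
containment convention.

## Hyperparameter search

Candidates are drawn uniformly without replacement from the grid product
(default 500; the published-value grid covers learning rates over five
decades, L1/L2, regularizer rates, momenta 0.9/0.95, batch-norm momenta,
dropout rates, base units and unit-ratio tuples).  Every candidate is
evaluated at all four annotation levels with the same 2-fold split, scoring
the fold-averaged Pearson correlation; failed or degenerate runs are
recorded as missing and excluded.  For each hyperparameter dimension, the
best value is picked per (level, statistic) pair — the statistic being the
mean or median PCC over all candidates sharing a value (marginal
aggregation) — yielding 8 selections counted as votes.  The modal value
wins; vote ties are broken by the higher overall average PCC and exact PCC
ties deterministically by grid order.

## Evaluation statistics

Cross-validation uses seeded balanced folds; every sample is predicted
exactly once.  Accuracy is reported both ways: *together* (test folds
pooled before one Pearson correlation) and *separate* (one correlation per
fold) — the two genuinely differ when fold means are shifted.  Relative
efficiency RE(k) is the realized top-k genetic gain under the predicted
ranking over the gain under the observed ranking, both centered on the test
mean; ties break by stable sample order, fractional top-percent counts
floor with a minimum of 1, and a `minimize` switch handles traits improved
downwards.  RE is 1 under a perfect ranking, −1 when predictions select the
bottom, ≈0 under random ranking, and is invariant to positive affine maps
of the predictions.  Model contrasts use the paired t test on fold-wise
metrics; degenerate cases (zero-variance differences, constant vectors)
propagate as missing rather than 0.

## Backward tracing

For m trained replicates (one per CV fold), every node of a biological
layer — metaterm, term, gene, element, noncoding SNP, RNA structure, coding
SNP — is scored by the sum of absolute outgoing weights and the nodes
ranked descending, normalized by the layer's node count.  A node's m
normalized ranks are combined with the beta order-statistic score
ρ = min_k P(Beta(k, m−k+1) ≤ r₍ₖ₎), Bonferroni-corrected within node (× m)
and Benjamini–Hochberg-corrected across the layer's nodes; entities with
adjusted p below the threshold (default 0.01) are significant.  Because
injection weights start at zero, a trained weight magnitude is accumulated
gradient — learned relevance.  A `scaled` variant multiplying by the
node's training-set standard deviation is exposed for exploration.

Known limitation: CV replicates share the genotype matrix, and
high-variance annotation features attract some weight even when fitting
noise, so under a phenotype-permutation null the per-layer flagged fraction
at BH 0.01 runs slightly above nominal (about 2–3% in our checks).  The
rank-aggregation machinery itself is exactly calibrated on exchangeable
ranks.  Treat the significant sets as prioritization, not inference.

Candidate cis-regulatory SNPs for a significant gene are noncoding SNPs
within ±1 Mb of the gene (boundary inclusive), significant in the SNP layer
(default 0.05), and with at least one allele's accessibility at or above
the peak threshold; candidates are ranked by adjusted p and reported with
their target gene, distance and allele scores.

## Synthetic cohorts

The generator lays one chromosome with evenly spaced elements and genes,
places noncoding SNPs inside elements and coding SNPs inside genes, links
every element to its nearest gene within ±1 Mb, and draws genotypes
per-SNP Binomial(2, maf) with maf ~ Uniform(0.05, 0.5) by default.  SNPs are
independent (linkage equilibrium) unless the optional block-LD mode is
enabled, which correlates adjacent SNPs through a latent AR(1) Gaussian
copula.  Causal structure cascades through the annotations: causal
elements each contribute one causal noncoding SNP; causal coding SNPs are
marked nonsynonymous; causal SNPs get large allelic impact deltas
(|alt − ref| ~ U(0.25, 0.45)) versus near-zero Gaussian deltas elsewhere;
the genes of causal SNPs score highly on a small set of causal terms, and
those terms form the signature of one causal metaterm (each term loads on
a single metaterm, mirroring near-disjoint factorization modules).
Additive effects follow the BayesR-style mixture over the small/medium/
large classes, scaled proportionally to the SNP's impact delta; an optional
fraction of within-module causal pairs adds centered pairwise interaction
terms.  Environmental noise is scaled against the realized genetic
variance so the realized heritability matches the target (default 0.4);
identical config and seed reproduce the cohort bit for bit.

Default sizes (1000 samples, 1000 SNPs in 200 elements and 60 genes, 40
terms, 8 metaterms) keep every recovery experiment in the test-suite and
the acceptance script within a few CPU-minutes; larger cohorts (n = 2000)
are used where an estimator's precision demands it.  What passing tests
show, and don't: the cascade is annotation-consistent by construction, so
the level-4 > level-1 accuracy ordering and the backward-tracing recovery
demonstrate that the machinery exploits *correct* annotations; they say
nothing about misannotated or LD-confounded real data, where such claims
would need a real cohort.

## Numerical notes

REML tolerance 10⁻⁸ on the log-likelihood; variance components clipped at
the zero boundary with a log message.  Batch-norm ε = 10⁻⁵.  Ranking ties
everywhere break by stable (first-listed) order.  Network training aborts
with a diagnostic naming the step if the loss goes non-finite.  The Gibbs
sampler caches per-SNP squared norms; chains are reproducible from a single
integer seed, as are fold plans, candidate draws and simulations.
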