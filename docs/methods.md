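# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, the numerical choices, what the synthetic-data
generator does and does not emulate, and known limitations.

## 1. Per-study enrichment

Gene-level DE p-values per study are reduced to pathway-level enrichment
p-values in one of two ways.

**Over-representation (default).** The top *n* genes by DE p-value (default
n = 400; ties at the rank boundary broken by lexicographic gene id for
reproducibility) form the candidate list. For a pathway with K genes in the
background of N genes, the overlap k with the n candidates is tested
one-sided: p = P(X ≥ k), X ~ Hypergeometric(N, K, n). The background is the
*measured* genes of the study intersected with the collection universe —
never the full annotation universe — because genes that could not have been
detected must not dilute the null.

**Kolmogorov–Smirnov (threshold-free).** One-sided two-sample KS comparing
in-pathway vs out-of-pathway gene p-values, alternative: in-pathway values
stochastically smaller. A one-sample variant against Uniform(0,1) would be
an alternative reading; the two-sample form is used because it conditions on
the study's actual p-value distribution (which is never exactly uniform
under global signal).

Pathways are size-filtered to [15, 500] genes (inclusive) before testing;
the count can optionally be taken after intersection with the measured genes
(`restrict_to`), since annotation-only genes inflate apparent pathway size.
Exact zeros are floored at 1e-300 before any log-transform.

ORA p-values are discrete, so their null distribution is only approximately
uniform; the uniformity property test therefore exercises the KS branch,
which is nearly continuous at realistic sample sizes (500 genes, 50-gene
pathways).

## 2. Adaptively weighted Fisher meta-analysis

For p-vector (p₁..p_K) and binary weights w, V(w) = −2Σ w_k log p_k and
U(w) = P(χ²_{2Σw} ≥ V(w)). The reported weights minimize U over the 2^K − 1
nonzero vectors. Since for fixed weight-sum s the minimum of U is attained
by the s smallest p-values, the search reduces to K nested candidates; the
equivalence with exhaustive search is asserted by test on random vectors up
to K = 8. Ties in U are broken toward the smaller weight sum (the sparser
explanation); ties are measure-zero but determinism matters for regression
tests.

The minimized U is a minimum of dependent p-values, not itself a p-value.
The combined p-value is P(min_w U(W) ≤ U_obs) under K i.i.d. uniform
p-values, estimated by Monte Carlo: B null vectors, the same nested search
per vector (vectorized: sort, cumulative log-sum, regularized upper
incomplete gamma), and the +1-corrected estimator (1 + hits)/(B + 1), which
never returns zero. Whole-matrix meta-analysis shares one sorted null sample
across pathways (the null depends only on K), making the cost O(B·K) once
plus a binary search per pathway. Calibration is asserted by a KS uniformity
test of combined p-values over thousands of null vectors with independent
draws each.

For K ≤ 3 a deterministic oracle computes the same probability by numerical
integration: the event {min U ≤ t} equals ∪_s {product of the s smallest
p's ≤ c_s} with c_s = exp(−½·χ²⁻¹(1−t; 2s)); the complement is integrated
over the ordered simplex with all constraints folded into integration limits
(continuous integrand), on a midpoint grid refined until two successive
refinements agree to 1 %. An earlier indicator-on-a-grid formulation was
rejected: its O(1/m) boundary bias can satisfy a naive convergence check
while still ~3 % off.

Default B = 10,000 suffices for screening at q < 0.0005 over ~10³–10⁴
pathways because BH only needs the small p-values ranked, but a combined
p-value near 5×10⁻⁶ needs B = 10⁷ for ~50 expected null hits (relative
Monte-Carlo SE ≈ 13 %); the acceptance script uses that size. A warning is
emitted whenever fewer than 10 hits back an estimate.

Benjamini–Hochberg adjustment is delegated to statsmodels. Significant
pathways (q < 0.0005 by default) are tagged `consensual` when every study
weight is 1 and `differential` otherwise.

## 3. Pathway clustering

**Kappa.** For pathways A, B over universe size n with a = |A∩B|, b = |A\B|,
c = |B\A|, d = n−a−b−c: Po = (a+d)/n, Pe = ((a+b)(a+c)+(c+d)(b+d))/n²,
κ = (Po−Pe)/(1−Pe). This is exactly Cohen's kappa of the two membership
indicator vectors (cross-checked against the generic implementation in
scikit-learn). The kappa universe defaults to the union of genes across the
clustered pathways rather than the full collection universe: genes annotated
to none of the clustered pathways only inflate the d cell identically for
all pairs and wash out contrast. This is configurable.

**Consensus clustering.** For each candidate K: resample 80 % of the items
(500 resamples by default), cluster each subsample by average-linkage
hierarchical clustering of 1 − κ, and record co-membership. The consensus
matrix is co-clustering count / co-sampling count; pairs never co-sampled
are NaN and excluded from the CDF. The area under the consensus CDF A(K)
and its relative increments drive the elbow rule: K is advanced while the
relative gain exceeds 0.1 and stops at the first flat step. Stopping early
matters — beyond the true K, forced fragmentation re-inflates the area, so
"largest K with a gain" overshoots. Automatic selection is best-effort; a
fixed K (as the reference protocol itself uses) takes precedence when given.
Average linkage was chosen as the deterministic inner clusterer; PAM would
be a drop-in alternative.

**Silhouette tightening.** s(i) = (b(i)−a(i))/max(a(i),b(i)) with a(i) the
mean within-cluster dissimilarity (0 for singletons) and b(i) the nearest
other-cluster mean, computed on 1 − κ (the quantity the clustering
optimizes; 1 − consensus is an alternative). Each iteration removes *all*
items below the cutoff (default 0.1) at once — order-independent and at most
n iterations — and dissolves clusters that shrink to a singleton (their
a(i) = 0 convention would otherwise pin s near 1 and make them immortal).
Removed pathways form the scattered set, which is carried through annotation
flagged as secondary, never dropped. The post-condition min retained
silhouette ≥ cutoff is asserted on every run.

## 4. Penalized text mining

Incidence is per pathway, not per occurrence: a phrase appearing six times
across three descriptions contributes three. Name (v) and description (w)
binary matrices share one vocabulary. The score
x_ij = 1 if v_ij = 1; exp(−α|w_j|) if v_ij = 0 ∧ w_ij = 1; else 0, with
|w_j| the number of unique phrases in description j (the column sum of w).
α = 0.05 by default; at α = 0 the statistic is a plain count and the
permutation test reduces exactly to a hypergeometric tail on a names-only
corpus — asserted against scipy's hypergeometric at 3 binomial SEs.

T_i(C) = Σ_{j∈C} x_ij is tested against B subsets drawn uniformly without
replacement from the background (all pathways of the loaded collection by
default, mirroring matrix construction over the full corpus; configurable
to the significant set). The p-value is the upper tail with +1 smoothing:
p = (1 + #{T(S_b) ≥ T(C)})/(B + 1). One shared permutation stream serves
all phrases of a cluster (exchangeability holds and it is an order of
magnitude cheaper). BH runs within each cluster (keywords are interpreted
per cluster; a global variant is a one-line change); phrases are ranked by
(q, then T descending).

The default extractor is a deterministic rule-based chunker: split at
punctuation and at function-word/verb boundaries, keep maximal noun chunks
(determiners survive to stop-word removal). It requires no model download
and is snapshot-tested; industrial NP extractors plug in as callables.
Normalization: lowercase, stop-word removal (bundled list), rule-based
plural→singular on the final token with an irregular-noun exception table,
then single-word phrases on the bundled common-English list are dropped.
The common-word list is a curated high-frequency vocabulary (~900 entries,
versioned data file, configurable); domain terms are deliberately absent.
Synonym merging is supported for a user-supplied pair source: the
lower-occurrence row is OR-merged into the higher and deleted
(lexicographic tie-break); no synonym discovery is attempted. Phrases
supported by fewer than two pathways (name OR description) are pruned.

The penalty exists because long descriptions generate hits by chance: on a
corpus where one phrase sits in five names and another in five 100+-phrase
descriptions, raw counting ties them while the penalized statistic separates
them by ~e⁵ — the rank-inversion property asserted in the tests.

## 5. Pipeline, outputs, reproducibility

Stages write TSVs (`enrichment`, `meta`, `significant`, `clusters`,
`keywords`) so each is resumable and independently invocable via CLI
subcommands. Study dendrograms per cluster use Euclidean distance between
the studies' log10 p-value vectors restricted to the cluster's pathways
(average linkage, newick output); the metric is a configuration choice —
nothing in the model fixes it — and log10 keeps strong enrichments from
dominating. Plots: cluster-ordered kappa heatmap (scattered last), −log10 p
heatmap capped at 10 for readability, classical (Torgerson) MDS of 1 − κ
with a deterministic sign convention, and consensus CDF/delta-area
diagnostics. Plot failures are logged, never fatal; tables are always
written. Every run records a manifest (parameters, derived stage seeds,
versions, shapes); re-running a config reproduces all tables byte-for-byte,
asserted by test.

All randomness flows from a single user seed through
`numpy.random.default_rng`, with per-stage child seeds recorded.

## 6. The synthetic-data generator

`fixtures` plants known truth at every stage: three gene-set families of 10
members sharing a 60 % core gene block (within-family κ ≫ between-family κ),
30 unrelated null pathways, 2,000 genes, six studies. DE p-values are
Uniform(0,1) for null genes and Beta(a,1) with a = 0.05 for family-core
genes in enriched (family, study) cells — Beta(a,1) is the standard
analytically tractable alternative for p-values. The default design plants
one consensual family (all six studies) and two differential families
(studies 3–6 and studies 1–2), mirroring a two-tissue/three-diagnosis
contrast. Keywords are injected into 80 % of member names as standalone noun
chunks and into all member descriptions; background phrases come from a
~900-phrase vocabulary with Poisson(15) description lengths.

What the generator does **not** emulate: gene–gene correlation, platform
effects, realistic pathway-size distributions, hierarchical (GO-style)
containment between families, or natural-language descriptions with real
syntax. Passing tests therefore demonstrate correctness of the statistical
machinery under its stated assumptions, not performance on real annotation
corpora — in particular the chunker is only exercised on controlled text.

Problem sizes used in the test-suite: 2,000-replicate uniformity checks,
5,000-vector null calibration at B = 10⁴, 20-seed end-to-end recovery, and
the B = 10⁷ worked-example calibration. These sizes keep the whole suite in
the low minutes while leaving Monte-Carlo error well below the asserted
tolerances.

## 7. Known limitations

* The combined p-value is Monte-Carlo only; the closed-form small-p null of
  the weighted Fisher statistic is out of scope, so extremely small combined
  p-values (≪ 1/B) saturate at 1/(B+1).
* Automatic K selection is a heuristic elbow; for publication-grade analyses
  K should be fixed after inspecting the CDF/delta-area diagnostics.
* Keyword quality is bounded by description quality; collections without
  descriptions fall back to names only.
* The permutation test treats pathways as exchangeable under the null; the
  strong gene-sharing that motivates clustering in the first place mildly
  violates this for heavily overlapping corpora.
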