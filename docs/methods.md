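# Methods

This note documents the models implemented in `aromdeg`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Functional profiles

The abundance of an EC or KO annotation in a sample is the sum of the
coverage depths of every gene carrying it. A gene with *m* annotations
contributes its **full depth to each of the m rows**: coverage measures how
many gene copies are present, and each annotation of a multifunctional gene
is genuinely present in every copy, so splitting the depth would understate
all of them. Depths are continuous (mean fold-coverage), so nothing in the
normalization assumes integer counts.

Per-million scaling uses the effective-library-size convention:
`value = raw / (library_reads × TMM factor) × 1e6`. The TMM factors follow
the canonical trimmed-mean-of-M-values definition (two-sided 30% trim on
log-ratios, 5% on average log abundance, precision-weighted mean, factors
rescaled to geometric mean 1; rows zero in either member of a pair are
excluded). The reference sample is the one whose upper quartile of
**nonzero** relative abundances is closest to the mean upper quartile;
coverage matrices are much denser than raw read-count matrices, so
including structural zeros in the quantile adds nothing here. The factors
are computed on the annotation-aggregated matrix by default; external
factors can be passed instead. Given the same reference column, the
factors agree with edgeR's `calcNormFactors` to 10 decimals (frozen oracle
in the test suite).

The Hellinger transformation is applied per sample:
`value → sqrt(value / column_sum)` (ecology's convention of treating
samples as observations); all-zero samples stay zero, all others end with
unit sum of squares.

## Ordination

Bray–Curtis dissimilarity `d(u,v) = Σ|uᵢ−vᵢ| / Σ(uᵢ+vᵢ)` with `d = 0` for a
pair of empty samples. NMDS minimizes Kruskal stress-1
`sqrt(Σ(d̂−e)² / Σe²)` by alternating an isotonic regression of the embedded
distances on the dissimilarity rank order with a Guttman (SMACOF) update.
Numerical choices: the first restart starts from classical metric scaling
and the remaining restarts from seeded Gaussian configurations; primary
tie-handling in the isotonic fit; convergence at relative stress change
< 1e-6 or 300 iterations; a guarded step rejects any update that would
raise stress-1 (the normalizer Σe² moves between iterations, so the raw
majorization guarantee does not transfer verbatim), which makes the
per-iteration stress trace non-increasing by construction.

## Sub-metagenome decomposition (nsNMF)

The abundance matrix V (annotations × samples) is factorized as
V ≈ W·S·H with the smoothing matrix S = (1−θ)I + (θ/q)·11ᵀ. θ defaults to
0.5, the convention of the non-smooth NMF formulation this implements;
θ = 0 reduces exactly to standard multiplicative-update NMF. Updates are
the Lee–Seung squared-error rules with S absorbed into the fixed factor
(H updated against W·S, then W against S·H), which keeps the squared
Frobenius objective non-increasing; runs stop at a relative objective
change below 1e-5 or 2000 iterations.

Initialization: W is i.i.d. uniform(0,1) from the run seed; **H starts as
all-ones** and becomes data-driven at its first multiplicative update.
Keeping the randomness in W alone makes every run exactly equivariant
under sample (column) permutations of V, so consensus matrices permute
with the samples rather than only in distribution.

Consensus and rank selection: each run hard-assigns every sample to the
component with its maximal coefficient (argmax over the H column — the
long-standing NMF-consensus convention); the consensus matrix holds the
fraction of runs in which two samples co-assign. The cophenetic
correlation compares (1 − consensus) with the cophenetic distances of its
own average-linkage dendrogram; an all-equal distance matrix is assigned
correlation 1 (the tree reproduces it exactly). The selected rank
maximizes cophenetic correlation, ties going to the smallest rank.
Per-rank diagnostics also include the best-run rss, the explained-variance
dispersion `1 − rss/ΣV²`, and the absolute-residual sum.

## The EC index

For annotation *i* and component *k*:

- ρ(i,k): Spearman correlation between the annotation's per-million
  abundance profile and the component's coefficient profile (average ranks
  for ties; constant profiles are assigned ρ = 0 and flagged). The
  per-million matrix (not the Hellinger one) feeds ρ and Cosθ by default
  because the index reads abundance covariation, not ordination geometry; a
  flag switches the input.
- Cosθ(i,k): both profiles are L2-normalized, so the "multidimensional
  projection" is a true cosine in [0,1] for non-negative data (a
  sum-to-one normalization is available behind a flag).
- Score(i): entropy specificity of the basis row,
  `1 + (1/log₂ q) Σₖ p(i,k) log₂ p(i,k)` with `p(i,k) = W(i,k)/Σₖ W(i,k)`
  and `0·log 0 ≡ 0`. Row-normalizing W is the only construction that reads
  "probability of finding annotation i in component k" off the basis
  matrix. Point-mass rows score 1, uniform rows 0, all-zero rows 0
  (flagged).

I(i,k) = ρ × Cosθ × Score lies in [−1, 1] since each factor is bounded by 1
in magnitude. Every annotation contributes one index per component, so a
component's index distribution has one value per annotation.

Group comparisons mirror the permutational-ANOVA-then-t workflow:
a univariate one-way permutation F-test (p = (1 + #{F* ≥ F})/(1 + n_perm);
exhaustive enumeration of distinct label arrangements whenever there are at
most 10,000), followed by pairwise Student t-tests that reuse the pooled
residual variance s² = SSW/(N−g) with N−g degrees of freedom and a 0.05
significance flag.

## Pathways, fractions, genomes

Marker selection priority: (1) ring-opening / ring-oxidation /
ring-reduction reactions whose EC occurs in no other catalog pathway;
(2) CoA-addition or side-chain-oxidoreduction reactions under the same
uniqueness rule; an EC shared by exactly two pathways and found nowhere
else is granted to the lexicographically smaller pathway id (a
deterministic stand-in for an arbitrary choice between the pair); pathways
with no qualifying reaction get no marker. At most one marker per pathway,
no EC marks two pathways.

Sample-level pathway completeness counts **distinct** ECs present
(abundance strictly above a configurable threshold, default 0) over the
pathway's distinct ECs. MAG-level scores instead divide ECs present by the
**number of reactions** and normalize by MAG completeness/100 — low
completeness inflates the ratio, so the normalized value is capped at 1
(toggleable). A MAG is called enriched when the median over all funneling
pathways — zeros included — strictly exceeds 0.04; ring-fission pathways
are excluded because they also serve non-lignin substrates. Quality
thresholds are strict (> 30% completeness, < 10% contamination), as are
the enrichment (> 4%) and genomospecies (ANI > 95%) cutoffs; the
recruitment minima (≥ 100 bp, ≥ 98% identity) are inclusive. Genomospecies
are single-linkage connected components of the ANI graph, so chains of
>95% links merge transitively. The genome-fraction estimator divides
distinct gene-variant clusters carrying a KO by distinct recA (K03553)
variant clusters; it assumes one copy per genome and can exceed 100% when
paralogs are common.

## Synthetic communities

The generator emulates a stratified survey: 4 water features × 6 samples,
300 enzyme functions of which 15 per feature are disjoint signatures. The
background is log-normal (μ = 1, σ = 1) — functional abundances are
heavy-tailed — while signature backgrounds use a narrower σ = 0.3:
degradation-pathway genes sit in the mid-range of abundance, not in the
housekeeping tail, and this keeps the four signature blocks comparable in
mass. A signature is enriched 8-fold in its home feature and, because the
water column is a gradient with fuzzy boundaries, 8^0.15 ≈ 1.37-fold in
the two adjacent features. Per-cell noise is multiplicative log-normal
with σ = 0.7, the sample-to-sample coverage variability we consider
realistic for replicate metagenomes. Library sizes are fixed at 10⁶ reads
per sample. Each sample also carries 20 single-copy recA variant clusters
so genome-fraction estimates run end to end. One master RNG per generator;
per-sample streams are spawned deterministically, so a fixed seed gives
byte-identical output.

At these defaults the full procedure recovers the planting: the consensus
survey (30 runs, ranks 3–7) selects rank 4, and ≥90% of signature
annotations attain their maximal index in their home feature's component
(both exercised in the acceptance suite over seed sweeps; problem sizes
there — 24 samples × 300 annotations, 10–30 runs — are the package's
test-scale choices).

What the generator does **not** emulate: phylogenetic correlation between
functions, co-varying pathway modules, compositional closure effects,
read-level sequencing error (no FASTQ), assembly/binning artifacts, or
real taxon abundances (taxon labels come from a small fixed vocabulary).
Passing tests therefore demonstrate that the statistical machinery recovers
planted structure of this specific shape, not that it is robust to every
failure mode of real survey data.

MAG simulation plants enrichment by construction: enriched MAGs carry the
complete EC sets of a majority of funneling pathways at 70–95%
completeness; background MAGs touch strictly fewer than half (median score
exactly 0) and straddle the quality thresholds (one fails completeness at
25%, one fails contamination at 12%). ANI blocks are drawn at 96–99.5%
within planted genomospecies and 80–88% between. Recruitment hits pass the
(100 bp, 98%) filter independently with a configured probability, and
secondary hits always score strictly below the primary unless tie
injection is requested.

## Known limitations

- TMM's weighted variant is only approximately invariant to rescaling one
  sample's depths (the precision weights depend on magnitude); the
  unweighted variant is exactly invariant.
- Consensus clustering uses argmax assignments; samples with near-tied
  coefficients can flip between runs, which is informative for rank
  diagnostics but makes individual consensus entries noisy at small run
  counts.
- nsNMF multiplicative updates converge to local optima; all multi-run
  statistics assume the seeded restarts sample the landscape adequately.
- The pipeline treats metagenome and metatranscriptome assays
  independently; no cross-assay matching of annotations is attempted.
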