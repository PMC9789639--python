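# aromdeg

Tools for locating and attributing **aromatic-compound-degradation
capacity** in stratified ocean microbiomes from functional metagenome and
metatranscriptome annotations.

Water columns such as the salinity-stratified Arctic basins are layered
into distinct features (surface mixed layer, subsurface chlorophyll
maximum, the humic-rich FDOMmax, deep waters), and the enzymatic repertoire
of the microbiome is partitioned along the same layers. `aromdeg`
implements the full analysis chain that turns per-gene coverage tables into
that attribution:

1. **Functional profiles** — EC/KO abundance matrices built by summing gene
   coverage depths, normalized to copies per million reads with TMM
   (trimmed mean of M-values) composition factors, and Hellinger-transformed
   for multivariate analysis.
2. **Ordination** — Bray–Curtis dissimilarities and 2-D nonmetric
   multidimensional scaling (Kruskal stress-1).
3. **Sub-metagenome decomposition** — non-smooth non-negative matrix
   factorization (nsNMF): V ≈ W·S·H with smoothing
   S = (1−θ)I + (θ/q)·11ᵀ, run many times per candidate rank; the rank is
   chosen by the cophenetic correlation of the run-consensus matrix.
4. **The EC index** — for annotation *i* and component (sub-metagenome) *k*,

   I(i,k) = ρ(i,k) × Cosθ(i,k) × Score(i)

   where ρ is the Spearman correlation between the annotation's abundance
   profile and the component's coefficient profile, Cosθ the cosine between
   the L2-normalized profiles, and
   Score(i) = 1 + (1/log₂ q) Σₖ p(i,k) log₂ p(i,k) the entropy specificity
   of the row-normalized basis matrix. I ∈ [−1, 1]; values near 1 mark
   enzyme functions specific to one component. Group contrasts of index
   distributions use a univariate permutational ANOVA with pairwise Student
   *t*-tests on the pooled residual variance.
5. **Pathway analytics** — marker-reaction selection (ring-attacking
   reactions first, CoA-addition/side-chain fallbacks), per-sample pathway
   completeness, the aromatic gene fraction, and recA-normalized
   genome-fraction estimates (fraction of genomes carrying a KO).
6. **Genome analytics** — MAG quality filtering (>30% completeness, <10%
   contamination), enrichment selection by the median
   completeness-normalized funneling-pathway score (>4%), genomospecies
   clustering at ANI > 95%, recruitment best-hit filtering (≥100 bp, ≥98%
   identity), and RPKG.
7. **Synthetic communities** — a seeded generator that plants K water
   features with disjoint signature functions on a heavy-tailed background,
   pathway-bearing MAGs, block-structured ANI matrices, and recruitment
   hits, with ground truth returned for every planting.

Core computations are scikit-learn-style estimators (`NSNMF`, `NMDS`,
`TMMNormalizer`, `ANIGenomospecies`) that compose with sklearn pipelines;
module-level functions wrap them.

## Worked example

Run the whole pipeline on a simulated four-feature community (24 samples,
300 enzyme functions, 15 signatures per feature):

```bash
aromdeg run-all --seed 1 --outdir demo_out
# selected rank 4; 20 artifacts in demo_out
```

The rank survey picks four sub-metagenomes (cophenetic correlation is
maximal at rank 4):

```
rank  cophenetic  rss    dispersion
3     0.9845      2.498  0.8959
4     1.0000      2.069  0.9138
5     0.9988      1.877  0.9218
```

each labeled by the water feature of its samples (surface, SCM, FDOMmax,
deep — 6 samples each). The top of the index table shows single-component
specialists (Score ≈ 1, high ρ and Cosθ):

```
annotation component_label   rho  cos_theta  score  index
    EC0257         surface 0.824      0.961  1.000  0.792
    EC0292         FDOMmax 0.837      0.933  1.000  0.780
    EC0017             SCM 0.839      0.799  1.000  0.670
```

and the aromatic-vs-other contrast singles out the humic-rich FDOMmax
component, where the planted aromatic-degradation ECs live
(mean index 0.229 vs 0.006 for other functions; t = 10.7, p < 10⁻⁴):

```
  component  mean_aromatic  mean_other       t    p_t
component_1        -0.0380      0.0192 -2.0179 0.0445
component_4         0.2292      0.0055 10.6976 0.0000
```

Consistently, the aromatic gene fraction peaks in the FDOMmax samples
(11.8% vs 1.7–2.9% elsewhere in this simulation). Every artifact (abundance
matrices, NMDS coordinates, consensus and basis/coefficient matrices, index
tables, pathway completeness, MAG scores, genomospecies, RPKG) is a TSV in
`demo_out/`, with seeds and SHA-256 digests in `manifest.json`; rerunning
with the same seed reproduces the digests byte for byte.

## Layout

- `src/aromdeg/` — `profiles`, `ordination`, `factorization`, `indices`,
  `pathways`, `genomes`, `synthetic`, `pipeline`, `cli`, `io`
- `tests/` — unit, property (hypothesis), and acceptance suites
- `docs/methods.md` — models, parameter choices, and limitations
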