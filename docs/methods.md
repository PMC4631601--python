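# Methods

This note documents the statistical models, the synthetic data-generating
process, numerical choices, and the design decisions that were genuinely
open, in the order the pipeline runs them.

## Taxon preprocessing

Counts arrive as one row per (individual, season, technical replicate).
The canonical order of operations is fixed and tested: subsample →
combine replicates → relative abundance → prevalence filter → inverse
normal transform → correlation prune.

**Subsampling.** Replicates above the depth cap (default 2,000,000 reads)
are drawn down without replacement — a multivariate hypergeometric draw —
so expected taxon proportions are preserved exactly; replicates at or below
the cap pass through unchanged.

**Prevalence.** A taxon is kept when it has ≥ 1 read in at least 75% of
individuals, boundary inclusive ("at least"). Rare taxa contribute almost
no association power and inflate the multiple-testing burden.

**Inverse normal transform (INT).** Value of rank r maps to
Φ⁻¹((r − a)/(n + 1 − 2a)) with the plotting-position offset a = 3/8 for
n ≤ 10 and a = 1/2 otherwise — the documented convention of R's
`qqnorm`/`ppoints`, which this transform mirrors. Ties receive the average
of their ranks before transformation; constant taxa are an error (they
should have been filtered upstream). For n = 3 the transform of (1, 2, 3)
is (−0.8694, 0, 0.8694), a frozen worked value in the tests.

**Correlation pruning.** While any pair of taxa has Pearson r ≥ 0.9, the
pair with the largest r (ties broken lexicographically) is resolved: across
taxonomic levels the broader-level taxon is removed (a genus and its family
at r ≈ 1 carry one signal; the finer label is more informative), at the
same level the alphabetically first is removed. Remaining pairs are
re-checked after each removal. The iteration order is our choice — any
fixed order gives a deterministic result, and the whole procedure is tested
against a brute-force enumeration oracle on tables of ≤ 12 taxa.

**Season combining.** For the combined analysis, taxa are first restricted
to those passing prevalence in *both* seasons; each season is transformed
separately; dual-season individuals get the mean of their two INT values;
pruning runs after averaging. A PCA QC utility tests the top 10 principal
components of the combined matrix against any user-supplied binary label
(e.g. season membership); the label is user-supplied because season is
genuinely ambiguous for averaged individuals.

**Alpha diversity.** Genus-level richness S, Shannon H = −Σ pᵢ ln pᵢ
(natural log) and Pielou evenness J = H/ln S, computed from raw counts
without normalization; J is undefined (reported missing) for S = 1.

## Genotype QC and relatedness

SNP filters: MAF ≥ 5% (computed on non-missing calls), call rate ≥ 95%,
exact Hardy–Weinberg p ≥ 0.001; all inclusive. The HWE test conditions on
the observed allele counts and sums the probabilities of every heterozygote
count no more probable than the observed one; it matches an exact-rational
enumeration oracle for all configurations up to 30 alleles. A second MAF
filter (≥ 10%, strictly-below removed) is recomputed on each analysis
subset before association testing. Mendelian-error filtering requires
pedigree records and is out of scope; the QC report says so.

Relatedness is the centered genomic relationship matrix (GRM),
K = (1/p) Σₛ (gₛ − 2fₛ)(gₛ − 2fₛ)ᵀ, with per-SNP mean imputation of missing
dosages and monomorphic SNPs skipped. A `standardized` variant divides each
SNP term by 2fₛ(1−fₛ). A pedigree-informed IBD matrix would be preferable
when a pedigree exists; the GRM plays the same role as the random-effect
covariance and is the standard substitute.

## The linear mixed model

Model: y ~ N(Xβ, σ²_g K + σ²_e I). With K = U D Uᵀ and λ = σ²_g/σ²_e, the
rotated model has diagonal covariance σ²_e(λD + I); β and σ²_e are profiled
out analytically and the profiled (restricted) log-likelihood is maximized
over log₁₀ λ ∈ [−5, 5] by a 50-point grid followed by bounded Brent
refinement — the grid guards against the multimodality of the profiled
surface, and a boundary flag is raised when λ̂ pins at the range edge.
Eigendecomposition is done once per kinship matrix and reused across
traits, SNPs and permutations.

**Association tests** are likelihood-ratio tests with ML fits (REML
likelihoods are not comparable across fixed-effect changes): p = P(χ²₁ ≥
2(ℓ₁ − ℓ₀)), negative statistics clipped to zero. In the genome scan the
alternative-model λ is re-optimized per SNP on a 41-point log grid with a
parabolic refinement, all SNPs vectorized; a `fast` mode reuses the
null-model λ for every SNP, reducing each test to a weighted simple
regression in which the whole scan is three matrix products. Fast mode is
the default inside permutation loops only.

**Chip heritability (PVE)** uses REML with an intercept design on
covariate-residualized traits: PVE = c·σ̂²_g/(c·σ̂²_g + σ̂²_e) with
c = tr(K)/n, so K keeps its natural scale. The SE is the delta method
applied to the numerically inverted observed information of (σ²_g, σ²_e)
(central differences, one-sided at the σ²_g ≥ 0 boundary). The estimate is
flagged non-zero when PVE − SE > 0. Two caveats are documented rather than
hidden: (i) the SE estimator of the original variance-component software is
not published, so this choice is validated by simulation only; (ii) for a
boundary-truncated REML estimator with an accurate ±1-SE rule, the null
flag rate is inherently ≈ P(Z > 1) ≈ 0.15 of the unconstrained sampling
distribution — we verified that the observed-information, expected
(Fisher)-information and log-λ profile-curvature SEs all give the same null
flag rate, so a materially lower false-flag rate would require a
deliberately conservative SE, which we do not apply.

**Multiple testing.** Storey q-values with the smoother π̂₀ (cubic spline
over λ ∈ 0.05…0.95); with fewer than 100 p-values the smoother is unstable
and π₀ falls back to 1, making the result exactly Benjamini–Hochberg.
Bonferroni and q-value calls are made within each GWAS; the study-wise
Bonferroni threshold α/Σ(traits × SNPs) is reported separately.

**Overlap permutation.** The number of taxa both flagged heritable and
carrying ≥ 1 genome-wide hit is compared to the distribution obtained by
permuting the heritability flags across taxa; empirical p =
#(perm ≥ observed)/n_perm, which can be exactly 0 — a `plus_one` option
applies the (count+1)/(n_perm+1) correction for users who prefer the
strictly positive estimator.

## Candidate-tissue enrichment

Cell lines are represented by binary presence vectors over the merged union
of all peak intervals and clustered by average-linkage hierarchical
clustering on Euclidean distances, cut into k groups (k = 16 for the real
DHS compendium; 5 in the synthetic studies). The linkage is our choice —
only the distance is canonical — and is deterministic given input order.
Per tissue, the peak set is the base-pair *intersection* across member cell
lines (a `union` alternative exists and is flagged as a deviation when
used; intersection across many heterogeneous lines is conservative).

All interval arithmetic is 0-based half-open; a SNP at position p overlaps
[s, e) iff s ≤ p < e. The SNP × tissue membership mask is computed once and
reused across traits and permutations.

Fold enrichment per tissue and threshold t: (in-peak fraction among SNPs
with p ≤ t) / (in-peak fraction among all tested SNPs), over the ladder
1.0, 0.5, 0.1, 0.05, 0.01, 0.005, 0.001, 5e-4, 1e-4, 5e-5, 1e-5, 5e-6,
keeping only bins with ≥ 50 SNPs. Significance of the smallest retained bin
comes from whole-GWAS permutation: trait values are shuffled across
individuals, the scan re-run (fast mode, null λ refit per permutation, all
SNPs batched), and the same number of top SNPs scored. Because only trait
labels move, the null preserves genotype and peak structure — including any
correlation between SNP density and peaks. Reported empirical p-values are
not corrected across tissues, and the output header says so.

## Synthetic data

The generator emulates a communal founder population sampled in two seasons
with technical replicates. What it reproduces, and what it does not:

* **Genotypes**: non-overlapping sibships; each family has two simulated
  parents and each child draws one haplotype per parent independently per
  SNP. True kinship is block-structured (1 diagonal, 0.5 within family, 0
  between; a monozygotic option makes sibs identical). SNP allele
  frequencies are uniform on the configured MAF range. There is **no
  linkage disequilibrium** beyond family sharing — real array data has LD,
  so synthetic enrichment signals are carried only by the causal SNPs
  themselves, not by proxies. Passing tests therefore demonstrate method
  correctness, not realistic LD-mediated behaviour.
* **Taxon counts**: per-taxon latent trait z = planted per-allele effects +
  polygenic term with variance h² (drawn from the true kinship) + sex/age/
  collection-group effects + N(0, 1−h²) noise; counts per replicate are
  multinomial over softmax(α + z + season shift), with α ~ N(0, 2) giving a
  realistically skewed abundance profile. The softmax makes counts
  compositional: a strong effect on one taxon induces small opposite
  effects on others, as in real relative-abundance data.
* **DHS peaks**: each tissue has an archetypal peak set on non-overlapping
  slots (default 1,500 peaks of 300 bp on a 5 Mb genome, ~9% coverage);
  cell lines keep each archetype peak with probability 0.95 and add a
  matching number of private peaks. Causal SNPs are covered by core peaks
  present in every causal-tissue cell line and excluded from other tissues'
  archetype slots.

**Randomness**: one root seed; each generator derives a child stream from a
fixed offset, so outputs are reproducible individually and jointly.

## Study conditions used by the tests and the acceptance script

* LMM calibration: n = 300 in 60 sibships of 5, 5,000 SNPs, four null
  polygenic traits (h² = 0.4) — 20,000 tests; type-I error at α = 0.05 and
  median genomic-control λ.
* PVE recovery: n = 400 in 80 sibships, 100 traits per h² ∈ {0, 0.3, 0.6},
  estimated against the true block kinship.
* QTL recovery: 1-SD per-allele effect at the SNP closest to MAF 0.3,
  n = 300, 5,000 SNPs, polygenic background h² = 0.3, 100 cohorts.
* Tissue-enrichment recovery: one strongly heritable polygenic taxon with
  20 causal variants of 0.5 SD each, all inside the causal tissue's peaks
  (the regime the method targets: a heritable taxon whose regulatory
  variants concentrate in one tissue); n = 200, 5,000 SNPs, 5 tissues × 4
  cell lines, 200 permutations per cohort; 100 cohorts in the test suite,
  50 in the acceptance script.
* Recovery and calibration studies use the *pedigree* (true block) kinship
  as the random-effect covariance, the analogue of a pedigree-derived IBD
  matrix. Using the SNP-derived GRM instead absorbs part of the causal
  SNPs' own variance into the random effect (proximal contamination) and
  visibly deflates their association signal; the GRM remains the default
  for file-based analyses where no pedigree exists.

## Known limitations

* No LD, no X-chromosome handling, no genotype imputation beyond per-SNP
  means, no multi-component variance models, no binary traits.
* The PVE standard error is asymptotic; with ~100–400 related individuals
  the ±1-SE non-zero rule has the null behaviour quantified above.
* Empirical permutation p-values are reported as count/n_perm and can be
  zero; resolution is limited by n_perm.
* The intersection rule for tissue peaks becomes extremely conservative as
  the number of cell lines per tissue grows; the union option trades
  specificity for coverage.
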