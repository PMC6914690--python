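# Methods

`xqtl` implements a cross-species systems-genetics pipeline: quantitative
trait loci (QTL) mapped in a two-founder recombinant-inbred (RI) mouse panel
are carried across species through homology and screened against human GWAS
evidence at the gene level, then followed up with coexpression and
disease-catalog enrichment. This note records the models, the parameters
that matter, what the synthetic-data generators do and do not emulate, and
the numerical decisions taken where the design was open.

## QTL mapping on strain means

The panel is fully inbred: every strain is homozygous B (first founder) or D
(second founder) at every marker, coded additively B → −1, D → +1, so a
positive additive effect always means "the D allele raises the trait". At
each marker the strain-mean trait is regressed on the additive code by
ordinary least squares and scored with the likelihood-ratio statistic

    LRS = n · ln(RSS0 / RSS1),      LOD = LRS / (2 ln 10),

where RSS0 is the intercept-only residual sum of squares. Because the
predictor is binary, the fitted group means saturate the alternative model
and the OLS slope equals half the D-minus-B difference in allele-group
means. Internally the scan uses the identity LRS = −n·ln(1 − r²) with r the
trait–genotype correlation, which lets thousands of scans (permutations,
calibration replicates) run as one matrix product. A perfect fit (RSS1 = 0)
is reported as the finite sentinel LRS = 9999 with a `perfect_fit` flag so
scan tables stay serializable; monomorphic markers score 0 and are flagged.

Genome-wide significance uses the standard permutation scheme: trait values
are shuffled across strains (default 5,000 shuffles) with genotypes fixed,
which breaks the trait–genotype pairing while preserving marker LD; the
threshold is the (1 − α) empirical quantile (linear, "type 7" interpolation)
of the per-shuffle maximum LRS. Support intervals use the 1.5-LOD drop rule:
the interval runs outward from the peak to the first flanking markers whose
LOD falls below peak − 1.5, clipped to chromosome ends. An expression-QTL
peak is called *cis* when it lies on the gene's chromosome within a 5-Mb
window of the gene body (configurable), else *trans*.

Mixed-model (kinship-corrected) scanning is deliberately absent: the scan
models strain means of an RI panel, where the single-marker regression is
the classic first-pass mapping procedure.

## Gene-based association (GATES)

SNP p-values inside a gene (span ± a window, default 0 kb, closed intervals)
are combined with the extended-Simes statistic

    p_gene = min_j  Me · p_(j) / Me(j),

where p_(1) ≤ … ≤ p_(M) are the sorted SNP p-values and Me(j) is the
effective number of independent tests among the j most significant SNPs,
computed from the eigenvalues λ of their p-value correlation matrix as
Me(j) = j − Σ_i I(λ_i > 1)(λ_i − 1), clipped to [1, j]; Me = Me(M). Under
identity LD this reduces exactly to the Simes combination; under perfect LD
to min p (implemented exactly: a fully saturated correlation block counts as
one effective test without consulting the eigensolver).

The p-value correlation is approximated from the dosage correlation r of an
external LD reference panel. Two transforms are available: the degree-six
polynomial fit published with the method (default) and plain |r|. The
default matters: in a null calibration with 10,000 synthetic 10-SNP genes
(AR(1) blocks, adjacent correlation 0.6, 300 reference individuals) the
polynomial transform keeps the fraction of genes with p_gene ≤ 0.05 at
≈ 0.052–0.055, inside the 99% binomial band around 0.05, while |r|
overstates the p-value correlation and inflates the rate to ≈ 0.069.
Feeding the *exact* block correlation instead of the panel estimate gives
0.0506 — the residual inflation is attributable to LD-estimation noise in
the finite reference panel, a property the real procedure shares with any
reference-panel-based method. Transformed matrices can be slightly
indefinite, so they are projected to the nearest positive-semidefinite
matrix (eigenvalue clipping at 0) before the prefix eigendecompositions;
ties in p are broken by SNP id so results are input-order invariant.

## Cross-species integration

Mouse genes overlapping a significant QTL interval (closed-interval overlap,
Mb units; a magnitude heuristic rejects accidental bp input) are mapped to
their human homologs through an explicit homology table in which
one-to-many pairs are allowed in both directions. The multiple-testing
burden N for Bonferroni selection counts *distinct* human homologs with a
gene-based p-value across all analyzed traits jointly; homologs absent from
the gene-based results are reported as untested rows and excluded from N
(counting untestable genes would deflate the threshold without adding any
test). A candidate is flagged nominal when p ≤ α and corrected when
p ≤ α/N, both with the ≤ rule so boundary values pass. On the bundled
worked example (two QTL intervals, 11 mouse genes, 12 distinct homologs) a
gene-level p of 0.0117 is nominal but not corrected-significant
(0.0117 > 0.05/12 ≈ 0.00417); the package reports both flags and does not
adjudicate between them.

## Coexpression and eigengenes

A seed transcript is correlated against every row of an expression matrix
(Pearson by default, Spearman optional) over pairwise-complete strains;
two-sided p-values come from the t transform (also applied to Spearman's
rho — adequate at the panel sizes used here; exact small-n Spearman tails
are not implemented). The screen keeps genes with |r| ≥ 0.5 and p ≤ 0.05 by
default, both inclusive (the ≤ rule is applied uniformly), ordered by |r|
descending then id. When a gene has several probes they are standardized
(zero mean, unit variance; missing values mean-imputed inside the PCA only)
and collapsed to the first principal component — an eigengene, one score
per strain, variance explained reported. The PC sign is arbitrary, so it is
fixed to correlate non-negatively with the mean standardized probe.

## Disease-gene enrichment

The observed statistic is the overlap k between the coexpression set
(size n) and the disease catalog, both restricted to the expression
background (N genes, K of them in the catalog). Catalog rows mapping several
genes expand to one record per gene before intersection. The permutation
null redraws n genes uniformly without replacement from the background,
100,000 times by default. Two p-values are reported: the strict estimate
#{overlap > k}/n_perm (a zero prints as "< 1/n_perm", since the estimator
cannot resolve below its own floor) and the smoothed default
(#{overlap ≥ k} + 1)/(n_perm + 1), which is never exactly zero. The null is
exactly hypergeometric, so the analytic upper tail P(X ≥ k) is computed
alongside (scipy's log-space survival function) as a permanent cross-check;
on toy configurations the smoothed estimate agrees within 3 Monte-Carlo
standard errors, including the exact case P = 1/C(10,3) = 1/120 for
N=10, K=3, n=3, k=3.

Permutations are drawn in fixed chunks of 1,024 from a counter-based Philox
stream keyed by (seed, chunk index), so results are reproducible and
independent of chunk execution order.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline reads, with the statistical
structure the analysis assumes:

- **RI genotypes** are per-strain, per-chromosome Markov mosaics. Map
  distances convert to per-meiosis recombination fractions by the Haldane
  function r = (1 − e^(−2d))/2 (no interference), then expand for repeated
  inbreeding: R = 4r/(1 + 6r) for sib-mated panels (the default — two-founder
  mouse RI panels are sib-mated), R = 2r/(1 + 2r) for selfing. Adjacent-marker
  discordance converges to R (verified to 3 Monte-Carlo SE at 4,000 strains).
- **Traits** follow y = a·g + e with Gaussian e scaled from the realized
  genotype variance so the causal marker explains h² of the variance in
  expectation; h² = 0 yields pure noise.
- **LD panels** draw haplotypes per block by a copy-or-refresh chain whose
  allele correlation is exactly ρ between neighbors and ρ^k at lag k
  (AR(1)), independent across blocks; dosages are sums of two haplotypes.
- **GWAS summaries** draw z ~ MVN(Rλ, R) with R the panel's (ridge 1e-6)
  LD correlation and λ per-SNP noncentralities, p = 2Φ(−|z|); the global
  null gives marginally uniform p-values.
- **Expression** mixes one latent factor per module (loading L, noise s,
  expected pairwise r = L²/(L² + s²)) with optional cis effects of a marker
  genotype; background genes are independent noise.
- **Annotation/homology** tables place non-overlapping genes and assign 0,
  1 or 2 human homologs per mouse gene at configurable fractions.

Not emulated: heterozygosity and genotyping error, interference-aware map
functions, realistic allele-frequency spectra and haplotype sharing beyond
AR(1) blocks, population stratification, probe-level artifacts, and any
real genome's gene density. Passing tests therefore certify the
*procedures* — calibration of the permutation threshold, validity of GATES
under block LD, agreement of the permutation null with its analytic form,
recovery of planted signals — not performance on any real dataset, whose
headline values depend on cohorts and catalogs this package does not ship.

## The planted end-to-end scenario

`xqtl.scenario.build_scenario` wires one ground truth through every input:
80 strains on two 60-cM chromosomes mapped at 2-cM density, a causal marker
mid-chromosome with h² = 0.5, a mouse gene straddling it, 10 human homologs
(one mouse gene with a paralog split, one with none), 8 SNPs per human gene
in ρ = 0.6 blocks over 300 reference individuals, noncentrality 6 at one
SNP of the target homolog, a 12-gene coexpression module sharing a
cis-eQTL at the causal marker, and a catalog covering half the module. At
these settings the full pipeline reports the planted homolog as the unique
Bonferroni-significant candidate in ≈ 98 of 100 seeded runs.

## Determinism and problem sizes

A single master seed drives everything; per-stage seeds are derived by
SHA-256 of "master:stage-name" (reduced below 2³¹), so adding a stage never
perturbs another stage's stream. Identical config + seed reproduces
byte-identical output tables.

The validation suite runs the calibration studies at their full stated
sizes — 500 null traits × 5,000 permutations for threshold calibration,
10,000 null genes for GATES, 100,000 permutations for enrichment, 100 runs
for each recovery study — at small panel dimensions (50–80 strains, tens of
markers, tens of SNPs per gene) chosen so each study completes in seconds
on one core while keeping Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

- Single-marker scans only: no interval mapping between markers, no
  multi-QTL or epistasis models, no kinship correction.
- The GATES p-value correlation transform is an approximation either way;
  the polynomial fit is adopted for calibration, not derived here.
- Spearman p-values use the t approximation (no exact small-n tails).
- Enrichment treats genes as exchangeable under the null; it does not model
  LD-aware catalog gene assignment or gene length bias.
- TSV dialects only; binary formats (PLINK/VCF/BAM) are out of scope.
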