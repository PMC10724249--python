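# Methods

This note documents the models implemented in `apaqtl`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical conventions that matter when reading the code.

## Two-site APA model and PDUI

A 3'UTR is assumed to express exactly two isoforms: a *long* isoform
covering the full annotated UTR and a *short* isoform covering only the
region upstream of a proximal polyA site shared by all samples of a
transcript.  Expected per-base coverage is then piecewise constant:
`w_short + w_long` upstream of the proximal site, `w_long` downstream.  For
a candidate breakpoint the least-squares abundances are the two segment
means, constrained to `m_up >= m_down >= 0`; when the unconstrained means
violate the ordering the constrained optimum collapses to the pooled mean
with `w_short = 0`.  The breakpoint is chosen to minimize the residual sum
of squares **summed over samples** (joint fitting), with ties broken to the
most distal candidate so that a flat track deterministically reports
PDUI = 1.  The search keeps a 50-nt margin from both UTR ends (degenerate
end fits would otherwise always win on one-point segments) and steps 1 nt
for UTRs up to 2 kb, 5 nt beyond, bounding cost on long UTRs.

PDUI per sample is `w_long / (w_long + w_short)`, undefined (masked) when
both weights are zero.  Normalization is per-sample library-size scaling to
a fixed target depth — the simplest scheme consistent with comparing
"normalized reads" across samples; any scheme proportional to it yields
identical PDUI because the index is scale-free (tested).

Filters: an entry is missing when its mean normalized UTR coverage is
<= 20 (strict "> 20" keeps), and a transcript is dropped when missing in
strictly more than 50% of samples.  Filtering is applied **after** joint
fitting, so low-coverage samples still contribute (weakly) to breakpoint
localization but never report a PDUI.

## Synthetic cohorts

The generator inverts the quantifier's model so that model faithfulness is
testable: with noise disabled, quantifying the expected coverage returns
the true per-sample PDUI exactly.

* **Genotypes.** Haplotypes are thresholded latent AR(1) Gaussians
  (rho = 0.9) within LD blocks, giving positive within-block r and
  independence across blocks; allele frequencies are uniform on
  `maf_range`.  With `fst > 0` the cohort splits into two equal
  populations whose frequencies are Beta-distributed around a shared
  ancestral value (Balding–Nichols); the planted differentiation is
  recovered by the Hudson FST estimator within +-0.03 in tests.
* **True PDUI.** Per gene: a baseline usage drawn U(0.25, 0.75); an
  additive genotype term (`effect_size` per alternative allele at the
  causal SNP, for the `aqtl_fraction` of genes that have one); a condition
  term (`stim_shift = -0.2` applied to `stim_shift_fraction = 20%` of genes
  upon stimulation, emulating global 3'UTR shortening on immune
  activation); and independent donor-level Gaussian noise
  (`pdui_noise_sd = 0.1`).  The donor noise represents biological
  inter-individual dispersion of APA usage; without it the only phenotype
  noise is Poisson counting error (~0.01 PDUI at 50x), association power
  saturates at tiny effects and power comparisons are degenerate.  0.1 was
  chosen once as a realistic dispersion for interior PDUI values.  The sum
  is clipped to [0.02, 0.98].
* **Coverage.** Poisson counts per base around the two-segment expectation
  at mean `depth` (default 50x) — chosen because sequencing coverage is
  count data with a simple mean/variance oracle.  Tracks are emitted in
  genomic orientation (minus-strand genes reversed), as a bedgraph would
  store them.
* **Response structure.** Of the aQTL genes, `response_fraction` (default
  0.3) have their genetic effect only in non-baseline conditions; the rest
  share it across all conditions.  Conditions are repeated measures of the
  same donors on one genotype matrix.
* **GWAS summary statistics** are generated analytically rather than by
  simulating a phenotype cohort: under a single causal SNP c with
  noncentrality z_c, E[z_i] = r_ic z_c and Cov(z) = R, the realized LD
  correlation of the panel; z is drawn from that multivariate normal and
  converted to beta/se with se = 1/sqrt(2 f (1-f) n).  This is exact under
  standard GWAS asymptotics, fast, and gives precisely controlled truth
  for colocalization and SMR.  The causal z can be set directly or derived
  from a per-SNP heritability.

What the generator does **not** emulate: read-level errors and alignment
artifacts, realistic human LD maps and allele-frequency spectra, more than
two isoforms per UTR, trans effects, cell-type deconvolution, and
expression-level confounding of coverage.  Passing tests therefore show
that the *statistical machinery* is correct and calibrated under the
model's assumptions, not that those assumptions hold in any particular
real dataset.

## cis-QTL mapping

Ordinary least squares of PDUI on dosage plus covariates, computed by
Frisch–Waugh partialling: phenotype and dosages are residualized against
the covariate design once per gene, after which per-SNP slope, standard
error and two-sided t-test follow from cross-products.  This equals the
full-design OLS exactly (tested to 1e-8 against a normal-equations solver)
and makes the permutation loop a single matrix product per gene.

Covariates: optional known covariates (ancestry-group indicators when two
populations are merged, genotype PCs) plus hidden factors — the top k
(default 10) left singular vectors of the standardized PDUI matrix,
playing the role PEER-style latent factors play in expression QTL
pipelines.  PCs are the standard lightweight surrogate; the number of
latent factors is a documented choice, not an estimate.  When the genomic
inflation factor exceeds 1.05 the known genotype PCs escalate from 3 to 10
and the condition is re-mapped.

The gene-level null shuffles individual labels of the phenotype vector
jointly for all cis SNPs (preserving LD and the covariate alignment with
genotypes).  Empirical p carries a +1 pseudocount:
`(1 + #{perm min-p <= observed}) / (n_perm + 1)` — never zero, and exactly
1/(n_perm+1) when the observed minimum beats every permutation.  Gene
significance uses Storey q-values (pi0 from the smoother estimate on a
lambda grid) at q < 0.05; SNP-level calls are Benjamini–Hochberg at 5% on
nominal p-values within significant genes.  The alternative reading of the
SNP-level rule (a permutation-derived nominal threshold) is noted in the
code; BH over significant genes' SNPs is the implemented default.

"At least 10 counts per allele" is implemented as minor-allele dosage sum
>= 10 (allele copies, not genotype classes); MAF exactly 0.01 survives the
strict "< 0.01" filter.  The cis window is +-1 Mb around the 3'UTR
midpoint.  Missing PDUI entries drop the donor for that gene's scan;
`n_used` is recorded per association.

A note on permutation resolution: with 200 permutations the empirical-p
floor is 1/201, so across a 200-gene cohort the Storey cut at q < 0.05
behaves almost dichotomously (all floor-level genes pass or none do).
Power comparisons across effect sizes therefore use the full 1,000
permutations, which the vectorized scan affords comfortably at cohort
sizes of 80–200 donors and 200 genes.

## Multivariate shrinkage, sharing, response calls

Effects of the lead SNP per gene across R conditions are modelled as
`bhat_j ~ N(b_j, S_j)` with mixture prior
`b_j ~ sum_{k,l} pi_{k,l} N(0, omega_l^2 U_k)`.  Covariance patterns:
null, identity, per-condition singletons, equal-effects, plus data-driven
patterns from the top 3 principal components of the strong-signal z-matrix
(rank-1 outer products and the rank-3 reconstruction) — a deliberately
smaller surface than empirical-Bayes matrix factorization, capturing the
same shared/specific structure.  Scales are a sqrt(2)-geometric grid from
0.1 x median se to 2 x max |bhat|.  Only the weights are learned (EM on
the random-SNP panel, so the prior reflects the genome-wide effect
distribution rather than the selected strong signals); because component
parameters are fixed, the log-likelihood is provably non-decreasing and a
numerical decrease aborts with a diagnostic.  Posterior moments and the
local false sign rate `lfsr = min{P(b >= 0 | D), P(b <= 0 | D)}` are
computed per gene and condition; point masses at zero (the null component
and singleton patterns in their zero conditions) are accounted
analytically.

The random panel should resemble "random SNP sets" from the same scans —
mostly null with dilute signal.  Training the prior on a *pure* null panel
over-shrinks true effects; the pipeline's panel builder draws random
gene-SNP pairs from the nominal scan output, which naturally contains
signal.

Sharing by magnitude between two conditions: among genes with lfsr < 0.05
in at least one, the fraction whose posterior means have the same sign and
magnitudes within a factor of 2 (boundary inclusive).  Response calls per
stimulus: induced (significant in stimulus, not at baseline), lost (the
reverse); shared requires significance everywhere with all stimulus
magnitudes within the factor-2 band of baseline.  Whether "condition
-specific" should require significance in *all* members of a group or
*any* is genuinely ambiguous; both are expressible through the per-gene
lfsr table the fit returns.

Differential APA between conditions uses the two-sided Wilcoxon test —
signed-rank on within-donor differences when conditions share donors,
rank-sum otherwise — BH-corrected, with significance additionally
requiring |delta PDUI| > 0.1, where delta is the difference of group
means (the difference statistic is a documented choice).  All-tied
inputs report p = 1.

## Colocalization and SMR/HEIDI

Per SNP and trait, the Wakefield log approximate Bayes factor is
`0.5 log(se^2/(se^2+W^2)) + (z^2/2) W^2/(se^2+W^2)` with prior effect sd
W = 0.15 for quantitative traits (0.2 on the log-odds scale is the
case-control convention).  Under one causal variant per trait per region,
the five hypothesis weights are sums of prior-weighted ABF products,
accumulated with log-sum-exp so nothing overflows; the result equals
exhaustive enumeration over all causal-configuration pairs to 1e-10
(tested).  Priors p1 = p2 = 1e-4, p12 = 1e-5; the colocalization call is
PP4 >= 0.75 and PP4/(PP3+PP4) >= 0.9.  Region selection is greedy on GWAS
peaks: index SNPs below 5e-8 in ascending p order with a 1-Mb exclusion
zone, each spanning +-100 kb.

SMR at the lead 3'aQTL: `b_xy = b_GWAS/b_aQTL`,
`T = z_a^2 z_g^2/(z_a^2+z_g^2)` against chi2(1), significant at
p < 3.5e-9; a weak-instrument guard requires the lead to reach 5e-8 aQTL
significance.  HEIDI compares Wald ratios of SNPs linked to the lead
(r^2 in [0.05, 0.9], capped at the 20 highest-r^2 SNPs, minimum 3):
differences d_i = b_xy(i) - b_xy(lead) get a delta-method covariance
propagated through the signed LD matrix, and the statistic sum z_d^2 is
referred to a Satterthwaite-scaled chi-square matched to the mean and
variance implied by the correlation of the d_i.  This approximation is
mildly conservative relative to the exact distribution of the correlated
quadratic form; under exact single-shared-causal simulation the rejection
rate at 0.05 stays near nominal (retention >= 90% in tests), and linkage
regions (two causal variants in moderate LD) are rejected in the
majority of simulations.  Genes with fewer than 3 eligible SNPs are
flagged "HEIDI undefined" rather than failed.

## Annotation

Variants are scanned against the polyA-signal catalogue (AAUAAA, AUUAAA
and the ten common single-substitution hexamers) on the transcript strand,
testing every motif-length window overlapping the variant under both
alleles; "destroyed" (ref-only match) takes precedence over "created" when
one substitution does both against the full catalogue.  AU-rich context is
additionally scored as the A/U fraction of a 20-nt window (>= 0.8 is the
suggested cutoff) since no single catalogue defines "uridylate-rich".
Enrichment near polyA sites (< 50 nt, edge-to-point on 0-based half-open
intervals) and inside RBP peaks uses two-sided Fisher exact tests with
log-OR normal CIs; zero margins get the Haldane 0.5 correction and are
flagged.  Controls are sampled uniformly from gene-body intervals on the
query SNP's own chromosome, size-matched k:1.

## Numerical conventions and limitations

* Coordinates: bedgraph/BED 0-based half-open, VCF 1-based; breakpoints
  reported as strand-oriented offsets (and convertible to genomic).
* All generators and analyses are pure functions of (config, seed); the
  CLI derives per-stage seeds from one master seed and writes a manifest.
* p-values are floored at the smallest positive double, never zero; se = 0
  rows are rejected, not regularized.
* Problem sizes used in the validation suite — 100 transcripts for oracle
  equivalence, 30–200 donors and 200 genes for calibration/power, 500-gene
  panels for sharing, 60–100 regions for colocalization, 200 regions for
  HEIDI — were chosen as the smallest sizes at which the binomial error of
  the measured rates is well inside the asserted margins.
* Known limitations: exactly two polyA sites per UTR (no intronic APA, no
  de novo site discovery); single-causal-variant colocalization (no
  SuSiE-style extension); no mixed-model association or trans-QTLs; HEIDI
  uses an approximation rather than the original saddlepoint; the PEER
  surrogate is plain PCA.
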