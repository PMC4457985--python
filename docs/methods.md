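# Methods

This note records the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data does and does not establish about behaviour on real cohorts.

## Data model

Genotypes are held as an effect-allele dosage matrix: per sample and
biallelic SNP, the count (0/1/2) of a user-designated *effect allele*,
NaN for missing calls. The effect allele is annotation input — which
allele is ancestral/derived or protective/risk is asserted by the analyst,
never computed. Genotype strings are unphased and strand-naive: allele
letters in data files must match the annotation exactly, and no strand
flipping is attempted. Missing calls are excluded per SNP per comparison
(complete-case within each test), the standard convention when per-SNP
missingness varies; rows of published frequency tables at fixed n are
generally not invertible to exact counts for exactly this reason.

TSV genotypes use two-letter unordered genotype strings (`CT` ≡ `TC`) with
a configurable missing token (default `NN`). VCF input consults the GT
subfield only, maps allele indices through REF/ALT, and codes half-missing
genotypes (`./1`) as missing.

## Allelic screen

For each SNP and ordered pair of groups the screen builds the 2×2 table of
effect/other allele counts and the 2×3 table of genotype-class counts
(dosage 0/1/2; no dominant or recessive collapsing). Both are tested with
the two-sided Fisher exact test under the point-probability rule: the
p-value sums the probabilities of all tables with the observed margins
whose probability does not exceed the observed table's, with relative
tolerance 1e-7 on the comparison to absorb floating-point ties. The
implementation enumerates the margin-preserving tables directly from a
cached log-factorial table (the probability of a 2×C table given margins
is ∏ⱼ C(cⱼ, aⱼ) / C(N, r₁)); it agrees with `scipy.stats.fisher_exact`
to 1e-9 relative and with exact rational-arithmetic enumeration on every
2×2 table with N ≤ 30 (both asserted in the tests). If every table ties at
or below the observed probability the p-value is exactly 1. Tables with a
zero row margin, or with all counts in one column, carry no association
information and are flagged degenerate with p = 1; a zero *column* simply
drops out of the enumeration, so a 2×3 table with an empty genotype class
equals the 2×2 test on the remaining classes.

Multiple testing is controlled by Benjamini–Hochberg (via statsmodels;
Benjamini–Yekutieli available as an option). The FDR family is all SNPs
within one comparison, allelic and genotypic arms adjusted separately —
the natural reading of correcting a screen "between the groups"; a
`joint_fdr` flag adjusts across comparisons instead. Significance flags
use the allelic arm. Comparisons accept pooled group specifications
(e.g. V+P+K against a background pool).

## Combined protective-allele score

The score is the unweighted count of designated protective alleles over k
loci (0..2k), generalising the two-locus case (k = 2, scores 0–4, nine
genotype combinations) that is the default configuration: protective T at
rs480902 (EGLN1; the high-altitude-adaptation-associated allele) and at
rs1063856 (VWF; the derived, non-thrombotic allele). No effect-size
weighting is applied — the score is deliberately a plain count. Samples
missing any configured locus are excluded from score analyses by default
(listwise exclusion; a `not_applicable` policy emits them unscored
instead). The enumeration operation is restricted to k = 2, where the
3 × 3 genotype-combination table is the natural presentation.

## Logistic models

Group membership is modelled as the outcome with the score as a numeric
(0..2k) predictor — the direction that matches "associate the scores with
the groups"; under score-as-ordinal assumptions the reverse
parameterisation yields the same likelihood-ratio test. A
categorical-score treatment was considered and rejected as the default
(it spends df needlessly at these sample sizes). Fitting is
Newton–Raphson on the full baseline-category likelihood with step-halving,
convergence on log-likelihood change < 1e-12 or maximal step < 1e-10
(within 100 iterations); the tight tolerances make fits invariant to the
choice of reference level and exactly antisymmetric under score negation,
both asserted in tests. The intercept-only null has closed-form MLE
(observed class proportions), and significance is the likelihood-ratio
statistic against it (df = groups − 1; df = 1 for binary), preferred over
Wald at n ≈ 30 per group. Fitted slopes exceeding 10 log-odds per score
unit are treated as (quasi-)separation: the fit is flagged not-converged
with a warning and the LRT p is reported at the likelihood boundary
reached. No covariates are supported — these cohorts are analysed
unadjusted. statsmodels' Logit/MNLogit serve as independent cross-checks
in the test suite, not as the implementation.

## Altitude cline

Populations are summarised by mean score and by the frequency of the
maximal score among scored samples; both are rank-correlated with
altitude. Spearman's ρ is the Pearson correlation of mid-ranks (ties get
average ranks). The two-sided p-value is an exact permutation enumeration
of one rank vector for n ≤ 8 populations — exactness matters most at
panel sizes where the t-approximation is weakest, and 8! = 40,320
permutations is still instant — and the t-approximation with n − 2 df
(scipy) above that. Two-sided testing is the conservative default even
though the scientific expectation is directional. Zero variance in either
vector (e.g. all populations at one altitude) yields an undefined ρ,
flagged, with p = 1. Population altitude is metadata supplied per sample
and must be single-valued within a population; no geocoding is performed.

## Synthetic data

Cohorts are sampled per group and locus as dosage ~ Binomial(2, f) under
Hardy–Weinberg equilibrium at the group's effect-allele frequency f, loci
independent, with optional uniform per-call missingness; genotype-class
probabilities can be supplied directly for non-HWE sampling. Panels draw
per-population frequencies from a cline function of altitude — logistic
in altitude, so frequencies are bounded in (0,1) by construction — then
sample the same way. One SeedSequence per run is spawn-keyed per
group/population, making outputs bitwise reproducible (byte-identical
TSVs) from the seed.

The reference cohort encodes the study conditions the screen is sized
for: subgroups V/P/K of 39/29/28 samples plus a 92-sample heterogeneous
background pool; nine planted (SNP, comparison) frequency contrasts over
eight distinct SNPs (rs3741860 contrasts in two comparisons) at their
published-table values; the two score loci with contrasting
protective-allele frequencies (the rs480902 values are synthetic defaults
— its true per-group frequencies in such a cohort were never published);
and 2,791 null SNPs sharing a frequency drawn once from Uniform(0.05,
0.95). Groups without a planted value at a planted SNP, and the
background pool, receive the unweighted mean of the planted values, which
reproduces the qualitative behaviour that pooling the subgroups averages
the contrasts away relative to the background. The default panel spans 20
populations from 0 to 4,000 m with protective frequency rising
logistically from ≈0.30 to ≈0.76 at both score loci.

What the generator does *not* emulate: linkage disequilibrium between
loci (the screen is marginal and the score additive, so independence is
the analysis's own working assumption), population substructure within
groups, genotyping-batch artefacts, and ascertainment of the SNP panel.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated sampling model, not robustness to stratified
or LD-structured real data — on real cohorts the screen's FDR guarantee
inherits BH's behaviour under dependence.

## Simulation scale and measured behaviour

Test-suite simulation sizes are chosen to give stable Monte-Carlo
estimates at desk scale: 1,000 replicates for type-I calibration bands
(multinomial LRT within [0.03, 0.07] and cline test within [0.02, 0.08]
at α = 0.05), 200 generation seeds for planted-effect recovery on the
full 188 × 2,800 reference cohort, and 200 replicates for parameter
recovery (binary-logistic slope β = 0.8 at n = 500 within ±0.25; planted
cline detected at ρ > 0, p < 0.05). Measured over 200 seeds, recovery
power for the planted contrasts ranges from ≈0.47 to ≈0.87 with mean
realized false-discovery proportion ≈0.04 among the null SNPs: the three
weakest planted contrasts (frequency differences of ≈0.33 at 28–39
samples per group) sit at the recovery boundary for a 2,800-test family
at FDR 5%, so their per-seed recovery is close to a coin flip — an honest
property of exact-test screening at these group sizes, and the reason
single small cohorts of this design replicate their weakest hits
inconsistently.

## Known limitations

- Exact 2×C enumeration is quadratic in the smaller margin; it is meant
  for cohort-scale tables (hundreds of alleles), not biobank counts.
- The multinomial fitter handles the single-predictor models it was built
  for; it does not implement regularisation, weights, or covariates.
- The screen treats groups as genetically homogeneous: no genomic
  control, PCA/admixture adjustment, or haplotype tests.
- No imputation, phasing, LD computation or tag-SNP selection; panels are
  taken as given.
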