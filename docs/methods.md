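# Methods

This note records the models behind each stage of the pipeline, the
parameter choices that matter, what the synthetic generators do and do not
emulate, and the numerical decisions a maintainer would want written down.

## Coordinate conventions

All intervals held in memory are 0-based half-open. GFF3 (1-based closed)
and VCF/variant-id positions (1-based) are converted at the I/O boundary;
variant identifiers keep their 1-based position because the canonical
`chr_pos_ref_alt` string is the join key across every table. bedGraph is
already 0-based half-open and passes through unchanged. The single internal
convention makes the intron-rescaling arithmetic in the coverage plots a
plain piecewise-linear map with no off-by-one cases.

## Genotype QC

The Hardy-Weinberg test is the exact conditional test: given the observed
allele counts, the heterozygote count under equilibrium follows
P(n_Aa = h) ∝ N! 2^h / (n_AA! h! n_aa!) over all h with the parity of the
minor-allele count, and the two-sided p-value sums the probabilities of all
heterozygote counts no more probable than the observed one. The
distribution is built by the ratio recurrence
P(h) = P(h−2) · 4(hom_r+1)(hom_c+1)/(h(h−1)) with periodic rescaling, so no
factorials are formed; the test suite verifies agreement with an
exact-rational enumeration to 10⁻¹² for totals up to 200.

Filter thresholds (HWE p < 10⁻⁶, missingness > 0.05, MAF < 0.01 for
exclusion; post-imputation MAF ≥ 0.01 and R² ≥ 0.4 for retention; samples
excluded above 5% missing) are all strict in the direction stated, and each
boundary is exercised on both sides by the tests. MAF is computed from
observed dosages (half the mean, folded), not from hard calls, so imputed
and hard-called inputs behave identically.

On the X chromosome the three variant statistics are computed on female
samples only and the decision applied to everyone; a male-only panel leaves
X variants unevaluable (flagged, excluded). Male dosages in the non-PAR
region are doubled and clipped to [0, 2]. The doubling is applied to a
dosage of exactly 1.0 as well — for imputed data that is a legitimate
fractional dosage; an opt-in flag (`mask_male_hets`) instead treats such
values as impossible heterozygous hard calls and sets them missing, for
panels known to contain hard calls only. Dosages above 1 before doubling
violate the haploid expectation and trigger a warning. MAF is folded after
harmonisation, so the order (harmonise, then filter) is the one the code
fixes. GRCh38 PAR bounds (PAR1 chrX:10,001–2,781,479; PAR2
chrX:155,701,383–156,030,895) are built in and overridable.

## Normalisation

Count traits (gene, exon) follow counts → GC correction → TPM filter →
inverse normal transform; usage traits (transcript, event, junction) follow
expression → usage ratio → inverse normal transform. Junction clustering
itself is an input contract — junction-by-cluster matrices arrive already
clustered.

The low-expression boundary is inclusive: a gene is dropped when *at least*
95% of samples sit below 1 TPM, so exactly 95/100 triggers exclusion.

The inverse normal transform is Φ⁻¹((rank − 0.5)/n) with average ranks at
ties; the offset is configurable but 0.5 is the default because it makes
the sorted output exactly the Φ⁻¹ quantile grid, a property the tests
assert directly. A fully tied trait maps to all zeros and must be removed
before scanning (the scan refuses zero-variance traits).

GC correction is a deliberately simplified stand-in for conditional
quantile normalisation: per sample, the deviation of log2(count + 0.5) from
the cohort-mean profile is smoothed against GC fraction with LOWESS
(frac = 0.5) and subtracted, then each trait is re-centred on its original
mean. Only *between-sample* GC bias is removed; the GC trend shared by the
whole cohort is retained on purpose, because the per-trait inverse normal
transform downstream erases trait-level shifts anyway, and estimating the
cohort trend from a few hundred traits adds more noise than it removes.
Fewer than 20 traits: the correction is skipped with a warning, as no
trend is estimable.

## Cis association

The window is ±1 Mb around the strand-aware transcription start (leftmost
base on +, rightmost on −; configurable to unstranded), clamped at the
chromosome origin. Traits with fewer than 5 cis variants or zero variance
are refused. The per-variant model is OLS of the standardised trait on
dosage plus covariates, computed through the Frisch–Waugh–Lovell
decomposition: both sides are residualised on the covariates (QR
projection) once, and each variant's β, SE and two-sided t-test p follow
from scalar projections. This is algebraically identical to the full
multiple regression — the suite checks β/SE/p against textbook
(XᵀX)⁻¹Xᵀy to 10⁻¹⁰ and against `statsmodels.OLS` — and fast enough to
permute directly. Missing dosages are dropped pairwise per variant; a
residualised dosage column whose sum of squares falls below 10⁻¹⁰·n is
reported as monomorphic (missing β, flagged) rather than producing a
garbage estimate.

Group permutations shuffle the sample labels of the trait matrix with one
shared permutation per round, preserving the trait–trait correlation that
makes the group-minimum p-value non-trivial. Covariates are handled by
residualising once and permuting trait residuals; with residualised
columns the t statistic is monotone in the correlation coefficient, so each
round needs a single matrix product and the group minimum p equals the
maximum |r|. The estimator is the add-one form (1 + #{perm ≥ obs})/(1 + B),
floored at 1/(B+1); B = 1000 by default, matching standard practice. The
acceptance suite verifies the null distribution is uniform (KS at 200
replicates × 2000 permutations) — a direct-permutation design, chosen over
the beta-approximation used by large-scale tools because at package scale
exact permutation is affordable. Phenotype PCs are computed on the
standardised matrix (scaled PCA, deterministic sign convention); genotype
PCs likewise, with a `scale=False` option for covariance-based scores.

Dataset-level discovery applies Benjamini–Hochberg at 1% across the group
empirical p-values. The exon effect profile fits the same OLS per
exon-level trait against the lead variant's dosage, reports β ± 1.96 SE,
and flags exons by BH at 1% across the gene's exons.

## Credible-set filtering

The unit is the (trait, signal) credible set. Order of operations is fixed:
first discard weak (max member |z| < 3) and unresolved (> 200 members)
sets — both strict, both reasons recorded when both hold — then build the
overlap graph on the survivors. A discarded set therefore cannot bridge two
components. The max-|z| is taken over credible-set members, not the whole
region. Edges require exact canonical-id equality; no LD-based merging.
Components are ordered by smallest cs_id and the tag is the trait owning
the set with the largest member PIP, ties broken by trait id then cs_id,
making the partition fully deterministic and row-order invariant (both
properties are tested, the component structure against a pairwise-merge
fixpoint oracle on 1000 random instances). Gene-level (single-trait)
scans bypass filtering — there is nothing to prune. Retained rows are all
rows of any tag trait; the report gives rows_in, rows_out and
reduction = 1 − out/in.

## Colocalisation

Log-space throughout: S1 = lse(a), S2 = lse(b), S12 = lse(a+b), and the H3
cross term ln Σ_{k≠j} e^{a_k+b_j} = lndiff(S1+S2, S12) with
lndiff(x, y) = x + ln(1 − e^{y−x}) guarded to −∞ when y ≥ x — which also
makes PP3 exactly 0 for a single shared variant. Priors default to
p₁ = p₂ = 10⁻⁴ and p₁₂ = 5·10⁻⁶, the conventional single-variant prior
scale, and are exposed as arguments/flags. Variant sets are intersected on
the canonical id; swapped-complement (strand-ambiguous) pairs are dropped
rather than guessed. The scan evaluates every cross-pair of signals,
truncating to 10 signals per trait/locus with a warning, and flags PP4
strictly above 0.9. Posteriors are verified against a per-configuration
enumeration oracle to 10⁻¹⁰ and satisfy the swap symmetry
(PP1 ↔ PP2, PP0/PP3/PP4 fixed).

## Coverage plots

The display axis keeps exons at natural scale and maps every intron to
exactly 50 display units (flanks, if any, map length-preservingly). The
map is strictly increasing and invertible on exonic bases; total display
length is Σ merged-exon lengths + 50·gaps + 2·flank — both facts asserted
numerically. Gaps shorter than 50 bp are *stretched* to 50; this distortion
is inherent to the fixed-width rule and documented rather than avoided.

Samples join genotype class round(d) when |d − round(d)| ≤ 0.25, otherwise
they are dropped and counted — hard-called VCFs are unaffected, imputed
dosages get an explicit contract. Coverage is normalised per sample by its
own mean over the plotted span before class-averaging, so multiplicative
depth factors cancel exactly (tested to machine precision); CPM or no
normalisation are available alternatives. Input coverage arrives in 5-bp
bins (the bin width the upstream coverage extraction uses) and is re-binned
at the same width on the display axis, averaging within bins that cross
exon boundaries. The figure has three vertically aligned panels sharing
the display axis — stratified coverage, exon effects (significant exons in
dark blue at FDR ≤ 1%), transcript boxes — and every plotted number is
also emitted as a tidy table, so tests assert on tables, never on pixels.

## Synthetic fixtures

Genotypes are hard calls drawn under Hardy-Weinberg equilibrium; optional
LD is created by having each haplotype copy a per-block anchor allele with
probability √r, giving pairwise genotype correlation ≈ r within a block
while preserving the marginal frequency (frequency is held constant within
a block for that reason). Calibration tests confirm HWE rejection at the
nominal rate and allele frequencies within three binomial standard
deviations of target.

The splicing-QTL gene is the two-transcript motif: four shared exons, one
of which has a long and a short version; per sample, usage of the short
transcript is logistic(base + effect·dosage) with the effect in logit
units; exon and gene counts are Poisson around the mixture expectation
(negative-binomial overdispersion deliberately omitted — Poisson is the
simplest model that exercises every contract); per-base coverage is the
depth-scaled expected read density of the mixture with Poisson noise per
5-bp bin and a uniform(0.5, 2) per-sample depth factor, so depth-invariance
claims are actually stressed. Total gene output is genotype-independent: a
pure splicing QTL with no expression QTL, which the tests verify.

Trait groups with planted signals give the lead trait a full effect
(default 1.0 residual-sd per standardised-dosage unit — the scale used in
the recovery analyses at n = 500) and the decoys an attenuated effect
(0.5) plus noise correlated at 0.5 across traits, mimicking exon-level
traits that partially overlap a spliced event. The decoy attenuation is
what makes tag recovery a real test: every trait fine-maps to the same
variant, but only the lead should win the PIP comparison.

Fine-mapping outputs use the single-effect Wakefield approximation:
ln ABF = ½ ln(se²/(se² + W)) + ½ z² W/(se² + W) with prior effect variance
W = 0.15², PIPs as the softmax of the ABFs, and the credible set as the
smallest variant set with cumulative PIP ≥ 0.95. One signal per trait;
multi-signal plumbing is exercised by superposing independent single-effect
constructions. This stands in for a full sum-of-single-effects fit, which
is consumed, not fitted, by this package.

What the fixtures do **not** emulate: realistic LD panels, population
structure, sequencing-batch effects, negative-binomial overdispersion, or
sex-specific expression (X fixtures only exercise the dosage/QC
contracts). Passing tests therefore demonstrate the correctness of the
algorithms and their decision boundaries, not the power or calibration of
the methods on real cohort data.

## Problem sizes

The test and acceptance analyses use deliberately compact configurations:
recovery analyses at n = 500 samples, ~24 variants and 50 replicates;
calibration at 200 replicates × 2000 permutations and 1800 null confidence
intervals; oracle comparisons at 200–1000 random instances. These sizes
make the full suite run in well under a minute while leaving the Monte
Carlo error of each rate far below the margins being asserted.

## Known limitations

- The GC correction is a smooth-trend removal, not conditional quantile
  normalisation; quantile-dependent GC effects are not modelled.
- The permutation pass mean-imputes missing dosages (the nominal scan does
  pairwise-complete estimation); with substantial missingness the two can
  diverge slightly.
- Credible-set overlap is exact-id only; signals tagged by different but
  perfectly correlated variants land in different components.
- `bigWig` input is not required; binned bedGraph is the coverage contract
  (a bigWig reader can be slotted in where available).
- Windows are clamped at the chromosome origin but not at chromosome ends
  (no assembly lengths are carried).
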