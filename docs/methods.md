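# Methods

This note records the models implemented in `vitipanel`, the defaults and
why, the numerical choices, and what the synthetic-data tests do and do
not demonstrate about real germplasm data.

## Data model

Diploid genotypes are held in a single container mixing biallelic SNPs
(dosage-coded 0 / 0.5 / 1 for hom-ref / het / hom-alt, NaN missing) and
multiallelic SSR loci (two integer allele labels per locus, −1 missing).
The 0/0.5/1 coding — rather than 0/1/2 — is deliberate: it is the coding
of the mixed model used for power, so effect calibration and LD
computations share one scale. Coordinates are 1-based; distance is
|pos_i − pos_j| in bp; genotypes are unphased and strandless. All
estimators accept missing data through pairwise-complete loci (kinship,
LD) or non-missing calls (frequencies); MAF for a multiallelic locus is
defined as one minus the major-allele frequency so one threshold serves
both marker types.

## Diversity and differentiation

He = 1 − Σp², Ne = 1/Σp² (so Ne = 1/(1 − He) exactly), Ho as the
heterozygous fraction of non-missing calls, Nei's diversity equal to He.
No small-sample correction is applied to He — the unadjusted formula is
the definition used throughout. Differentiation is Weir & Cockerham's
(1984) θ with the full a/b/c variance components computed per allele and
locus and ratio-of-sums averaging, valid for SNPs and SSRs; estimates may
be negative and are reported as computed. Which exact Fst variant the
original GenAlEx-based analyses used is not recoverable; θ was chosen as
the standard, testable estimator.

## Kinship estimators

* **AIS**: the mean over shared loci of ¼[I(a=c)+I(a=d)+I(b=c)+I(b=d)].
  Its self-value is 1 − Ho/2, an identity asserted in tests.
* **WAIS**: published descriptions of the original implementation specify
  only "two correction factors" per locus; the reading implemented is a
  per-locus baseline s_l = mean AIS over all pairs spanning two assumed-
  unrelated groups, with corrected value mean_l (AIS_l − s_l)/(1 − s_l).
  Loci with s_l = 1 are skipped with a warning.
* **BNO**: the same correction with one global s (the pair-count-weighted
  mean of s_l).
* **LOI** (Loiselle): the bias-corrected frequency-correlation estimator;
  with no missing data the implementation matches the textbook formula
  term by term, and with missing data missing genotypes contribute zero
  to the cross-products while the bias and denominator terms stay global.
* **MLE**: per pair, EM over the mixture of the three IBD-state pair
  likelihoods, from (⅓, ⅓, ⅓), at most 200 iterations, log-likelihood
  tolerance 1e-6; no genotyping-error parameter (the motivating data were
  manually curated). The diagonal is fixed at the no-inbreeding
  self-coancestry ½. The EM approaches boundary optima (k0 → 1) slowly;
  at the default tolerance the fitted likelihood can sit ~0.05 below the
  boundary value, so the optimality test tightens the tolerance.

Corrected estimators produce negative values; they are kept in the matrix
(they are informative as "less related than the baseline") and truncated
at zero only when the matrix feeds whitening or the mixed model.

### Making corrected matrices usable as covariances

The per-locus centering of WAIS/BNO subtracts multiples of the all-ones
rank-one matrix, so the result is genuinely indefinite (minimum
eigenvalues around −0.6 on realistic panels), and zero-truncation does
not restore definiteness. The conditioning policy for whitening and V
inversion is: attempt Cholesky; on failure add a ridge of
1e-6 × mean(diag) and retry; on a second failure shift the whole spectrum
by |λ_min| + ridge. The shift preserves eigenvectors and relative
contrasts; eigenvalue clipping at a tiny floor was rejected because
whitening then amplifies the clipped directions catastrophically
(measured spurious r²_V ≈ 0.9 between unlinked loci).

### Estimator selection and relationship calls

Because true LD between loci on different chromosomes is null, the mean
r²_V over inter-chromosomal pairs (MAF ≥ 5 %) measures the bias a
correction leaves behind; the selector returns the estimator minimizing
it, with ties broken in the fixed order AIS < WAIS2 < WAIS4 < BNO < LOI <
MLE. The relationship classifier evaluates each pair's log-likelihood at
the canonical IBD vectors U = (1,0,0), HS = (½,½,0), FS = (¼,½,¼),
PO = (0,1,0); an opposite-homozygote locus drives the PO likelihood to
−∞ (Mendelian exclusion); ties prefer U, then HS.

## Corrected LD

r²_V whitens the two dosage vectors and the intercept by the inverse
lower Cholesky factor of the (conditioned) kinship matrix, residualizes
on the whitened intercept, and squares the residual correlation; r²_VS
adds the whitened structure columns, dropping the last for
identifiability. With K = I this reproduces classical r² to machine
precision, and the whole computation equals the explicit GLS partial
correlation (tested against that independent formulation). Kinship enters
as provided — no doubling to a relationship-matrix scale — and the same
convention is used in the power module so the two are mutually
consistent. Sliding windows require both loci inside the window (the
midpoint convention was the open alternative; both-inside is implemented
and documented), anchor at the window start, and emit missing below the
minimum pair count (default 10).

## LD decay

The Hill–Weir expectation is fitted to (distance, LD) pairs by unweighted
least squares over a log-spaced bounded multi-start in ρ ∈ [1e-12, 1]
(8 intervals, deterministic); binning before fitting is available but off
by default. The sample size n in the expectation is the number of
genotyped individuals in the LD table — the cited formulation counts
gametes, but for these unphased clonal panels individuals are the unit;
the choice is configurable. Note the curve's large-C limit is the 1/n
sampling floor, not zero, and its value at d = 0 is ≈ 0.4545 + 0.4545/n
regardless of the data; extent at a 0.2 threshold therefore always exists
but is only meaningful when the observed short-range LD actually reaches
that level. The marker-count conversion assumes equally spaced markers at
spacing 2d*, which guarantees a marker within d* of any position; the
published marker-count figure uses an unstated convention and is not
compared against.

## Mixed-model power

On a unit-total-variance scale with heritability h² and a locus
explaining a fraction q of genetic variance: σ²_e = 1 − h²,
σ²_g = (1 − q)h², β = sqrt(q·h²/Var_emp(x)), V = σ²_g·K + σ²_e·I,
var(β̂) the x-entry of (XᵀV⁻¹X)⁻¹, noncentrality λ = β²/var(β̂), and
power the upper tail of a 1-df noncentral chi-square beyond the central
quantile at α = FWER/Meff (plain division, not Šidák). Variance
components are treated as known, and the Wald statistic is referred to
chi-square(1), not an F — consistent simplifications from the cited
power framework. Effect calibration uses the empirical genotype variance
rather than 2p(1−p), so related or structured panels need no equilibrium
assumption. Meff is the Li–Ji eigenvalue count on the locus–locus
Pearson correlation matrix.

Two consequences of this calibration are worth stating plainly. First,
with K = I the noncentrality is exactly n·q·h²/(1 − q·h²) for every
polymorphic locus — power is MAF-invariant, and any MAF dependence comes
only through the alignment of a locus with the kinship structure. Second,
under Balding–Nichols frequencies that alignment penalizes common
alleles (between-group variance scales with p(1−p)), the opposite of
real germplasm where rare alleles cluster within kin groups; the
generator therefore does not reproduce a positive MAF–power relation,
and no test asserts one. The Monte-Carlo validation simulates phenotypes
under the same generating model (components known, kinship square root
factored once) so the Wald statistic follows its stated distribution
exactly; the agreement test is calibrated for the nine simultaneous
Monte-Carlo cells (3 SE per cell plus a chi-square aggregate) rather than
a per-cell 2 SE rule, which would false-alarm on one cell in three runs
by construction.

## Synthetic panels

Defaults are the study conditions: subgroups WE/WW/TE/wild of
90/92/90/62; Balding–Nichols subgroup frequencies at F = 0.02/0.04/0.06/
0.09 around ancestral frequencies uniform on [0.05, 0.5] (targets within
the 0.01–0.09 differentiation range of the motivating panel); four 2 Mb
regions with 86/97/80/109 SNPs, 129 distributed SNPs, 20 SSRs with 8–15
alleles.

Within-region LD comes from a founder-haplotype copying model: per group
and region, a pool of founder haplotypes is sampled site-wise from the
subgroup frequencies, and each gamete copies along the region from a
random founder, switching founders between adjacent loci with probability
1 − exp(−switch_rate·gap). Two properties follow. (i) The short-range r²
ceiling is ≈ 1/pool-size (the expected r² among independent-site founder
haplotypes) decaying to the 1/n sampling floor; the defaults — pools of 8
cultivated / 4 wild founders, switch_rate 1e-5 per bp — were chosen once
to give clearly measurable monotone decay over the 10–500 Kb scale and a
lower wild diversity, at the price of a ceiling (≈ 0.125) below the 0.2
extent threshold, so fitted whole-panel extents are short; the extent-
recovery test instead uses a 3-founder pool with switch_rate 6e-6,
calibrated for a ~50 Kb extent. (ii) The finite pool adds drift beyond
the Balding–Nichols target on region SNPs (roughly +1/pool on Fst) —
that drift is precisely what creates the LD — so Fst-recovery checks use
the pool-free distributed SNPs.

Parent-offspring injection gives the child one recombination-free
parental gamete per region plus a fresh pool gamete; full sibs are two
children of the same two pool-drawn parents; unlinked loci transmit one
random parental allele. The registry of injected pairs is ground truth
for classification and MLE-recovery tests. Phenotypes follow the mixed
model with total variance normalized to 1 and β calibrated as above.

What the generator does not emulate: allele-frequency spectra skewed
toward rare variants, kin-group-specific rare alleles, genome-wide
background relatedness beyond the injected pairs, genotyping error, SSR
mutation models, and coalescent site-frequency/LD structure. Passing
tests therefore demonstrate correctness of the estimators and the
internal consistency of the pipeline under a controlled model — not that
real panels will show, e.g., the same power levels (the synthetic panel's
weak confounding yields near-saturated analytic power at h² = 0.9,
q = 0.25, where heavily related real germplasm does not).

## Panel design

The exact maximum-length-subtree procedure of the original workflow is
proprietary at the algorithmic level; a deterministic greedy maximin on
the simple-matching dissimilarity stands in: start from the founders (or
the globally most distant pair), repeatedly add the candidate maximizing
its minimum dissimilarity to the selection, ties to the smallest id.
Pruning removes, from each classifier-flagged first-degree pair, the
non-founder member with the larger mean kinship to the rest of the
selection (founders are protected; a founder–founder pair is flagged and
kept), refills by maximin, and iterates; each iteration strictly shrinks
the candidate pool or the flagged set, so the loop terminates. The rare-
allele threshold for retention reporting defaults to MAF 0.05. Rank-sum
tests use the normal approximation with tie correction; variance equality
uses the median-centred (Brown–Forsythe) Levene statistic.

## Problem sizes in tests and the acceptance script

Test simulations use 40–150 individuals and 80–500 loci per scenario;
the acceptance script runs the full 334-individual default panel, 2000
Monte-Carlo phenotype replicates per power cell, and a 150-individual
collection per subgroup for design — sizes chosen so the whole suite and
script each complete in minutes on one CPU while keeping binomial and
sampling errors well inside the asserted tolerances.
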