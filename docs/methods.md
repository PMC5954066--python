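# Methods

This note documents the models implemented in `abca7vntr`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinates and repeat arithmetic

Intervals are 0-based half-open internally; publication-style region
strings (`chr19:1049437-1050028`) are 1-based inclusive at the parse/format
boundary. The locus constants are the 592-bp reference repeat span, the
25-bp unit, and the 440-bp breakpoint-excluding core
(`chr19:1049514-1049953`). Unit counts are printed to one decimal
(592/25 = 23.7) and "approximate units" use round-half-away-from-zero, so
298 bp → 12 units and 10 678 bp → 427 units.

Sanger-read decomposition is greedy left-to-right with substitution-only
mismatches (default tolerance 2 per 25-bp unit). Indel-aware tiling was
deliberately not implemented: the quantity of interest is an approximate
unit count for short alleles, and inter-unit variation at this locus is
substitutional in character.

## Read-depth proxy

A read counts toward the core if its primary alignment overlaps the core by
at least one base (standard region-query semantics); secondary and
supplementary alignments are dropped when flags are available, and
duplicates are counted as given (no dedup by default — whether duplicates
were removed upstream is an input property, so it is configurable, not
assumed). There is no mapping-quality threshold by default, because the
repeat intrinsically yields low-MAPQ alignments and the proxy depends on
exactly those reads. Samples with ≤ 5 core reads are excluded; zero total
reads is a distinct exclusion reason. Normalized coverage is the
dimensionless ratio core/total.

## Expansion association

The expansion cutoff is the largest allele observed among control subjects
with zero copies of the rs3764650 risk allele; "expanded" is **strictly
greater** than the cutoff (ties are wild-type). The carrier 2×2 table is
subject-level, because carriers, not alleles, are the unit of the reported
counts. Fisher's exact test is two-sided (minimum-likelihood definition);
the odds ratio is the conditional maximum-likelihood estimate and its 95%
CI inverts the noncentral hypergeometric tail probabilities — the behaviour
of classical exact-test software, against which the implementation is
tested on frozen reference values.

## Heritability of liability

Disease liability is standard normal with threshold t = Φ⁻¹(1 − K). For
genotype group *g* with population frequency p_g and odds ratio OR_g, the
calculation is:

1. OR_g → risk ratio at prevalence: RR_g = OR_g / (1 − K + K·OR_g);
2. baseline risk f₀ solved so that Σ p_g f₀ RR_g = K;
3. group liability means μ_g = t − Φ⁻¹(1 − f_g), assuming unit-variance
   within-group liability;
4. explained variance V = Σ p_g (μ_g − μ̄)², reported both as a fraction of
   total liability variance and as V/h² (share of total heritability).

The conversion in step 1 keeps every group risk strictly below 1, so the
guard against a saturated risk-scale model cannot trigger under the default
conversion; it protects future parameterizations.

Two free choices are exposed because the convention behind the published
headline number is not derivable from print: the carrier-frequency source
(`controls` or `pooled`) and the risk model (`multiplicative`, which treats
the supplied frequency as a per-allele risk frequency with Hardy–Weinberg
genotype proportions and odds ratios (1, OR, OR²), or `carrier`, a binary
exposure). The pinned default — control-derived carrier frequency entered
as the risk frequency of the multiplicative model, result read as a share
of h² = 0.79 — is the combination under which the worked example
reproduces the cohort's headline estimate to one decimal; the acceptance
test pins it explicitly, and both normalizations are always reported so the
choice is visible rather than baked in.

## Endophenotype models

CSF regressions use log₂-transformed levels as the response and the allele
sum (or longest allele) in bp as the predictor; slopes are per bp, so
rescaling bp → kb multiplies β by exactly 1000 (tested as an equivariance).
Nonpositive levels are rejected by subject id rather than silently dropped.

qPCR relative quantification follows the multi-reference-gene convention:
technical replicates are averaged on the Ct scale, per-gene relative
quantities are E^(Ct_cal − Ct) with the sample-mean Ct as calibrator and
E = 2 (perfect doubling; configurable per gene, since efficiencies are not
part of the input tables), the normalization factor is the geometric mean
of the reference-gene quantities, and the normalized quantity is
target/NF. The sample-mean calibrator makes the output invariant to adding
a constant to all Ct values of any one gene.

The expression model is a linear mixed model: fixed effects VNTR sum (bp)
and gender, random intercept for the culture batch; the VNTR term is tested
by a likelihood ratio between ML fits (χ² on 1 df). With a single batch or
a degenerate random intercept the model falls back to OLS with batch as a
fixed effect, logged, and the LRT compares the corresponding OLS fits. Fold
changes between two stated diploid sums (defaults 9974 and 872 bp, the
largest and smallest observed diploid combinations) are computed on the
linear-predictor scale — relative expression is modelled linearly, not
log-linearly — at the cohort mean of the gender covariate.

## Splicing

The transcript model stores the published cryptic-site coordinates verbatim
as 3-bp intervals (chr19:1049314–1049316 and 1049461–1049463) without
reinterpreting them as AG/GT dinucleotides; junction positions within one
base of a site are accepted. Exon boundaries not derivable from print are
fixed configuration chosen to be consistent with the measured coding deltas
(−52, +25, −132); the classifier never recomputes −52 from annotation it
does not have. Frame logic: a delta divisible by 3 is in-frame with
delta/3 residues gained/lost; any other delta is a frameshift, which at
this locus introduces a PTC. Unknown junctions are reported `unclassified`,
never dropped.

Fragment-analysis quantification assigns each peak to the nearest expected
combination size within a tolerance (default 3 bp; expected sizes must be
separated by more than twice the tolerance). The eight combination
amplicons are all subsets of the three events added to a configurable
canonical amplicon length (default 520 bp — the true length is not an input
the analysis depends on, only the deltas matter). Event ratios are
containment sums: a combination peak counts toward every event it carries,
matching event-level rather than isoform-level reporting. The default
denominator includes all matched peaks; `include_unit_retention=False`
reproduces the three-peak convention (canonical + cryptic acceptor + skip).
Both modes are tested.

Allele-specific skipping counts reads per phased SNP base; reads with an
ambiguous base or an unclassified junction are tallied separately and
excluded from ratios. The fold change is the expanded allele's skip ratio
over the wild-type allele's, NaN when a denominator is empty.

The NMD contrast is the per-sample CHX-minus-untreated change in each
PTC-category ratio, regressed by OLS on the diploid VNTR sum; under
length-independent NMD the slope is null, which is how the generator's CHX
layer is configured.

## The synthetic cohort generator

The generator's defaults are the study conditions, not tuning knobs:

* **Cohort**: 275 patients / 177 controls; prevalence K = 0.13; total
  heritability h² = 0.79.
* **Haplotypes**: tag-SNP risk haplotype frequency 0.12 (the cohort's MAF);
  a secondary SNP riding on half the risk haplotypes; wild-type allele
  lengths log-normal with median 2388 bp and σ = 0.641 (chosen to match the
  reported 2130-bp interquartile range), truncated below at 298 bp (the
  smallest observed allele) and above so that length plus the LD shift
  (+800 bp on risk haplotypes) stays at or below the truth cutoff.
* **Expansions**: a mixture component strictly above 5720 bp with an
  exponential tail (mean 1500 bp), placed predominantly on risk haplotypes
  (per-haplotype probabilities 0.0925 vs 0.0015), giving a population
  carrier frequency of ≈ 2.4% — the value implied by the cohort's carrier
  counts at prevalence 0.13.
* **Disease**: liability-threshold, not logistic — the heritability
  calculation is defined on the liability scale, so parameter recovery is
  self-consistent. The carrier liability shift is solved numerically so
  that carriers have exactly the configured odds ratio (default 4.5) at the
  configured prevalence.
* **Onset age**: Normal(73, 9), independent of VNTR length, reflecting the
  null finding; it doubles as inclusion age for controls.
* **Expression**: linear in the diploid sum, calibrated so the largest
  printed diploid combination (9974 bp) sits 33% below the smallest
  (872 bp); exon-19 skip probability calibrated to 3.2× over the same
  range; exon-18 event probabilities length-independent (their null).
* **CSF**: log₂-scale slopes −4.6×10⁻⁵ (Aβ₁₋₄₂), −4.0×10⁻⁵ (P-tau₁₈₁), 0
  (T-tau) per bp. The P-tau trend is described in words as directly
  proportional in the source cohort while the printed coefficient is
  negative; the generator follows the printed sign.
* **Reads**: core-overlapping reads Poisson with mean depth_rate·(L₁+L₂)/kb
  (default 20 reads/kb), placed uniformly over positions overlapping the
  core; flank reads are placed wholly outside the core so the
  breakpoint-exclusion query is exercised. A (0, 0) genotype therefore
  yields no core reads.
* **ASE**: one subject with alleles 837/9711 bp phased A/G at rs3752240;
  per-allele skip probability linear in allele length with defaults chosen
  so the expanded/wild-type skip-ratio fold is 4.1.
* **CHX**: PTC-event probabilities multiplied by a length-independent 1.8.

All layers draw from one seeded generator in a fixed order; a fixed seed
reproduces every table byte-for-byte.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequence-level reads (no bases, qualities or
error model), GC bias in depth, LD structure beyond a two-SNP haplotype,
somatic mosaicism or Southern-blot sizing error, qPCR efficiency drift,
isoform-level (as opposed to event-level) peak structure, and any
correlation between onset age and length (fixed at zero by design).
Recovery tests therefore demonstrate that the estimators are correct and
calibrated under the stated model, not that the model captures every
property of bench data.

## Numerical conventions and problem sizes

* Exact-test root finding uses Brent's method on log-odds in [−36, 36].
* Kruskal–Wallis with all-tied values returns H = 0, p = 1 (the
  tie-corrected statistic is otherwise undefined); a single non-empty group
  is an error ("no contrast").
* The Mann–Whitney test returns p = 1 for fully tied samples.
* The conditional-MLE odds ratio is 0 or ∞ when the observed cell sits at
  the boundary of the conditional support, matching exact-CI endpoints 0
  and ∞.
* Test-suite problem sizes were chosen for desk-scale runs: 500 seeds for
  odds-ratio recovery/CI coverage at the cohort's sample size, 12 seeds for
  the expression/skip gradient recovery, 120 null cohorts for KW and
  onset-age calibration, 60 replicates for LMM and NMD calibration, and
  10⁴–2×10⁴ label permutations for the rank-test oracles.

## Known limitations

* The expansion-cutoff rule is data-circular by construction (the cutoff is
  an order statistic of a genotype-defined control subset); in simulation
  a rare expansion on a non-risk haplotype in that subset inflates the
  cutoff and biases carrier counts downward. This is a property of the
  rule, faithfully reproduced, not corrected.
* The heritability parameterization is pinned by reproduction, not
  derivation; both frequency sources and both risk models remain available
  and reported.
* With expected control-carrier counts near 3, single simulated cohorts
  frequently yield infinite or undefined odds-ratio estimates (zero
  expanded controls); recovery is therefore assessed by medians and CI
  coverage across seeds, never by a single draw.
* The mixed model treats the growth batch as the only random effect; cDNA
  batch and replicate structure are averaged into the Ct means upstream.
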