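# Methods

`qvburden` implements a rare-variant collapsing analysis of red blood
cell (RBC)-related phenotypes in small, deeply phenotyped cohorts, plus
the synthetic-cohort machinery needed to test every stage with known
ground truth.  This note records the models, the numerical choices, the
defaults and their rationale, and what the synthetic tests do and do
not establish about real data.

## Qualifying variants

A *qualifying variant* (QV) is a rare, putatively function-disrupting
variant defined by three rules applied to an annotated catalog:

1. **Impact class.** The consequence term must be one of the six
   high-impact (HI) classes: splice acceptor, splice donor, stop
   gained, frameshift, stop loss, start loss.  Consequence vocabulary
   accepts both underscore and spaced spellings through a synonym
   table; unrecognized terms — however severe-looking — fall to OTHER,
   never silently to HI.
2. **Population frequency.** Reference-database alternate-allele
   frequency strictly below 0.001, or absent from the reference
   database ("no-AF"); absence is treated as inclusion by default
   because novel variants are disproportionately rare.
3. **Cohort allele count.** The cohort alternate-allele count must not
   exceed `floor(2 n_samples × target_MAF)` with target MAF 3% (at
   least 1): 3 alleles at n = 50, 4 at n = 77.  The count is computed
   on the delivered genotype matrix, i.e. the analysis cohort after
   any upstream sample exclusions, so the cap is reproducible from the
   distributed data.  Missing genotypes are excluded from counts.

Multi-allelic records are decomposed to one variant per alternate
allele ("position and allele" defines variant identity), and the
allele-count cap is applied per decomposed allele.  Exclusions carry a
single machine-readable reason in fixed precedence (impact class →
population AF → allele cap), so reasons partition the rejected
variants.  AF bins for spectrum summaries are
missing | (0, 0.001) | [0.001, 0.01) | [0.01, 1]; the boundary
conventions follow the strict `< 0.001` filter and the `> 0.01`
reading of "common", and both cut points are configurable.

## Burden profiles and the dominant model

For each person and gene set, the burden is the number of **distinct QV
sites** at which the person carries at least one alternate allele — a
homozygous site counts once (dominant inheritance).  A dosage-sum mode
exists for sensitivity analysis.  Carrier status is burden ≥ 1.  A
person missing genotypes at every QV of a unit is flagged missing for
that unit rather than counted as a non-carrier.

## Stratified exact association (CMH)

Association between carrier status and a binary phenotype is tested
with the Cochran–Mantel–Haenszel framework over 2×2 strata.  The
default stratification unit is the gene (per-gene carrier tables are
the natural reporting unit for collapsing analyses); per-variant
strata are available via `stratify_by="variant"`.

* **Common odds ratio.** The Mantel–Haenszel estimator
  `OR_MH = Σ(a_i d_i / n_i) / Σ(b_i c_i / n_i)`, with the
  Robins–Breslow–Greenland variance for its 95% CI (via statsmodels).
  No continuity-correction pseudocounts are added — the estimator
  tolerates zero cells; degenerate CIs are flagged, not fabricated.
* **Exact p-value.** Under the null, each stratum's carrier-in-case
  cell follows a central hypergeometric distribution conditional on
  its margins; the null distribution of the summed cells is the
  convolution of the per-stratum distributions, computed exactly by
  numerical convolution of the probability vectors.  The two-sided
  p-value is twice the smaller tail, capped at 1 — simple and
  conservative.  With one stratum this reduces to a tail-doubled
  Fisher test (note this differs from the minimum-likelihood
  two-sided Fisher convention used by `fisher_exact`).
* **Asymptotic p-value.** The continuity-corrected CMH chi-square with
  1 df, for large balanced strata.

Exact mode is the primary analysis because the regime of interest —
a handful of carriers per gene in cohorts of 50–80 — is exactly where
the chi-square approximation fails.

The exome-wide single-variant scan runs a two-sided Fisher exact test
per variant on the carrier 2×2 table, reports the Bonferroni threshold
0.05/m, QQ coordinates with expected quantiles −log10((i−0.5)/m), and
a genomic-inflation factor (median observed chi-square quantile over
the chi-square(1) median).  With exact conditional tests on rare
discrete data the null scan *deflates* (lambda well below 1, QQ points
under the diagonal); this is expected behaviour, not an error, and the
tests assert absence of inflation rather than lambda ≈ 1.

## Phenotype endpoints

RBC panels (RBC 10¹²/L, HGB g/L, HCT fraction, MCV fL, MCH pg, MCHC
g/L, RDW %) are time-ordered per patient.  Endpoints per parameter:
*first* and *final* are the earliest and latest non-missing values by
timestamp (ties broken by input order with a warning), and *min–max*
is the worst value over the stay — the minimum for every parameter
except RDW, whose maximum is unfavorable.  Anemia grading from a
hemoglobin value: severe < 80 g/L; moderate 80–109 g/L (implemented as
the half-open interval [80, 110) since HGB is continuous);
below-reference between 110 g/L and the sex-specific normal value
(130 g/L men, 120 g/L women); none otherwise.  The caller chooses
which measurement feeds the classifier.  Group comparisons use the
tie-corrected two-sided Mann–Whitney U with BH-FDR within the
comparison family; correlations with neurological scale scores use
Spearman's rho with a minimum of 5 complete pairs per cell.

## Regression with genetic covariates

Each model regresses one endpoint on sex (dummy: male 1 / female 2),
age (years), a clinical-status dummy appropriate to the timepoint
(admission severity for *first*; outcome for *final* and *min–max*),
and the per-person QV count in one gene set.  The dependent and
continuous covariates are z-scored; dummies enter as coded (the
conventional "standardized beta with raw dummies" choice).  CIs use
the t critical value with n−k−1 df.  Diagnostics per fit: Durbin–
Watson with the 1.50–2.50 acceptance range as a flag, Breusch–Pagan
LM (n·R² of squared residuals on the design), VIF with a flag at 5,
and Shapiro–Wilk on residuals — reported but never gating, since with
more than ten observations per covariate OLS tolerates moderate
non-normality.  Screening applies BH separately to overall-F p-values
and to covariate p-values within each declared family, both at
FDR 0.1.

## Synthetic cohorts

The generator draws, from one seed: a variant catalog with an
exome-like composition (defaults: 2% HI, 40% missense, 35% synonymous;
AF point masses from 5×10⁻⁵ to 0.3; 25% of background variants absent
from the reference database and simulated ultra-rare, true AF
= 1/(4n)); genotypes as independent binomial(2, AF) draws; gene sets
with planted genes carrying rare HI sites (default AF 9×10⁻⁴, below
the rarity threshold); a binary anemia-like phenotype; and RBC panel
series.

Two modelling choices matter for interpreting recovery tests:

* **Per-gene carrier liability.** The phenotype follows
  `logit P(case) = b₀ + log(OR) × (number of planted genes carried)`.
  A set-level 0/1 exposure would make the gene-stratified CMH common
  OR systematically smaller than the planted OR (non-carriers of one
  gene include carriers of others); with per-gene carrier terms each
  stratum's conditional OR equals the planted OR up to negligible
  odds-ratio non-collapsibility at the simulated carrier rates.  The
  intercept is re-centred on the realized mean carrier count to hold
  the marginal prevalence (default 0.5).
* **Endpoints first, series second.** First and final values follow
  the standardized linear model (variance budget: coefficients plus
  residual sum to 1, then scaled to clinical units); the worst value
  dips below the better of the two by a half-normal amount (rises, for
  RDW).  The series is constructed to pass exactly through the
  planted first/worst/final values (interior points interpolate and
  may go missing), so endpoint extraction recovers the planted values
  bit-exactly and end-to-end tests are sharp.  Because standardizing
  by the realized sample SD makes the estimand of a standardized
  regression cohort-specific, the ground truth records the *realized*
  standardized beta (planted beta divided by the realized endpoint SD
  on the standardized scale); t-CIs cover that quantity at their
  nominal rate, whereas coverage of the fixed planted value is
  slightly above nominal.

What the generator does **not** emulate: linkage disequilibrium,
population structure, sequencing error, cohort-specific enrichment of
variants beyond their population frequency (real cohorts showed
per-gene carrier counts far above reference AF expectations), and
treatment effects on trajectories.  Passing recovery tests therefore
demonstrates correctness of the estimators and calibration of the
tests under the stated sampling model, not robustness to those
real-data features.

## Problem sizes used in the tests

The statistical recovery tests use the sizes the analyses are designed
for: CMH coverage/calibration on cohorts of 1000 samples (≈500 cases /
500 controls) with one 10-gene set of 100 rare HI sites, 200
replicates each for the effect (OR 2.5) and null arms; regression
recovery on cohorts of 300 with a planted standardized beta of −0.4 on
MCHC, 200 replicates, a 7-endpoint screen at FDR 0.1; the exact-test
oracle sweep covers ≥1000 random tables/strata with totals ≤ 30 (≤ 10
per stratum for the brute-force CMH oracle, whose cost is the product
of stratum supports); endpoint extraction is verified exactly on
10,000 random series.  Unit tests use cohorts of 15–60 samples.

## Reproducibility

All randomness flows from a single top-level seed; pipeline stages
derive seeds by stable hashing of stage names.  One seed yields
byte-identical VCF/GMT/TSV/JSON outputs; the run manifest records the
config hash, input checksums and per-stage row counts, and re-running
on identical inputs reproduces identical output checksums.

## Known limitations

* The exact CMH two-sided convention (tail doubling) is conservative;
  a minimum-likelihood two-sided variant is not currently exposed.
* The exact Mann–Whitney mode enumerates labelings and is limited to
  small pooled samples (the normal mode handles the rest).
* Gene symbols are matched exactly (case-sensitive, whitespace
  stripped); alias resolution belongs upstream.
* The per-variant scan uses carrier (dominant) coding only, matching
  the collapsing analyses; allelic trend tests are out of scope.
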