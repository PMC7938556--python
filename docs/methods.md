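# Methods

## The cohort-identification model

`phenokit` operationalises multi-criterion electronic phenotyping over a flat
EMR extract: seven linked tables (encounters, reason-for-visit, forms,
orders, procedure results, diagnoses, documents) keyed by `encounter_key`,
with encounters additionally keyed by `person_key`. Each criterion is a pure
OR over an encounter's rows in one table, so criteria are monotone: adding
child rows can switch a flag on but never off. The score is the flag sum;
eligibility is score ≥ 1. There is no weighting, no probabilistic model and
no person-level lookback inside the criteria themselves — patient history
enters only afterwards, when reference encounters of index patients are
co-extracted back to a configurable epoch (default 2002-01-01, inclusive at
midnight; the epoch is stated to the day only, so midnight inclusion is a
package choice).

Assumptions: one row per encounter in the encounters table (duplicate keys
are fatal); free-text absence is the empty string, on which every match is
vacuously false; `year` is the calendar year of the ISO-8601 admission
timestamp; the facility → district map and the order-name → category
catalogue are configuration, not code.

## Keyword matching and lexicon construction

Matching is case-insensitive literal search over explicit variant lists —
the constraint of production query languages without regular expressions.
Two refinements, both configurable:

* **Word-boundary hybrid.** Variants shorter than `word_boundary_below = 4`
  characters must match a whole alphanumeric token; longer variants match as
  plain substrings. Raw substring semantics make two-letter abbreviations
  ("cp") fire inside unrelated words; requiring token identity only for
  short variants preserves the literal-matching spirit while avoiding the
  pathology. Setting `word_boundary_below = 0` recovers pure substring
  matching everywhere.
* **Document-level counting.** The lexicon admission rule counts the number
  of corpus documents containing ≥ 1 variant of a term (a document counts
  once however many times a term appears); `min_count = 20` is the default
  inclusive threshold at a corpus scale of roughly 30,000 triage documents.
  Occurrence-level counting is available as a switch, as is exempting
  clinician seed terms from the threshold (`exempt_seed_terms`, default
  off — the default filters every candidate alike).

The packaged default lexicon is a **stand-in**: a small set of
clinician-plausible ACS terms with example misspellings and abbreviations.
The term list actually used in the study this design follows is not public,
so the default exercises the mechanism, not the content; any analysis of real
data should supply its own term CSV.

## Composition analytics

Combination counts use exclusive (UpSet) semantics: each eligible encounter
contributes to exactly one 7-bit pattern, so patterns sum to the eligible
count and marginalise exactly to the per-criterion counts — both identities
are asserted in tests. The flag correlation matrix is the Pearson
product-moment correlation of the 0/1 columns, which for binaries equals the
phi coefficient; correlations involving a constant column are reported as
absent (NaN/None), never coerced to 0, and criterion 4 (met by nothing under
the default profile) is retained in all outputs as an explicit zero row.
Percentages are formatted at one decimal for marginals and whole percent for
combination shares; raw counts are always carried alongside.

## The synthetic generator

### What it emulates

* **Stratified prevalences.** A `CalibrationProfile` lists strata
  (year × district, each with a row count) and per-criterion marginal
  probabilities *among eligible encounters* — the scale on which published
  prevalence tables report. The packaged default encodes the published
  2013–2017 per-year percentages, identical across the two districts.
* **Pairwise dependence.** Target phi coefficients between named flag pairs,
  induced by a Gaussian copula: for each pair the latent normal correlation
  is solved by bisection on the bivariate normal CDF so the thresholded
  binaries hit the target joint probability; off-pair latent correlations
  are 0, and the assembled matrix is repaired to the nearest
  positive-semidefinite correlation (eigenvalue clipping, logged) if needed.
  Feasibility is enforced at profile load via the Fréchet bounds
  `phi ∈ [(max(0, p_i+p_j−1) − p_i p_j)/σ, (min(p_i, p_j) − p_i p_j)/σ]`.
  Notably, a phi of 0.9 between flags at 3.1% and 1.2% prevalence is outside
  these bounds (the maximum is ≈ 0.61): a strong code/procedure association
  at rare marginals cannot be represented — by any binary model, not just
  this one. The default profile therefore carries the (c6, c5) pair at 0.55,
  and the 0.9-recovery demonstration uses balanced 0.5/0.5 marginals, where
  it is feasible.
* **Eligible-conditional calibration.** Sampling flags at the published
  marginals directly would understate them after conditioning on
  eligibility. Because any set flag implies eligibility,
  P(X_k | eligible) = p_k / (1 − P0) with P0 = P(all flags false), so base
  marginals solve the fixed point `p = t · (1 − P0(p))`. P0 is estimated on
  a fixed, seeded copula sample of 100,000 draws reused across iterations
  (common random numbers); the residual error in the recovered prevalences
  is a few hundredths of a percentage point. Eligible rows are then obtained
  by rejection (discarding all-false draws), and reference rows are injected
  by the `ineligible_fraction` switch (default 0.2 — enough to exercise the
  cohort split at desk scale; the real eligible:reference ratio of roughly
  1:7 would mostly generate rows the analytics ignore).
* **Flag-faithful rendering.** Each flag vector becomes linked table rows:
  true flags plant qualifying rows (a positive text template with a randomly
  chosen lexicon variant, a qualifying order/result/diagnosis/document);
  false flags receive only rows that cannot satisfy the criterion —
  negative texts validated at build time to match no lexicon variant,
  non-qualifying categories, absent results. Innocuous noise rows are added
  with fixed probabilities so false flags are not simply empty tables. This
  makes rendering the exact inverse of evaluation: re-evaluating a rendered
  bundle reproduces the flag matrix bit-for-bit, a property tested on 1,000
  random matrices.
* **Persons and reproducibility.** Encounters are clustered into persons
  with geometric cluster sizes (mean 1.5 encounters/person). One root seed
  drives everything through `numpy.random.SeedSequence` spawning, one child
  stream per stratum, so strata are independently reproducible and a
  `generate()` call is deterministic given (profile, seed).

### What it does not emulate

Realistic clinical language (texts are templated), troponin values, vitals
or outcomes, within-stratum dependence beyond the configured pairs,
between-district differences (both districts share marginals), coding drift
within a year, or re-identification risk. Passing tests on synthetic data
therefore demonstrate the *mechanics* of the pipeline — matching, scoring,
counting, calibration recovery — not clinical validity of the criteria on
real narratives, which requires a gold-standard validation study outside
this package's scope.

## Numerical choices

* Bisection for the pair correlation runs 60 iterations on ρ ∈ (−0.9999,
  0.9999) to a 1e-10 bracket; the bivariate normal CDF comes from scipy.
* ICD-10-AM codes are normalised (strip dots and whitespace, upper-case)
  before prefix matching against I21–I25; empty codes are skipped with a
  warning rather than failing the row. SNOMED matching is case-insensitive
  substring over diagnosis description phrases, since the rule is stated in
  phrases, not concept identifiers.
* Combination patterns tie-break by pattern string after descending count,
  making reports deterministic.
* Degenerate inputs: empty corpus → all-zero frequencies; empty text → no
  match; zero eligible encounters → percentages reported absent, not 0;
  fewer than two eligible rows → correlation matrix absent.

## Problem sizes

Default simulation sizes were chosen so the whole suite and the acceptance
script run comfortably on a single CPU: 2,000–3,000 encounters per stratum
for structural checks, 20,000 encounters for prevalence recovery (binomial
SE ≈ 0.4 percentage points among eligible, well inside the ±1-point check),
and 50,000 draws for phi recovery (SE ≈ 0.002). Larger runs only tighten
the same estimates.

## Known limitations

The orphan-row policy treats referential integrity as per-row, not
transactional; the generator's noise rows use fixed probabilities rather
than learned distributions; the default lexicon is illustrative; and the
eligible-conditional calibration targets marginals, so higher-order
interactions among flags beyond the configured pairs are whatever the
copula implies, not calibrated quantities.
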