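# Methods

## Overview

The package reconstructs a two-stage epidemiological analysis of adult
head circumference (HC): (1) define microcephaly via stratified
mean − 2SD cutoffs after screening which covariates HC depends on, and
(2) mine association rules linking microcephaly to clinical and
sociodemographic items. Because the underlying autopsy data are
restricted, a synthetic cohort generator provides inputs with the same
statistical structure; everything downstream treats a cohort table as
opaque input, so real data with the same schema can be substituted
directly.

## Synthetic cohort model

One subject is drawn as:

- **sex** ~ Bernoulli(p_female = 0.477);
- **age** ~ Normal(70.8, 12.7²) years truncated to ≥ 50 (the study
  design's inclusion bound). The implied P(age ≥ 70) is ≈ 0.553; the
  age-group marginal is therefore a model consequence, not a free
  parameter;
- **education**: a three-level category (illiterate 15.8%, 1–4 years
  54.8%, ≥ 5 years 29.4%); years are drawn uniformly within the level
  (0; 1–4; 5–15). The level marginals are the calibrated quantities;
  mean years is a consequence;
- **height** ~ Normal(1.73, 0.07²) m for men, Normal(1.62, 0.07²) m
  for women — pooled mean ≈ 1.68 m. (The reference series prints a
  height SD of "10.3" with metre units; we read it as 10.3 cm.)
- **HC** = 47.234 + 4.3·height(m) + 1.627·[male] − 8.0·[low tail]
  + ε, ε ~ Normal(0, 2.3²) cm, clipped to the plausibility range
  [40, 70] cm. The slope (4.3 cm/m = 0.043 cm/cm) matches the scale of
  the reference regression coefficient; intercept and sex offset are
  calibrated so sex-specific means are ≈ 54.2 (women) / 56.3 (men) cm;
- **low tail**: with probability `low_tail_inflation` (default 0.055)
  a subject's HC is shifted down 8 cm. A pure per-stratum Gaussian
  yields a sub-(mean − 2SD) fraction of Φ(−2) ≈ 2.28%, below the
  ≈ 4.7% adult prevalence reported from autopsy data; the mixture
  raises it. Closed-form calibration (mixture mean −πΔ, variance
  σ² + π(1−π)Δ²) gives an implied sub-cutoff fraction ≈ 4.5% at the
  defaults. The within-stratum HC SD inflates to ≈ 2.9–3.2 cm
  (reference: 2.2–2.6 cm); we accepted this trade-off rather than
  shrinking the base residual further, since the tail fraction and the
  rule structure, not the SD itself, drive the downstream analysis;
- **brain volume** = −385 + 28.1·HC + ε, ε ~ Normal(0, 144²) mL,
  floored at 1 mL — calibrated to pooled mean ≈ 1,169 mL, SD ≈ 163 mL
  and an HC correlation ≈ 0.47;
- **comorbidities**: nine independent Bernoulli flags at the reference
  marginals (hypertension 0.647 … cardiac arrhythmia 0.069).
  Independence between flags is a simplification; real comorbidities
  co-occur (diabetes–hypertension etc.), so cross-comorbidity rules in
  simulation carry lift ≈ 1 by construction;
- **cognitive impairment**: a latent state with
  logit P = −3.03 + 2.11·[age ≥ 70] + 0.60·[low tail]. The
  coefficients are fixed by three anchors: P ≈ 0.046 for younger
  subjects, ≈ 0.284 for age ≥ 70, ≈ 0.42 for age ≥ 70 with a low-tail
  HC — so the marginal P(CDR > 0.5) ≈ 0.17–0.18 and the
  microcephaly–dementia lift gap emerge rather than being injected
  per rule. The low-HC input is mixture-component membership, the
  causally sensible stand-in for "microcephaly-range HC" (classified
  microcephaly is itself an output of the cutoff stage);
- **CDR** is > 0.5 exactly when the latent state fires (values drawn
  from {1, 2, 3} when impaired, {0, 0.5} otherwise); **IQCODE**
  crosses 3.4 with probability 0.95 given impairment
  (`cdr_iqcode_agreement`) and 0.017 otherwise, reproducing
  CDR ⇄ IQCODE confidences near 95%/93% and the IQCODE marginal
  ≈ 0.179.

All draws flow from one `numpy.random.Generator` seeded in the config;
no global state. Identical configs give bitwise-identical CSVs. The
generator emulates marginals and the specific conditional couplings
above — not autopsy logistics, cause of death, missing data (the
pipeline is complete-case by construction) or secular height trends.
Passing tests therefore demonstrate correctness of the *pipeline*, not
fidelity of any particular real population.

## Screening

Implemented from first principles: Spearman rho is the Pearson
correlation of average ranks, with the t-approximation p-value on
n − 2 df (an exact permutation null is impractical at n ≈ 2,500 and
unnecessary at these effect sizes); the sex comparison is the classic
pooled-variance t-test (a Welch option exists but is off by default,
matching the plain "independent samples" convention); the multivariate
model is OLS via the normal equations with t-based 95% CIs. Height
enters the regression in cm (coefficient ≈ 0.04 cm of HC per cm of
height), sex as female = 1. Significance is two-tailed at 0.05.
Rank-deficient designs raise a collinearity error naming the columns
whose removal restores full rank. scipy/statsmodels serve as
independent cross-checks in the test suite only.

## Cutoffs and classification

Strata are sex × half-open height bins (lower edge inclusive):
[−∞,1.60), [1.60,1.70), [1.70,1.80), [1.80,∞) m — the 10 cm divisions
used in adult HC references. Cutoff = stratum mean − 2·SD (sample SD,
n − 1 denominator; per-stratum SDs, not pooled), stored at full
precision; one-decimal rounding happens only at the reporting layer.
Classification uses strict `<` against the unrounded cutoff, so a
subject exactly at the cutoff is not microcephalic. A stratum with no
subjects is omitted (and listed as missing); a singleton stratum is an
error, since its SD is undefined. At the reference sample size the
tall-female cell averages only ~6 subjects, so occasional simulated
replicates are unusable for classification; calibration tests draw a
replacement replicate in that rare case.

## Transactions and mining

Encoding dialect: multi-level variables (age group, sex, education)
contribute one item per level — both `male` and `female` exist as
items, because sex appears as a consequent in both directions — while
binary clinical flags contribute a presence item only (no
"no-hypertension" items). Thresholds as printed in the screening
conventions: CDR strictly > 0.5; IQCODE ≥ 3.4 and age ≥ 70 inclusive.

The miner is a textbook level-wise Apriori: candidate k-sets are
lexicographic joins of frequent (k−1)-sets sharing a (k−2)-prefix,
pruned by the anti-monotone property, counted by transaction scan.
Support and confidence thresholds are both inclusive (≥). Consequents
are restricted to single items (a rule of size three = two antecedent
items + one consequent). Defaults: min support 0.01, min confidence
0.30, max rule size 3 — chosen low because the focus item is rare.

**Lift normalisation.** A count-ratio formulation of lift
(occ(X∪Y) / (occ(X)·occ(Y))) is off by a factor of N from the
probability-scale quantity; we implement
lift = confidence / support(consequent), the definition under which
1 means independence and which reproduces the standard worked values
(e.g. confidence 0.954 against a consequent support of 446/2508 gives
lift 5.4). Output ordering is lift desc, confidence desc, support
desc, then lexicographic — a total, deterministic order.

## Focus comparison

For each mined rule with the focus item in a two-item antecedent, the
counterpart rule drops the focus item and keeps the consequent. When
the counterpart was not itself emitted — typically because its
confidence falls below the 30% floor, which is exactly what happens to
`age ≥ 70 ⇒ CDR > 0.5` at ≈ 28% — its metrics are recomputed from raw
occurrence counts and flagged "sub-threshold" rather than reported
missing. Whether confidence and lift are higher with the focus item is
reported per pair, never asserted.

## Numerical choices and determinism

- Cohort CSVs round-trip exactly (`float_precision="round_trip"` on
  read; Python repr on write).
- All rule metrics are exact integer-count ratios; tests verify
  confidence·occ(X) = occ(X∪Y) in integer arithmetic.
- Reports, rule exports and the pipeline manifest are byte-stable
  under a fixed config; the manifest stores SHA-256 hashes of every
  artifact.
- Degenerate inputs: zero pooled variance with equal means gives
  t = 0, p = 1; an exact OLS fit reports zero-width intervals;
  constant vectors make Spearman undefined (error).

## Problem sizes

Simulation-based tests run at n = 2,508 (the reference sample size)
for pipeline-level properties, n = 10,000 for marginal-recovery checks
over 20 seeds, and n = 50,000 for the Gaussian-tail check; the miner
oracle uses 200 random databases of at most 8 items and 50
transactions, where brute-force enumeration is exact and fast. The
sub-cutoff tail check is restricted to strata with n ≥ 8,000, where
binomial noise is small against the ±0.4-point band.

## Known limitations

- Comorbidity flags are mutually independent, so the simulation cannot
  reproduce real comorbidity–comorbidity rules (e.g. diabetes ⇒
  hypertension with lift ≈ 1.4 in real data).
- The conditional sign of the female coefficient in the multivariate
  HC model (positive in the reference series once brain volume and
  height are held fixed) is not forced by the generator; simulated
  screening finds sex significant but with the marginal (negative
  female) direction.
- The reference series' exact rule counts and regression coefficients
  are data-dependent and not recoverable from any simulation; the
  package targets the printed worked values (cutoffs, lifts) and the
  qualitative structure instead.
- Mining cost grows with the candidate lattice; the implementation is
  adequate for tens of items and ~10⁴ transactions, not for
  market-basket-scale inputs.
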