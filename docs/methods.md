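# Methods

## The family risk score

The FamRS is a ratio of observed to expected affected-relative weight.
Each affected first-degree relative contributes an onset weight
(defaults: 2.0 if diagnosed before age 60, 1.0 at 60 or later, 1.5 if
the age at onset is not remembered); every *reported* relative —
affected or not — contributes to the expected sum an entry from a table
indexed by the participant's 10-year age band (defaults: 0.10 per
relative at 35–44 rising linearly to 0.30 at 75–84, identical across
relations). Relatives that were never reported contribute to neither
sum. The ratio form has three consequences we rely on:

- a family with no affected relatives scores exactly 0, producing the
  characteristic point mass of the non-case score distribution;
- the score is invariant to jointly rescaling all onset weights and all
  expected-risk entries;
- two relatives affected before age 60 always exceed the
  very-strong-positive cut (score > 2) for any family of up to six
  reported relatives and any participant age band: the observed sum is
  then at least 4.0 while the expected sum is at most 6 × 0.30 = 1.8.

One monotonicity caveat is intrinsic to the ratio form: adding a
*late-onset* affected relative to a family that already scores above
w(≥60)/e can lower the score, because the new relative raises the
denominator relatively more. The properties that do hold (and are
tested): the observed sum strictly increases, an affected addition
always beats the same addition unaffected, unaffected additions never
raise the score, and upgrading a relative's onset from ≥60 to <60 never
lowers it.

Category boundaries are right-closed at each cut (≤ 0.5 average,
≤ 1 positive, ≤ 2 strong positive, > 2 very strong positive). The exact
onset weights and expected-count table are configuration, not
constants: published versions of such scores specify them in ancillary
material, and all entries can be overridden from YAML.

## The polygenic score engine

Scores are dosage sums over a scoring file (PGS-Catalog TSV dialect).
Variant matching is exact on chromosome + position + allele pair; when
the scoring file's effect/other alleles are swapped relative to the
VCF's REF/ALT, the dosage is reflected (d → 2 − d), making every score
invariant to the VCF's allele orientation. Strand-ambiguous pairs (A/T,
C/G) cannot be oriented without frequency information and are excluded
by default (includable by flag). Missing variants contribute zero by
default; `mean_impute` substitutes the Hardy–Weinberg mean 2f;
`require_any` errors when a person matches nothing. Standardisation
uses the in-sample mean and sd (n − 1); percentile group b holds rank
fractions in ((b−1)/20, b/20]; "top q%" means strictly above the
empirical (100−q)th percentile, with ties broken by stable input order
so outputs are deterministic.

## Epidemiological models

All effects come from logistic regression (IRLS via statsmodels to a
deviance tolerance of 1e−14, ≤ 100 iterations), with Wald 95% CIs and
p-values. Separation is flagged (any |β| > 15 or a separation warning)
and reported as non-converged rather than silently accepted. Weights
enter as per-observation multipliers of the log-likelihood
(`freq_weights`); the default variance is the naive weighted
information matrix, with a sandwich (HC0) estimator available by flag
since the appropriate estimator for IPCW-weighted fits is a modelling
choice.

Incident models drop prevalent cases from the risk set (asserted, not
assumed) and weight the remainder by 1/Ŝ_C(t−), where the censoring
event is death or loss to follow-up before the administrative end.
Ŝ_C comes from a Cox model (default covariates: age, sex, BMI, physical
activity — configurable, since the choice is not canonical) with a
product-limit baseline

    S0(t) = Π_{t_j ≤ t} (1 − d_j / Σ_{risk(t_j)} exp(x'β)),   S_i = S0^{exp(x_i'β)}

chosen over the Breslow exponential form so that a null covariate
effect reduces *exactly* to the Kaplan–Meier estimator (the
`kaplan_meier` method is the covariate-free special case). With no
censoring events all weights are 1 and the model is flagged degenerate.
Weights are not truncated by default.

Age-stratified models use 10-year bands, collapse FamRS to
average vs above average (> 0.5), include only the two scores
(mutually), and skip bands with fewer than 10 events (configurable).

## Discrimination and reclassification

AUC is the Mann–Whitney concordance probability computed from
mid-ranks, so ties count one half; the "best" threshold maximises
Youden J with ties broken toward higher specificity (the criterion is
exposed in case a different convention is needed). The continuous NRI
counts strict up/down moves of predicted risk — exact ties move
neither way, a deterministic and conservative convention — with per-class
binomial-difference variances for the z statistic. IDI is the change in
discrimination slope with per-class paired-difference standard errors.
Spearman correlation is Pearson on mid-ranks with the t-approximate
p-value.

## The cohort simulator

The generator emulates a population-based study of ~3,000 participants
aged 35–84 (truncated-normal ages, mean 57.4, sd 12.9) with family
history for both parents and all siblings, a small genotyped variant
panel with a scoring file, baseline covariates, and ~11 years of
follow-up for incident disease with death and loss to follow-up
competing.

**Genetics.** Founders draw Hardy–Weinberg dosages (Binomial(2, f),
f ~ U(0.05, 0.5) by default over 50 variants); children receive one
allele per parent, heterozygotes transmitting each with probability
1/2. Effect weights are Gaussian, rescaled so the population sd of the
raw score is 0.123 (a realistic magnitude for a genome-wide T2D score;
the scale cancels after standardisation).

**Liability.** Each person's liability is
L = z_PGS·√(h²·capture) + G_resid + C + E with variance fractions
h²·capture, h²(1−capture), c², and 1 − h² − c², so L is standard normal
in expectation. G_resid is transmitted as mid-parent value plus
segregation noise of variance h²(1−capture)/2, preserving the
parent–offspring covariance h²/2 of the additive part. C is drawn once
per family and shared by **all** members, parents included. Defaults
h² = 0.40 (the middle of published T2D heritability estimates),
capture = 0.5 (a genome-wide score captures part of the additive
variance), and c² = 0.10. The c² default is chosen so the
shared-environment share of the parent–offspring liability covariance,
c²/(h²/2 + c²), is exactly one third — the proportion simulation-based
decompositions attribute to shared environment in the parental T2D
association. A consequence of sharing C with parents is that the
parent–offspring regression slope of liability is h²/2 + c², not h²/2;
the additive-transmission property (slope = h²/2) is therefore verified
in a c² = 0 configuration.

**Onset and follow-up.** Age at onset is Weibull proportional hazards:
h(t) = k·s·t^(k−1)·exp(β_L·L + β_BMI·z_BMI + β_PA·PA), with β_L = 1.5,
a weak adverse BMI effect (0.25 per sd) and protective physical
activity (−0.2). BMI and activity are weakly loaded on C, so the
covariate adjustment in the models has genuine confounding to absorb.
The scale and shape defaults (s ≈ 1.31e−9, k ≈ 4.20) are produced by
`calibrate_onset`: nested Brent root-finds on a common-random-number
Monte Carlo sample (n = 200,000) that solve the scale (parametrised by
the characteristic age t0, s = t0^−k) for 8.3% prevalence and the shape
for 5.3% incidence of the full cohort, under 11 years of administrative
follow-up, death hazard 0.009/y and loss hazard 0.002/y. Follow-up ends
at the first of onset, death, loss, or the administrative boundary;
incident disease requires onset strictly first among the
baseline-disease-free.

**Family history.** Parents are evaluated at the index age + 27 years
(a generational gap that lets parents plausibly fall on either side of
the age-60 onset boundary), siblings at the index age ± Gaussian(0, 4)
years. A relative is reported affected iff their simulated onset
precedes their current age; the onset category (<60 / ≥60) is replaced
by "age unknown" with probability 0.2, a realistic recall-failure rate
for relatives' diagnosis ages. Sibling counts follow
{0: 0.25, 1: 0.40, 2: 0.25, 3: 0.10} (family-size data for such cohorts
are rarely published; the distribution is configurable).

**Determinism.** All randomness flows from one seed through named
`SeedSequence` substreams (panel, founders, transmission, liability,
ages, covariates, onset, follow-up, recall), so identical
configuration + seed yields bit-identical output files, which the
pipeline manifest verifies by sha256.

**What the simulator does and does not emulate.** It reproduces the
study's sampling frame (age structure, prevalence, incidence, follow-up,
family reporting with onset categories) and the qualitative
genetics/environment decomposition. It does **not** model linkage
disequilibrium, assortative mating, genotype imputation error,
within-cohort relatedness between index participants (one per family by
design, matching the independence assumption of the analysis), type 1
diabetes, or recall bias that differs by case status. Passing tests on
simulated data therefore validate the statistical machinery and its
qualitative behaviour, not cohort-specific effect sizes: with a
50-variant panel capturing half the additive variance, per-sd PGS odds
ratios land near 1.8 for prevalent disease rather than the much larger
values attainable with a genome-wide score in a real cohort.

Two deliberate emergent properties: the rank correlation between the
two scores is weak but positive (r² ≈ 0.02–0.04 at n = 10,000),
because relatives' phenotypes are partly driven by transmitted scored
variants; and participant age confounds the *unadjusted* family-score
association even under a global null (h² = c² = 0), because parents age
with their children — null-calibration checks therefore read the
covariate-adjusted models.

**Parameter-recovery design.** Verifying confidence-interval coverage
requires a generator whose true logistic log-odds ratio is known
exactly, which a liability-threshold pathway does not admit in closed
form. `simulate_logistic_outcome` therefore draws the outcome directly
from logit P(y) = logit(rate) + β·z; the recovery study uses
β = ln(1.66) at an incident-like base rate of 5.3%, 200 cohorts of
n = 5,000, and requires ≥ 90% Wald coverage.

## Numerical conventions

- Category intervals right-closed at each cut; percentile bins
  right-closed; top-q strictly above the (100−q)th percentile.
- GLM deviance tolerance 1e−14, ≤ 100 iterations; separation threshold
  |β| = 15; Wald z = 1.959963984540054.
- Ties: AUC mid-ranks; NRI "no move"; PGS ranking by stable input
  order; Youden ties toward specificity.
- Degenerate inputs error loudly: empty relative lists, ages outside
  the expected-risk table, zero score variance, single-class labels,
  constant or collinear design columns, all-missing dosages under
  `require_any`.

## Problem sizes used in the test suite

Calibration checks use one 10,000-family cohort; replicate-based
behaviour checks (shared-environment attenuation, global null) use 100
cohorts of 800 families with a 30-variant panel — large enough for
~65 prevalent cases per replicate, small enough that the median across
replicates is stable; parameter recovery uses 200 direct-logistic
cohorts of n = 5,000. These sizes are the package's own choice of a
stable-but-economical design.

## Known limitations

- The default expected-risk table is generic; with it, the simulator's
  relative-affection rates produce a more right-shifted FamRS category
  distribution than a real interview-based cohort. Supplying a
  population-calibrated table restores realistic category frequencies.
- IPCW assumes censoring is explained by the chosen covariates;
  weights are untruncated and can be large under heavy censoring.
- Wald inference is first-order; rare exposure categories (e.g. top 1%
  contrasts in small cohorts) may separate and are flagged rather than
  rescued.
- The NRI/IDI z statistics use the classical normal approximations,
  which are known to be anti-conservative in small samples.
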