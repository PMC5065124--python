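# Methods

## Study design being emulated

The package targets the analysis of a multi-study case-control consortium
testing genome-wide SNP × alcohol and SNP × smoking interactions on disease
risk.  Genotypes enter as allele dosages (expected alternate-allele copies
in [0, 2], from imputation), treated log-additively.  Alcohol is harmonised
from grams/day into three categories — non/occasional (< 1 g/day),
light-to-moderate (1–28 g/day, both boundaries included, reading the
printed closed interval against its strict neighbours), heavy (> 28 g/day)
— and coded by indicators, because light-to-moderate and heavy drinking
have opposite associations with risk and a single linear term would average
them away.  The categorical-vs-continuous choice is adjudicated by AIC with
a 6-point decision margin.  Smoking is ever/never plus pack-years
(packs/day × years; never-smokers are 0); because the published per-unit
scaling for pack-years is reported inconsistently (per 10 in one place, per
20 in another), the scaling is an explicit parameter rather than a
constant.

## Synthetic consortium generator

`simulate_cohort` draws, per study: HWE genotypes at the configured MAF; a
3-category exposure from a multinomial logit with a linear dosage term
(`P(E=k|G) ∝ p_k·exp(θ·G·1[k>0])`, so θ = `ge_corr_beta` is the per-allele
log-OR of drinking and θ = 0 gives exact G–E independence); sex, age
(N(62, 8²) years), smoking, and three standard-normal PCs (nuisance
adjusters only, no confounding unless configured); disease from the
logistic model with the configured main-effect and interaction log-ORs and
per-study intercept.  Cases and controls are filled retrospectively by
rejection sampling (candidates drawn until the requested counts are met,
capped at 10⁷ draws per study, then a diagnostic error).  Defaults mirror
the alcohol-analysis consortium scale: 14 studies × 575 cases/625 controls
(~16,800 subjects), MAF 0.33, category probabilities (0.47, 0.45, 0.08),
exposure main-effect ORs 0.91 and 1.22, baseline logit −2.2.

Seed discipline: one master seed; per-study streams, the genome stream, the
grams/day stream and per-permutation streams are derived through fixed
`SeedSequence` spawn keys, so any stratum or permutation is independently
reproducible.  `spike_signal` re-simulates from the stored config with the
causal variant moved to the requested id (keeping that variant's simulated
MAF); with a zero coefficient and the same seed it reproduces the null
cohort byte-for-byte.

What the generator does **not** emulate: linkage disequilibrium between
variants (all independent), imputation error beyond an assignable R² label,
study-level covariate confounding, age/sex effects on disease, or
questionnaire measurement error in exposures.  Passing tests therefore
demonstrate correctness of the statistical machinery under a clean
multiplicative logistic world, not robustness to those real-data features.

## Fitting engine

All logistic fits use a hand-rolled IRLS (Newton) solver with tolerance
1e-8 on the maximum coefficient change and 50 iterations, batched across an
item axis so thousands of per-variant or per-permutation fits sharing one
shape run as a few einsum calls.  Numerical choices: working weights
floored at 1e-10; a diagonal-relative ridge of 1e-14 (plus 1e-30 absolute)
keeps exactly singular systems solvable so that separated or degenerate
fits run off to the divergence bound (|β| > 30) and are *flagged* rather
than raising; covariance is the inverse observed information at the
optimum, computed only for converged items.  The single-fit path agrees
with statsmodels' Newton ML to ~1e-12 on well-posed data (tested), and the
batched path agrees with the single path to 1e-8.

## Per-stratum models and pooling

Strata are study × sex for alcohol (men and women analysed separately;
motivated by sex differences in alcohol metabolism and consumption) and
study with sex as a covariate for smoking-type exposures.  The adjustment
set is age + three PCs (+ centre indicators within multi-site studies —
modelled as covariates, not separate strata).  Subjects with missing dosage
or exposure are dropped from the affected variant's analysis only; a
per-stratum minor-allele-count gate (MAC > 5) and instability limits
(|β| > 10 or SE > 10) exclude fragile stratum fits from pooling, with the
exclusion visible in the per-variant stratum count k.  Pooling is
inverse-variance fixed-effects; heterogeneity is Woolf's
Q = Σ wᵢ(βᵢ − β̄)² on k−1 df.  Interaction inference is per term (G×E₁ and
G×E₂ each Wald-tested, matching a single reported interaction p for
light-to-moderate drinking); a joint 2-df Wald test is available on the
stratum fit.  λ is computed from the interaction-term p-values only.

The case-only estimator regresses the exposure indicator on dosage among
cases (covariate-adjusted), restricted to the two contrasted exposure
levels.  The empirical-Bayes combination is

    β_EB = (θ̂²·β_CC + var_CC·β_CO) / (θ̂² + var_CC),

θ̂ the G–E log-OR among controls; its variance uses the delta method
treating (β_CC, β_CO, θ̂) as independent (derivation in the code).  The
limits behave as required: θ̂ = 0 → case-only, |θ̂| → ∞ → case-control,
agreement is a fixed point.

## Cocktail two-step procedure

Screening computes, for every variant on the pooled sample with study
indicators: the marginal disease-association z and the G–E correlation z
(logistic regression of the exposure indicator on dosage, cases and
controls combined).  The screen statistic is the larger |z|; variants are
ranked by its p-value (ties broken by genomic position).  Alpha allocation
follows the doubling weighted-hypothesis scheme: group j holds B·2^(j−1)
ranks with per-variant threshold α·2^(−j)/(B·2^(j−1)); B defaults to 5 and
the summed budget is strictly below α.  The published description does not
restate the group constants, so both are configuration.  Testing uses the
case-only statistic when the marginal screen won and the case-control
interaction statistic when the correlation screen won, on a single binary
exposure contrast (light-to-moderate vs non/occasional by default) so that
each variant receives one rank and one test p.  Screening on the pooled
sample (rather than stratified-then-meta) is a design choice the source
description leaves open.

## Permutation engine

Case/control labels are permuted within study × sex strata (the analysis
strata; the permutation blocks are configurable since the published scheme
is unstated), preserving per-stratum case counts, and the per-stratum
fit + meta pipeline is recomputed per permutation.  The permuted model is
fitted on the exposure contrast of the tested term (non/occasional vs
light-to-moderate for G×E₁), exactly as in the case-only and Cocktail
testing steps: in small strata the other exposure level's sparse cells
would otherwise destabilise permuted fits without informing the tested
term.  The empirical p uses
the add-one estimator (r+1)/(B+1), valid for any B.  The permutation count
a reported p warrants is ceil(1/p) — 20,000,000 at 5×10⁻⁸ — which is
cluster-scale; the engine executes any requested B with identical
bookkeeping and refuses B beyond an explicit budget parameter.

## Stratified reports and absolute risk

Hard genotype calls for stratified tables use dosage thresholds 0.5/1.5
(ties to the heterozygote).  The within-genotype table fits the exposure
contrast per analysis stratum and pools; the joint-reference table fits
indicator terms for the five non-reference genotype × exposure cells in one
model per stratum and pools per cell.  Absolute risks consume the
joint-reference ORs and control prevalences: I_ref = I/Σ OR·P and
rate = I_ref·OR, so the prevalence-weighted mean of cell rates equals I
identically.  Two published anchors circulate for the SEER 1982–2011 White
population rate (42.9 and 74.5 per 100,000 person-years); the default is
74.5, the value the published absolute-risk table is anchored to, and
either can be supplied.  CIs are percentile bootstrap (resampling subjects
with replacement within study strata, 200 resamples by default); BCa was
judged unnecessary at these sample sizes.

## Problem sizes used in the test suite

Monte-Carlo checks run at desk scale, chosen once: type-I calibration on
2,000 null consortia of 5 studies × 200/200; parameter recovery at
log(0.8) over 200 consortia of 8 studies × 1,000/1,000; Cocktail
family-wise error over 300 replicates of 1,000 null variants × 500/500;
case-only bias at θ = 0.2 over 300 replicates of 1,000/1,000; permutation
exactness at B = 199 over 300 replicates of 150/150.  Binomial tolerances
are exact 99% intervals (two-sided for calibration, one-sided for error
bounds).

## Known limitations

No LD means the scan's multiplicity behaviour under correlated tests is
not exercised; Wald p-values in very small strata are approximate (the
MAC/instability gates mitigate but do not remove this); the case-only and
EB estimators assume the exposure contrast is binary; genotype imputation,
PC computation and phasing are out of scope — dosages and PCs are consumed
as given.
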