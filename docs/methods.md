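# Methods

## Scope and model of the problem

`pefkit` derives potency equivalence factors (PEFs) for carcinogenic
polycyclic aromatic hydrocarbons (PAHs) relative to benzo[a]pyrene (BaP)
from rodent tumor-incidence bioassays. The pipeline has three stages:

1. **Screening.** Bioassay experiments are filtered by pre-registered
   inclusion rules (tumor *incidence* endpoint, physiological exposure
   route, a concurrent BaP comparator arm in the same publication), then
   by dose–response rules (response at the single or lowest non-zero dose
   ≤ 50% in both arms, no non-positive result, no excess mortality), and
   finally by modeling-suitability flags (minimal response, non-monotonic
   dose–response, high control response).
2. **Benchmark-dose modeling.** Each surviving arm is fit with the
   standard suite of nine dichotomous (quantal) dose–response models under
   a binomial likelihood, and the dose giving 10% extra risk,
   `[P(d) − P(0)] / [1 − P(0)] = 0.1`, is the BMD₁₀. Posterior model
   probabilities from Laplace-approximated marginal likelihoods combine
   the per-model BMD distributions (Bayesian model averaging, BMA).
3. **PEF computation.** `PEF = BMD₁₀(BaP) / BMD₁₀(target)`, with the BaP
   BMD from the same publication (concurrency), then per-chemical
   arithmetic aggregation.

## Screening rules and their edge cases

The ≤50% rule is applied as "≤ passes, > fails" to the response fraction
at the single dose (single-dose arms) or the lowest non-zero dose
(multi-dose arms); mixed designs apply each arm's own rule. Conditions
that cannot be computed from printed group data — excess mortality,
author-declared non-positive results, missing incidence counts — are
carried on the record as structured annotations and fail the record when
present; nothing is imputed. A *non-positive* result is computed when an
arm has zero tumor-bearing animals at every dose: one inert arm blocks a
potency ratio regardless of the other arm.

Adjudications (`force_pass` / `force_fail`) let a catalog record reproduce
a historical inclusion decision that deviates from the strict rule; the
strictly computed reason codes are retained next to an `ADJUDICATED`
marker. The packaged catalog uses a single `force_pass`: one
initiation/promotion CPP study whose BaP arm responds at 58% at the lowest
dose but which the evidence base retains as acceptable.

Modelability flags operate on the *target* arm: `MINIMAL_RESPONSE` when
the best group has ≤ 1 tumor-bearing animal or ≤ 5% response,
`NON_MONOTONIC` when the peak response sits strictly below the top dose,
and `HIGH_CONTROL_RESPONSE` when any control group of either arm exceeds
5% response. All thresholds live in `ScreeningConfig` and the screen is a
pure function of (record, config).

## Dose units

PEF ratios are formed on a mass basis. Molar doses are converted at load
time (`nmol × g/mol → ng → mg`; `mmol/kg × g/mol → mg/kg`) using
molecular weights computed from molecular formulas with 4–5 significant
digit atomic masses (C 12.011, H 1.008, …), so the package needs no
chemistry database. Skin-painting doses are per-application amounts and
are modeled in the units given for each dataset; no body-weight
normalization or dose-rate adjustment is applied, and none is needed for
the ratio as long as both arms share units.

## The quantal model suite

Nine families, in conventional background-additive parameterizations
(`g` = background, `P(0) = g` for the log-dose families):

| family | P(d) |
|---|---|
| quantal linear | g + (1−g)(1 − e^{−bd}) |
| logistic | 1/(1+e^{−a−bd}) |
| probit | Φ(a + bd) |
| log-logistic | g + (1−g)/(1+e^{−a−b ln d}) |
| log-probit | g + (1−g)Φ(a + b ln d) |
| gamma | g + (1−g)·GammaCDF(bd; α) |
| Weibull | g + (1−g)(1 − e^{−b d^α}) |
| dichotomous Hill | g + (1−g)·v/(1+e^{−a−b ln d}) |
| multistage (degree 2) | g + (1−g)(1 − e^{−b₁d − b₂d²}) |

Every family is non-decreasing in dose over its whole parameter support
(property-tested), and every family admits a closed-form extra-risk
inversion; a bracketed Brent root-finder provides an independent
cross-check at 1e−8 relative tolerance. For logistic and probit the
inversion and the extra-risk function use complementary (survival) forms,
which stay accurate when the background probability approaches 1.

### Soft constraints (priors)

Power and slope parameters are *unrestricted* — no hard bound at 1 — and
regularized by soft priors on transformed scales, the consensus approach
for Bayesian averaging of quantal models. Defaults, all centralized in
`FitConfig.prior_overrides`:

| parameter kind | transform | prior | bounds (transformed) |
|---|---|---|---|
| background g, plateau v | logit | Normal(0, 2) | ±18 |
| slope b, b₁, b₂ | log | Normal(0, 2) | ±18 |
| power/shape α, ln-dose slope | log | Normal(0, 1) | (−7, ln 40) |
| intercept a | identity | Normal(0, 4) | ±40 |

The 2-SD log prior for slopes (rather than 1 SD) reflects that historical
skin-painting dose scales span roughly 0.1–100 dose units, so slopes
legitimately vary over several log-units; powers are weakly identified
and keep the tighter 1-SD constraint with an effective cap of 40.

### Fitting and the Laplace marginal

MAP estimation maximizes log-likelihood + log-prior on the transformed
scale by seeded multi-start L-BFGS-B (default 10 starts drawn around the
prior mean; gradient tolerance 1e−8). If the line search stalls, a
Nelder–Mead polish runs and convergence is judged by the projected
finite-difference gradient. Likelihood probabilities are clipped at
1e−12. The log marginal likelihood is the Laplace approximation
`log p(D, θ̂) + (k/2)·log 2π − ½·log det H` with H the finite-difference
curvature of the negative log posterior at the MAP; fits with
non-positive-definite curvature are excluded from averaging with a
diagnostic, as are non-converged fits and fits whose curve never attains
the benchmark response.

### Model averaging

Weights are posterior model probabilities with equal prior model
probabilities by default. The averaged BMD₁₀ distribution is the
weight-mixture of per-model BMD samples: 4000 total draws (seeded) from
each model's Gaussian (MAP, H⁻¹) approximation on the transformed scale,
pushed through the closed-form inversion; draws that do not attain the
benchmark are discarded and counted. The reported point estimate is the
mixture **median**; the weighted geometric mean of per-model MAP BMDs is
reported alongside, since the evidence base does not state which summary
its single reported BMD per dataset is. The 5th percentile (a BMDL₁₀
analogue) is computed but never used in PEFs — ratios of lower confidence
bounds are distorted when the two studies have different sample sizes.

### High-dose drop rule

Where the observed dose–response plateaus before the top dose, top doses
may be removed to improve fit (responses at high doses can reflect
saturation or different biology). Policy `auto` removes the top dose
while (a) the top-dose response is within one pooled binomial standard
error of the next-lower dose *and* (b) the goodness heuristic improves;
`manual` removes listed doses; the floor is two non-zero doses. The
heuristic is the mixture-weighted mean log marginal, corrected by the
saturated binomial log-likelihood and normalized per dose group — a
plateau group the suite cannot capture contributes a large misfit that
dropping removes, while dropping a well-fit group merely spreads the
complexity penalty over fewer groups and worsens the score.

## PEF aggregation and rounding

Display rounding is half-up to two decimals (two significant figures
below 0.01); a one-significant-figure "headline" value is emitted as a
separate field. Per-chemical aggregation is the arithmetic mean of the
*displayed* per-dataset PEFs — this reproduces the published aggregate
exactly — and the mean of the unrounded ratios is reported alongside,
since the two can differ in the final displayed digit. Chemicals with a
single contributing dataset carry an explicit caveat flag.

## The packaged evidence catalog

The catalog transcribes the printed evidence tables: per-publication
study counts, 48 screened experiments from 23 publications with their
printed dispositions (40 dose–response failures with reason codes, 8
passes, 4 modelable: 3 CPP + 1 BbF), and the four modeled BMD/PEF rows.
Only the printed single/lowest-dose percentages are data; higher-dose
group profiles for the 8 passing records are synthetic reconstructions
consistent with the printed qualitative comments, used solely to drive
the screening engine and never for BMD modeling. Per-dose incidence
tables for the four modeled datasets are not part of the printed
evidence and are **not** packaged or fabricated: full modeling runs
require user-supplied incidence tables, and the pipeline explicitly skips
(never imputes) modelable records that lack them. Resources are
checksummed; transcription ambiguities (row-count reconciliation between
the selection and disposition tables, a both-arm failure printed with a
single percentage) are recorded in per-record transcription notes.

## Synthetic data: what it emulates, what it does not

The generator emulates historical skin-painting designs: single- or
multi-dose arms with or without solvent controls, binomial tumor
incidence from a known quantal curve, and concurrent target/BaP arms with
an exact true BMD ratio. The default comparator truth is a log-logistic
with background 0.02, ln-dose slope 1.2 and BMD₁₀ = 1.0 dose unit, with
the default design (0, 0.5, 1, 2, 4, 8) straddling the benchmark region;
n = 30/group reflects the larger historical studies.

Scenario collections (`passing`, `single_dose_high_response`,
`non_monotonic_noise`, `minimal_response`, `plateau_top_dose`) construct
records whose screening disposition is known *by construction*: where
binomial noise could overturn the intended disposition, the drawn
incidence is minimally adjusted (monotone ordering, control caps,
enforced peaks). These adjustments are part of the scenario definition —
the scenarios test the screen's rules, not binomial sampling.

The generator does not simulate survival/mortality processes, grooming
ingestion of dermally applied material, promoter kinetics, litter or cage
effects, or tumor latency. Passing tests therefore demonstrate the
correctness of the screening logic and the statistical machinery under
clean binomial sampling, not robustness to those real-data complications.

## Numerical and design choices

- All randomness flows from explicit integer seeds; per-record seeds
  derive deterministically from the collection seed and record index.
  Refitting with the same seed is bit-identical.
- Finite-difference Hessians use central differences with per-coordinate
  relative steps of 1e−4.
- BMD root-finding brackets by doubling and solves with Brent's method at
  1e−10 relative tolerance; "benchmark not attained" is an explicit error,
  never a silent extreme value.
- A publication's BaP arm is modeled once and reused for every target PAH
  tested concurrently in that publication.
- Problem sizes in the validation suite: 50-dataset Laplace-vs-quadrature
  comparison, 200-simulation single-family BMD recovery at n = 50/group
  over 5 doses, and 100 paired experiments for end-to-end potency-ratio
  recovery at n = 30/group.

## Known limitations

- The Laplace/Gaussian machinery can misstate uncertainty for fits whose
  MAP sits near a parameter bound (e.g., zero-incidence arms, where the
  answer is prior-driven and flagged as low-information).
- Single-dataset BMD₁₀ recovery error grows for shallow dose–response
  slopes: for a log-logistic with ln-dose slope 1.2 at n = 50/group the
  median relative error is ≈20% from sampling noise alone (near-flat
  priors give the same figure). Potency *ratios* are more stable because
  arm-level biases partially cancel.
- Tumor multiplicity, added-risk benchmarks, continuous endpoints,
  time-to-tumor / poly-k survival adjustment, mixture-risk arithmetic and
  uncertainty-factor policy are out of scope.
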