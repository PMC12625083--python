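# Methods

`cuidose` implements a benefit–risk dose-selection workflow for
antibody–drug conjugates (ADCs) driven entirely by *summary-level* clinical
trial data: arm-level mean concentration–time points, reported exposure
metrics and outcome counts, of the kind a systematic literature review
yields.  The four stages are (1) a meta-analytic population-PK fit,
(2) posterior simulation of exposure metrics per dose level, (3) logistic
exposure–response (ER) modelling of efficacy and toxicity, and (4) a
clinical utility index (CUI) that turns the two ER curves into a single
bounded score and a threshold-based dose recommendation.

## Structural PK model

A two-compartment model with linear elimination and zero-order (IV
infusion) input, parameterised by clearances and volumes: CL, Vc, Vp, Q
(clearances in L/day, volumes in L).  The closed-form bi-exponential
solution and its analytic integral give the cycle-1 exposure metrics:

* Cmax — concentration at end of the 90-min infusion (for this linear
  model identical to the profile maximum);
* Cmin — trough at 504 h (day 21, end of the Q3W cycle);
* AUC(0–504 h) — analytic integral;
* AUC_inf = dose/CL.

Amounts are in mg, so mg/L ≡ µg/mL; concentrations are carried in ng/mL
throughout.  The absolute dose is dose (mg/kg) × the arm's median body
weight; defaults for the "typical subject" weight are 69.4 kg (T-DM1) and
59.0 kg (T-DXd), the observed medians for these drugs.  For the T-DM1
parameter set the fraction of lifetime exposure captured in cycle 1,
AUC(0–504)/AUC_inf, is 0.98 and is dose-independent under linearity.

## Meta-analytic mixed-effects estimation

Each meta-unit — by default every dose arm, i.e. arms are treated as
separate "studies" so that between-treatment-arm variability is absorbed
into between-study variability (BSV) — carries a bivariate log-normal
random effect on CL and Vc with SDs (ω_CL, ω_Vc) and correlation ρ.  Only
these two parameters carry random effects; Vp and Q are fixed, mirroring
what arm-level summary data can identify.

A summary concentration with model prediction f from an arm of n subjects
has residual SD

    σ = a + (b/√n)·f

— the proportional component shrinks with √n because the datum is an
arm *mean*; the constant floor a (ng/mL) is unweighted.  Options provide a
fully √n-weighted constant term and a quadratic combination
√(a² + (bf/√n)²).

**Left truncation.**  Published summary tables never contain non-positive
mean concentrations.  At realistic parameter values the constant error
term is comparable to (or larger than) typical late-cycle concentrations,
so an untruncated Gaussian would put substantial mass below zero.  The
residual model therefore treats each reported value as a draw from a
normal truncated at zero, adding log Φ(f/σ) to the point log-likelihood.
Where signal dominates noise the term vanishes; where it does not, it
removes the selection bias that discarding non-positive values would
otherwise induce.  A `truncated=False` option restores the plain Gaussian.

The marginal likelihood integrates the random effects by a Laplace
approximation.  The per-arm 2-D inner modes are found by a damped
Gauss–Newton iteration run vectorised across all arms (exact gradient,
Gauss–Newton curvature — the first-order-conditional flavour), warm-started
between outer iterations.  The outer maximisation runs L-BFGS-B on the
transformed vector (log CL, log Vc, log Vp, log Q, log ω_CL, log ω_Vc,
atanh ρ, log a, log b) from multiple seeded starts (default 5); starting
values come from non-compartmental heuristics (Vc from dose/Cmax, CL from
a trapezoid-plus-tail AUC).  Convergence requires optimizer success and a
positive-definite finite-difference Hessian; RSEs are 100·SE/estimate with
SEs from the inverse observed information, delta-transformed to the
natural scale.  Non-convergence is reported in flags/messages, never as an
exception.

The `separate_btav` sensitivity mode adds an independent arm-within-study
level (SDs ω_btav on CL and Vc) under a study-level BSV; its inner
problems (dimension 2 + 2·arms) are solved per study in whitened
coordinates.  At one arm per study it reduces exactly to the default
convention (verified numerically).  The `dose_finding_only` flag restricts
the fit to phase-I studies reporting ≥ 2 dose levels.

Diagnostics return observed-vs-predicted tables with standardised
residuals and a visual-predictive-check table (5/50/95% bands from
model-simulated replicates, raw and prediction-corrected).

## Posterior exposure simulation

For an arm with concentration data, the posterior of its random-effect
pair is sampled by random-walk Metropolis in 2-D (4 chains, 1000 warm-up +
1000 kept by default; proposal covariance 2.4²/2 × the Laplace curvature
at the mode), summarised by split-R̂ and ESS via arviz.  Arms without data
fall back to prior draws and are flagged.  Per dose level of the
escalation grid, 1000 replicates (the workflow's reporting convention:
7 dose levels × 1000 = 7000 simulated subjects per drug per metric) of
(η_CL, η_Vc) are pushed through the closed form at the median body weight.
Fixed-effect estimation uncertainty is *not* propagated by default; an
option draws fixed effects from the estimation covariance per replicate.
When several arms share a dose level and conditioning on data is
requested, their posterior draws are pooled weighted by n.

## Exposure–response models

The ER unit is a cancer-type × dose arm on the three-weekly schedule
(weekly arms are kept for PK estimation — cycle-1 exposure does not depend
on the dosing interval — but excluded from ER, where event counts do).
Scenarios restrict phases: `phase1`, `phase1_2`, `all`.  The fit is a
quasi-binomial logistic regression of the event proportion on the exposure
metric (untransformed ng/mL or ng·h/mL; a log-exposure option exists) with
prior weights √n, via a binomial GLM with variance weights; the dispersion
is the weighted Pearson χ²/(N−2), scaling the standard errors.  Complete
separation is flagged, a single distinct exposure raises an
"insufficient range" error, and no multiple-testing adjustment is applied:
these fits are estimation inside a decision pipeline, not hypothesis
screening.  PFS/OS counts are carried by the schema and fittable by the
same machinery but excluded from the CUI by default.

Missing-data rules applied before ER assembly: missing body weight ← the
n-weighted median of observed arm weights (each weight replicated n times;
midpoint on even counts); missing cycle-1 AUC ← AUC_inf × the median
observed AUC/AUC_inf ratio; any remaining missing metric ← the median of
that metric among same-drug arms at the same dose level (no donors ⇒ the
arm drops out of ER for that metric).  Observed values are never altered;
imputed values are clamped so AUC ≤ AUC_inf and Cmin ≤ Cmax always hold.
The composite dose-limiting-toxicity count is the most frequent of the
reported components (DLT proper, dose reduction, discontinuation,
interruption/delay), taken per arm.

## Clinical utility index and dose selection

With p_orr(x) and p_dlt(x) on a shared metric,

    CUI(x) = w·p_orr(x) + (1−w)·(1−p_dlt(x)),  w ∈ [0,1],

an additive utility with probability-scale utilities U₁ = p_orr,
U₂ = 1−p_dlt — both already bounded in [0,1]; optional min–max rescaling
over the exposure range is available.  The per-dose summary is the
*average CUI*: trapezoidal integral of CUI(x) over the span of the dose's
exposure replicates divided by the span (point value on a degenerate
span); an optional 2.5–97.5% trim guards against extreme draws.

Dose selection starts at the lowest dose and escalates while the
*relative* percent improvement 100·(CUI_k − CUI_{k−1})/CUI_{k−1} meets the
threshold τ, stopping at the first failure.  Relative (not
percentage-point) change keeps τ scale-free.  Scans evaluate ORR weights
10–90% in 0.5-point steps (fine enough to resolve reported medians like
77.5%) and thresholds {2.5, 5, …, 20}%, returning per-dose selection
frequencies and the median ORR weight among settings selecting each dose.
Average CUI is linear in w, so scans precompute the two utility averages
once per scenario.

## Synthetic data generator

The generator emulates a literature-derived meta-analytic dataset, and its
defaults are the study conditions for all experiments:

* generating PK/BSV/error values: the fitted literature estimates per drug
  (e.g. T-DM1: CL 0.809 L/day, Vc 3.283 L, ω_CL 0.334, ω_Vc 0.221,
  ρ 0.825, a 2633.766 ng/mL, b 0.430);
* escalation grids: T-DM1 {0.3, 0.6, 1.2, 1.8, 2.4, 3.6, 4.8} mg/kg;
  T-DXd {0.8, 1.6, 2.4, 3.2, 5.4, 6.4, 8.0} mg/kg (only 0.8, 3.2, 5.4 and
  6.4 are publicly named levels; the rest interpolate to seven levels);
* phase mix 45/30/15/10% for I/II/III/IV; phase-I studies are multi-dose
  escalation studies with probability 0.8 (consecutive grid windows),
  later phases sample the top of the grid; ~10% of arms are weekly-schedule;
* arm sizes uniform on 10–60 subjects (phase-I cohorts through small
  phase-II arms); body weight normal (mean = drug median, SD 12 kg,
  clipped to 40–130 kg); sampling times {1.5, 4, 24, 72, 168, 336, 504} h
  spanning end of infusion to the trough;
* observed summary concentrations = arm-level model curve + Gaussian noise
  of SD a + (b/√n)f, with non-positive draws left *unreported* (the
  reporting rule matching the truncated residual model);
* exposure metrics come from the arm's noiseless curve; ORR and DLT counts
  are binomial with logistic probabilities in the arm's true Cmax (default
  curves anchored at ~5%→48% response and ~8%→35% composite DLT across the
  grid — early-phase escalation shapes for this drug class); DLT component
  counts are constructed so their maximum equals the composite;
* per-field missingness (defaults 15–55%) emulates patchy reporting.

What the generator does **not** emulate: individual-level longitudinal
data, cancer-type effect heterogeneity, phase-dependent ER attenuation,
non-proportional (target-mediated) clearance, payload kinetics, or
correlated missingness.  Passing tests therefore demonstrate correctness
of the estimators under the assumed data-generating structure, not
robustness to the full messiness of literature data.

`recovery_config` builds the parameter-recovery layout: one arm per study
(so the number of meta-units is exact), all PK-relevant fields observed.

## Experiment sizes and numerical choices

The recovery experiments refit 10 replicate datasets of 14 arms (T-DM1
configuration), 8 arms (T-DXd) and 50 arms (for the random-effect
correlation), with 3 optimizer starts per fit — sizes chosen to mirror the
motivating analyses (14 and ~8 pop-PK meta-units respectively) while
keeping a full run in minutes on one core.  Tolerances: inner Newton
gradient < 1e-9, outer L-BFGS-B ftol 1e-9/gtol 1e-5, FD Hessians at step
1e-4, random-effect excursions clipped at |η| ≤ 8.  Ties in weighted
medians use the midpoint convention.  Degenerate inputs (single exposure
value, empty scenario, all-missing weights, empty dose grid) raise typed,
named errors at the boundary rather than propagating NaNs.

## Known limitations

* The Laplace/Gauss–Newton marginal likelihood shares the small-sample
  downward bias of ML variance estimation; at 14 meta-units ω estimates
  scatter widely (the 25% tolerance on ω recovery reflects this).
* Vp and Q are weakly identified from 7-point summary profiles (their
  recovery is the poorest, consistent with their large reported RSEs).
* The CUI rests on the ER fits being transportable across phases; the
  scenario machinery exposes, but does not correct, attenuation of the
  response slope when later-phase data are added.
* Exposure replicates condition on the population distribution by default;
  conditioning on same-dose arm data is available but depends on which
  arms reported concentrations.
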