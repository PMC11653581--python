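# Methods notes

This note records the modelling assumptions, defaults, and deliberate
design choices behind `patchpk`, in the order the pipeline runs.

## One-compartment models (`pk_models`)

Both study arms are described by a single well-stirred compartment.  The
IV bolus curve is C(t) = (D/V_d)e^(−kₑt); the transdermal curve is the
Bateman function with first-order input from a patch depot.  Units are
fixed package-wide: hours, ng/mL, 1/hr, litres; an IV dose in µg/kg over a
volume in L/kg gives µg/L ≡ ng/mL with no conversion constant.

**Patch-removal semantics.** The patch is removed at 24 h, but the default
`full_depot` dialect ignores removal: the absorbable amount F·D is treated
as a depot for all time, because F is estimated from the subject's own
AUC and therefore already absorbs the unabsorbed remainder, and because
the observed 30- and 48-h concentrations decline slowly, which is what a
continued slow depot predicts.  A `truncated_input` dialect (absorption
stops at removal; pure elimination from the state at 24 h) is available on
every relevant function and CLI command for sensitivity analysis.  No
absorption lag time is modelled.

**Degeneracy.** When |kₐ − kₑ| < 10⁻⁸·max(kₐ, kₑ) the removable
singularity is replaced by the analytic limit F·D·k·t·e^(−kt)/V_d.

**Parameter-set consistency.** `PKParameters` accepts a redundant triple
(kₑ, Vd_ss, CL_tot) only if CL_tot/Vd_ss matches kₑ within a declared
tolerance (default 20%): terminal-slope kₑ and moment-based CL and Vd_ss
are different estimators and agree only approximately on real data.  Note
this means a group-mean table in which kₑ comes from the terminal slope
while CL comes from dose/AUC can legitimately fail the check; the
simulator always generates internally consistent subjects (CL = kₑ·Vd_ss).

## Moment analysis (`nca`)

Defaults, all configurable: terminal slope λ_z from ordinary least squares
of ln C on t over the last 3 positive samples (rising tails are returned
flagged, never extrapolated); linear-up/log-down trapezoids, falling back
to linear across any segment touching a zero; tail areas C_z/λ_z and
C_z·t_z/λ_z + C_z/λ_z².  IV profiles are back-extrapolated to t = 0 by a
log-linear extension of the first two samples (first sample at 1 min);
transdermal profiles start at C(0) = 0.  Interior zeros are kept for
linear segments; trailing zeros are dropped before the terminal fit.
These conventions are standard NCA practice; the software used in the
original analyses does not document its internal rules, so ours are
declared rather than inferred.

On the sparse 8-point transdermal schedule, the trapezoid + tail estimate
of AUC₀₋∞ carries a grid error of a few percent (tested bound: 10%); on
dense noise-free grids every moment-derived parameter recovers its
generating value within 1%.

## Absorption-rate fitting (`ka_fit`)

kₐ is the only free parameter; F (the subject's own), kₑ and Vd_ss·weight
are fixed inputs.  The objective is weighted least squares on the
concentration scale (default uniform weights; 1/C and 1/C² and a
log-concentration scale are exposed, since the reference software's scheme
is unreported).  The optimizer is a bounded trust-region least-squares
with bounds (10⁻⁵, 10²) 1/hr and tolerances 10⁻¹⁵, started from the kₐ
that solves the Bateman peak-time relation T_max = ln(kₐ/kₑ)/(kₐ − kₑ) on
the flip-flop branch kₐ < kₑ (bisection; fallback kₑ/10 when the observed
peak is too early to admit a solution).  The fit is fully deterministic.
Noise-free recovery is exact to ≈ 10⁻⁶ relative; the sparse schedule keeps
the 1-D objective unimodal within ±50% of the optimum.

## Bioavailability (`bioavailability`)

F uses each animal's transdermal AUC against the **group-mean** IV AUC
(per-animal IV AUC available by option), dose-corrected per kg.  F values
above 1 are physically impossible and are returned with a warning rather
than clamped, so that assay problems surface in reports.  F_a is the exact
release formula; F_skin = F/F_a, so the decomposition F = F_a·F_skin holds
identically per subject.  Because group summaries average per-subject
ratios, a mean F_skin need not equal mean-F over mean-F_a.

## Titration rule (`titration`)

The titration period is the smallest day T ≥ 5 such that over the 5
consecutive days ending at T the dose never changed and every day's rescue
count was ≤ 3 ("within 3 per day" read as inclusive).  The rescue
criterion applies to **every day in the window** by default; applying it
to the qualifying day only is exposed as `rescue_convention="final_day"`.
Patients who never satisfy both criteria are censored and excluded from
the two-group analysis, with the count reported.  The minimum attainable
period is 5 days, matching the observed range.

## Logistic screening and AOR (`titration`, statsmodels backend)

Univariate fits are per-factor complete-case (serum albumin is missing for
some patients by design); factors with Wald p < 0.1 advance.  The
multivariate model is a single joint ML fit; AOR = exp(β) with Wald 95%
CIs (the convention of the original SPSS analysis); no multiple-testing
correction, continuous covariates untransformed.  Separation and
non-convergence are detected (non-finite or exploding standard errors)
and flagged per factor rather than reported as estimates.  Firth-type
shrinkage was deliberately left out to match the reference analysis.

## Synthetic data (`simulate`)

**Rats.** Strain presets hold the group-mean parameters (Wistar:
kₐ 0.0228, kₑ 0.279 /hr, Vd_ss 6.49 L/kg, F 53.0%, F_a 69.0%, 305 g; GK:
kₐ 0.0317, kₑ 0.255, Vd_ss 6.94, F 55.5%, F_a 78.0%, 339 g), the dosing
designs (IV 10 µg/kg sampled 1–300 min; transdermal 160 µg sampled 1–48 h,
removal 24 h) and per-parameter between-animal CVs computed from the
reported S.D./mean ratios.  Subjects draw lognormal mean-1 deviates on kₐ,
clearance (applied to kₑ with Vd_ss fixed, keeping each subject internally
consistent), F, F_a and body weight, independently — the true between-
animal correlation structure is unknown.  Measurement error is
proportional lognormal (default CV 10%).  Patch residuals are
X_used = X_unused·(1 − F_a·(1 + ε)) with 2% assay noise.  F and F_a draws
are truncated at 0.999 (a fraction cannot exceed 1); with the default CVs
this affects roughly 1% of Wistar F draws.

**Patients.** Covariates are drawn from lognormals matched to the
reported median/IQR (age 66 [58–73]; BMI 20.3 [18.3–22.5]; height 162.3
[155.4–168.2] cm; albumin 2.9 [2.4–3.4] g/dL, missing completely at
random at rate 34/387); weight is derived as BMI·height², which lands
within ~1% of the reported weight median; sex is Bernoulli(0.618 male);
the initial dose is discrete over formulation strengths {0.5, 1, 2, 4} mg
with probabilities {0.05, 0.75, 0.15, 0.05} (median 1 [1–1]).  Comorbidity
indicators are independent Bernoulli at prevalences consistent with the
reference cohort's reported univariate odds ratios and group sizes; two
null codes (I10, K21) with zero outcome coefficient give the screen true
negatives to reject.  The outcome model's coefficients are the log
multivariate AORs of the reference analysis for the 12 selected
comorbidities; the intercept is calibrated by exact expectation over all
2¹² flag combinations so that E[P(outcome)] equals the observed 126/387.

**Records.** The short-titration group gets period 5 exactly; the long
group draws 6 + (geometric − 1) days capped at 39, with per-day
continuation probability 0.735 chosen to echo the reported survival
fractions beyond 5/10/15 days (32.6%/7.0%/2.1%) — a qualitative match,
not a fit to the histogram.  Each record is then constructed so the window
rule recovers the drawn period *exactly*: either a dose escalation placed
so the final window is the first constant one (only possible for periods
≤ 9), or rescue overuse every 5th day counting back from day T−5, which
blocks every earlier window.  Both mechanisms also satisfy the stricter
"stable thereafter" reading of the rule, so the round trip does not depend
on that interpretive choice.

**What the generators do not emulate:** correlated comorbidities (a
correlation hook exists but defaults to independence), dose-outcome
feedback (records are built to match the drawn outcome, not a care
process), covariate effects on the titration outcome (the reference
multivariate model retained none), IV/TD carryover within an animal, and
multi-compartment disposition.  Passing recovery tests therefore shows
the *estimators* are unbiased under the assumed data-generating process,
not that the process captures all features of real records.

## Problem sizes and determinism

Recovery experiments use the sizes of the designs they emulate: 5 animals
per strain on the published sampling grids, and 200 replicate cohorts of
n = 387 for the clinical arm (about 7 s on one CPU).  Every stochastic
entry point requires an explicit seed; replicate seeds are spawned from a
single generator so one integer reproduces an entire experiment.
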