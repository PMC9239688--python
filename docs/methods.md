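# Methods

## Model

Tumour subpopulations compete under Lotka–Volterra dynamics

    dx_i/dt = beta_SC * r_i * x_i * (1 - sum_j a_ij x_j / K_i,eff),

with `a_ii = 1` and androgen-blocking therapy acting solely through the
carrying capacity of treatment-sensitive types,
`K_i,eff = K_i (1 - drop_i * Lambda)`.  The working two-population form has
a sensitive type (index 0, `drop = 0.9`: carrying capacity 10,000 -> 1,000
cells on drug) and a resistant type (index 1, `drop = 0`).  Serum PSA is
treated as a direct census of total burden through one global conversion
constant (200 cells per ng/ml, chosen so the generator's median baseline
PSA of 25 ng/ml corresponds to half the carrying capacity).  Absolute cell
numbers are therefore identified only up to this scale; it cancels out of
every dimensionless conclusion (thresholds, cycle counts, TTP).

Assumptions worth keeping in view: all types produce equal PSA per cell;
all types share one carrying capacity off drug; treatment has no direct
kill term — its entire action is the capacity collapse; the model is
deterministic and continuous, so populations can fall below one cell and
regrow.  A one-cell extinction floor is used for *reporting* ("resistant
population approached zero") but does not alter the dynamics.

### Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| `r_s` | sensitive growth rate | /day | 0.0156 |
| `r_r` | resistant growth rate | /day | 0.0091 |
| `beta_sc` | shared growth-rate scaling | – | 8 |
| `alpha_rs` | effect of sensitive on resistant | – | 6 |
| `alpha_sr` | effect of resistant on sensitive | – | 1 (fixed) |
| `K` | carrying capacity, all types | cells | 10,000 |
| `treatment_K_drop` | capacity loss of sensitive types on drug | – | 0.9 |
| `conversion` | cells per ng/ml PSA | cells/(ng/ml) | 200 |

`alpha_rs > alpha_sr` is the cost of resistance; with `alpha_rs = 6` the
resistant type has negative growth whenever `x_R + 6 x_S > K`, which is the
lever the adaptive protocol exploits.

## Numerical integration

Two integrators share one right-hand side.  The reference path is
adaptive-step LSODA (rtol 1e-8, atol 1e-10), restarted at every treatment
switch so the capacity discontinuity falls exactly on a solver boundary.
The fast path, used by the closed-loop protocol engine and the fitting
forward model, is fixed-step classical RK4 with step <= 0.25 day, likewise
restarted at switches; the two agree to sub-cell absolute accuracy on
multi-switch trajectories, and both match the closed-form logistic solution
to < 1e-6 relative error.  Populations are clamped at zero after every
step.  Threshold crossings (protocol switches) are located by bisection on
the integrated PSA to 1e-6 day.  Note that trajectories through many
switches amplify tiny perturbations, so endpoint agreement between solvers
is asserted at the 0.1–0.5 cell level, not machine precision.

## Protocols and progression surrogate

All protocols begin on therapy at day 0 with the day-0 PSA as baseline.
`adaptive_ideal` switches exactly at the stop/restart crossings
(stop at 50% of baseline, restart at 100%, both configurable;
`restart_fraction` may exceed 1 to explore deliberate overshoot).
`adaptive_sampled` evaluates the rules only at monitoring visits (default
every 28 days, matching the trial's 4–6-week labs) and can add separate
withdrawal/restart delays; `confirmation_delay_days` maps onto the
withdrawal side, emulating radiographic confirmation before a drug holiday.
`fixed_interval` alternates blind 8-month blocks; `continuous` never stops.

Radiographic progression has no analogue inside the model, so simulations
declare progression when either (a) PSA rises through 1.2x baseline while
on therapy (the "rising" condition stops a restart overshoot from firing
the rule spuriously), or (b) an on-period runs longer than twice the
longest previously completed on-period without reaching the stop threshold
(PSA failing to respond).  Both multipliers are configuration, not claims
about the trial; after progression therapy is locked on.  A completed cycle
is an off->on restart.

## Canonical initial conditions

The simulations' initial state is a declared default, not a fitted value:
total burden 0.7 K with a 10% resistant fraction — a patient presenting at
heavy burden near carrying capacity with a minority resistant clone.  In
this regime the model reproduces the qualitative sensitivity of cycling to
the competition coefficient: cycling fails quickly at `alpha_rs = 0.8`,
delays but does not prevent progression at `alpha_rs = 2`, and drives the
resistant clone below the extinction floor within four ideal cycles at
`alpha_rs = 6`.  At materially lower burden (<= 0.5 K) off-drug competition
is too weak for elimination and the `alpha_rs = 2` and `6` regimes blur
into each other.

## Synthetic cohorts

The generator emulates the *structure* of a two-arm trial data file, not a
seamless ODE solution:

* per-patient baseline PSA ~ lognormal (median 25 ng/ml, sigma 0.45),
  truncated so the implied burden stays in [0.15 K, 0.75 K] — the lower
  edge keeps the 50%-drop rule meaningful, the upper edge keeps the
  1.2x-baseline progression level below K;
* initial resistant fraction ~ Uniform(0.01, 0.4);
* monitoring visits every 28–42 days (per-visit draw); the adaptive arm
  executes the sampled protocol at those visits (idealised execution is a
  spec option), the comparison arm receives continuous dosing;
* observed PSA = model PSA x lognormal noise (sigma 0.1, a typical assay
  plus biological CV); switching decisions use the noiseless signal;
* the pre-therapy segment (four monthly draws before day 0) rises
  log-linearly at the patient's sensitive rate — the low-burden exponential
  regime the step-1 estimator assumes; per-patient rates carry 10%
  lognormal jitter by default;
* PSA progression is confirmed "radiographically" one imaging interval
  (84 days) later; patients stay on study, and on their assigned therapy,
  until that confirmed date.  Continuous-arm patients then contribute a
  post-progression segment rising log-linearly at the patient's resistant
  rate (therapy has changed, so these points are deliberately off-model and
  are excluded from the step-2 fit);
* one master seed drives per-patient counter-based substreams
  (`SeedSequence((seed, arm, index))`), so cohorts are reproducible under
  insertion or removal of patients, and the manifest records a hash of the
  full specification.

What the generator does *not* emulate: PSA production differences between
clones, measurement-driven switching errors, inter-patient variation in the
shared parameters, death, or any radiographic lesion process.  Passing
recovery tests on these cohorts therefore demonstrates the estimation
machinery is correct under the model's own assumptions — not that the model
is true of real patients.

An eligibility flag mirrors the trial's entry rule (>= 50% PSA decline
within two months).  Cohort-level contrasts (median TTP by arm, the
TTP-versus-resistant-fraction separation) condition on that flag, as the
trial's cohorts did.

## Estimation

Step 1 fits straight lines to log PSA: the earliest contiguous
non-decreasing pre-therapy run (minimum three points; all pre-therapy
points as a flagged fallback) for `r_S`, and post-progression points in the
continuous arm for `r_R`; patient-specific slopes are pooled by arithmetic
mean, and a Kruskal–Wallis comparison of the two rate sets is reported.
Patients with fewer than five usable on-study observations are excluded
from step 2 with a warning.

Step 2 is a nested least-squares fit.  Outer: a 7x7 logarithmic grid over
`beta_SC in [1, 20]`, `alpha_RS in [0.5, 12]`, one local 5x5 refinement
spanning the two coarse cells around the minimum, then a deterministic
Nelder–Mead polish in log-parameter space.  Inner, for every outer
candidate: each patient's `(x_S(0), x_R(0))` — parameterised as (total,
resistant fraction) with bounds total in [0.001 K, 0.999 K], fraction in
[0, 1], which enforces `x_S0 + x_R0 <= K` — fitted by bounded Nelder–Mead
from four fixed starts plus a warm start carried between outer points.  The
cohort objective sums squared PSA residuals over observations
(equal-per-patient weighting is a configuration alternative).  The full
evaluated surface is returned for inspection.  After the minimum is found,
the objective is probed at the parameter bounds: if the spread along an
axis is indistinguishable from zero against the overall objective scale,
that direction is reported as unidentifiable (`flat_directions`) rather
than returning an arbitrary coordinate — a cohort with no resistant cells,
for instance, cannot identify `alpha_RS`.

On a noiseless ten-patient cohort this procedure returns the generating
pair to four significant figures; with 10% PSA noise the pair is recovered
to within a quarter at modest cohort sizes (the test suite checks a
six-patient case).

## Statistics

Kaplan–Meier curves and the Mantel logrank test are delegated to
`lifelines`, Kruskal–Wallis (tie-corrected) to `scipy.stats`; all three are
verified against hand-computed oracles on toy inputs in the test suite, and
the Kruskal–Wallis p-value is calibration-checked on 500 null cohorts.
Simulated survival is censored only at the horizon; a median that is never
reached is reported as "not reached" (None).  Replicate-based properties
are run at desk scale: logrank power on 60 seeded replicates, the
regression-line separation check on 20.

## Known limitations

* The published analysis estimates `r_S` from raw pre-therapy PSA slopes
  yet multiplies all rates by the fitted `beta_SC = 8`, so fitted on-study
  dynamics run roughly eightfold faster than the raw slopes imply.  The
  generator reproduces that structure faithfully, with the consequence that
  monthly-sampled adaptive switching overshoots the thresholds badly and
  many virtual adaptive patients are overtreated — the same failure mode
  the delayed-withdrawal analyses highlight.  Idealised execution restores
  the full benefit.
* Absolute TTP values depend on the declared initial conditions and the
  PSA conversion scale; only orderings and recovery properties are
  meaningful outputs of the synthetic pipeline.
* The inner fit is a local search from fixed starts; pathological
  multi-modality of a patient's inner objective could in principle evade
  it, though the brute-force cross-check in the tests finds none.
* No uncertainty quantification beyond residual diagnostics: the procedure
  returns point estimates, as the source analysis does.
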