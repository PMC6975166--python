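# Methods

This package models when a macaque chooses to act in a dot-counting task
and re-implements the full analysis chain around that question: a
generative task simulator, a censored Cox hazard model of action time
with a survival-integral "deterministic actTime", explained-variation
and bias statistics, hierarchical behavioural GLMs with planned
transcranial-ultrasound (TUS) contrasts, fMRI design/time-course/PPI
machinery, multilevel bootstrap mediation, and a Pennes bioheat solver
for TUS heating.

## The task and its simulator (`acttime.task`)

On each trial dots appear one at a time (one per 100, 200 or 300 ms, up
to 25); responding when `d` dots are visible is rewarded with probability
`1/(1+exp(-0.5 (d-12)))`, so waiting trades time for reward probability.
Offered reward (1–3 drops) and dot period are drawn per trial; the
inter-trial interval (3/5/7 s) is fixed over 30-trial blocks; sessions
last 40 min (or a fixed trial count for controlled experiments).

The simulated agent carries the same covariate structure the fitted
hazard model uses: standardized present context (reward, dot period,
ITI) and the previous 10 trials' reward outcomes and actTimes, 23
covariates in all.  At dot `t` it responds with probability

    p_t = min(1, lambda0(t) * exp(beta . x + eps)),    eps ~ N(0, sigma^2)

where `lambda0` is a per-dot baseline hazard and `eps` is trial-level
unexplained variability (default sigma = 0.25).  Trials with no response
by dot 25 are censored; an additional flat 2% probability of withholding
models trials where the animal disengages outright.

**Calibration of the default world.**  The baseline hazard ramps from
0.018 to a 0.12 plateau by dot 12 and rises steeply from dot 18 (~0.55
at dot 25).  This shape was fixed once, for three reasons: (i) per-dot
response probabilities stay well below 1 in typical contexts, so the
clipped discrete hazard stays in the regime where the Cox
proportional-hazards model is the correct description and clipping is
negligible; (ii) censoring arises mostly from hazard-tail survival past
the final dot — which is exactly how the downstream Cox model treats
censored trials ("would have responded had the trial continued") —
rather than from a separate "cure" process that no hazard model could
recover; (iii) the resulting no-response fraction is ~16% (measured
0.157–0.176 across seeds at n≈10⁴), matching the behavioural sessions
the package emulates.  Default coefficient signs follow the fitted
pattern: reward +0.5, dot period −1.0, ITI −0.3, previous reward +0.5,
previous actTime −0.2, all further lags 0.  The agent standardizes
covariates with fixed moments (the factorial design's theoretical
moments for present context; centre 1/sd 1 for past outcome drops and
centre 14/sd 8.5 for past actTimes, the dispersions its own world
produces), so that the generating scale matches the per-session
z-scoring used at fit time.

What a green test on this generator does *not* establish: real sessions
have satiety drifts, motor noise on the seconds scale, perceptual
uncertainty about the dot count, and animal-specific strategies; none of
these are modelled, and effect sizes measured on real data (e.g. odds
ratios, explained-variance percentages) are not reproduced by
construction.

## Cox actTime model (`acttime.survival`)

actTime (dots at response, 1..25) is a discrete time-to-event outcome;
no-response trials enter as censored at dot 25.  Per session,
`CoxActTimeModel(trials).fit()` z-scores the 23-column design, maximizes
the Cox partial likelihood (lifelines; Efron tie correction — dot times
are massively tied; a `tie_method` tag records the choice) and retains
the Breslow baseline cumulative hazard on the integer dot grid.  Because
the design is z-scored, lifelines' baseline (evaluated at covariate
means) is exactly the `x = 0` baseline; the linear predictor is centred
accordingly so the identity holds for any design.

Derived quantities:

* **Survival curve** `S_x(t) = exp(-Lambda0(t) exp(beta.x))`.
* **Deterministic actTime** `E[T] = sum_{t=0}^{24} S_x(t)` — the
  discrete survival integral, exact for `T in {1..25}` since
  `E[T] = sum P(T > t)`.  The fMRI-facing variant uses only the present
  and 1-back coefficients of the full fit (`which="1back"`); the
  TUS-facing variant uses all 10 lags (`which="all"`).  Present-only and
  past-only variants come from separate fits of the respective blocks.
* **Schemper's V** `(D - Dx)/D`: distances `|S_i(t_j) - S(t_j)|`
  between each trial's empirical survival process and a model curve,
  averaged over all defined (trial, event time) pairs; censored trials
  are defined only up to their censoring time.  `D` uses the
  Kaplan-Meier curve.  For `Dx` the per-trial predictions use the
  product-limit transform of the Breslow increments,
  `prod (1 - dLambda0(t_j) exp(beta.x))`: with heavy ties this is the
  discrete-consistent form that reduces exactly to Kaplan-Meier at
  `beta = 0`, so a null fit gives V ≈ 0 (the naive `exp(-Lambda)` form
  is biased negative under ties).
* **actTime bias** `|observed - deterministic|` on responded trials,
  the TUS outcome measure.

Past actTimes of censored past trials enter as 25 (the animal observably
waited the full window).  The first 10 trials of a session are dropped
(incomplete history).  A trial-number covariate is deliberately absent.

## Behavioural GLMs (`acttime.behavior`)

All Gaussian models are `statsmodels` MixedLM fits with random
intercepts for animal and for session nested within animal (no random
slopes: four animals are too few), ML estimation, and likelihood-ratio
chi-square omnibus tests (dropping a factor removes its interactions
too).  Because the variance-component likelihood can have a flat
spurious optimum under lbfgs, each model is fitted with lbfgs and Powell
and the better log-likelihood kept.  Reward, dot period and ITI enter
as categorical factors (treatment coding by default, switchable);
planned contrasts are Wald tests with normal-approximation p-values.

* `fit_acttime_glm`: actTime ~ reward × dotSpeed × ITI (full factorial)
  + previous outcome + previous actTime, responded trials.
* `fit_response_logit`: responding ~ present context + 1-back history
  over all trials.  statsmodels has no ML random-intercept binomial
  model, so grouped data use the variational `BinomialBayesMixedGLM`
  (posterior sd as SE); degenerate single-group data fall back to an
  ordinary GLM, where the 2×2 contingency oracle applies exactly.
* `tus_reward_interaction` (condition × reward, planned ACC contrasts)
  and `tus_bias_model` (condition main effect on actTime bias computed
  with the 10-back deterministic variant, planned BF contrasts) expect
  the four conditions ACC, BF, POp, sham.

## fMRI design machinery (`acttime.fmri`)

* `monkey_hrf`: double-gamma kernel, main peak 3.0 s (gamma shape 6,
  scale 0.6), undershoot near 6 s at one sixth amplitude, unit area.
  Only the 3 s peak is empirically constrained for macaques; other shape
  parameters are conventional and exposed.
* `build_glm1`: 15 named regressors on the TR grid (TR 2.28 s) built
  from 500 ms boxcar trains at 0.1 s resolution; task regressors and
  outcome/hand confounds convolved with the HRF, distortion regressors
  aligned to TR boundaries and left unconvolved.  The high-resolution
  event trains are retained so convolution can be verified
  independently.
* `epoch_timecourse`: session-wise z-scoring, linear upsampling to
  10 Hz, −2..+6 s windows with time zero at the response; out-of-bounds
  events dropped and counted.
* `timecourse_glm` / `ppi_glm`: cross-trial OLS at each epoch time step;
  the PPI column is the product of the demeaned per-step seed signal and
  the demeaned psychological variable; rank deficiency raises with the
  offending columns named.
* `loo_peak_betas`: for each session, the extremum time of the other
  sessions' mean trajectory selects where that session's beta is read —
  removing temporal selection bias (the naive same-session extremum is
  provided as the biased positive control).
* `connectome_scaling`: per seed voxel, regress the condition-B
  whole-brain correlation profile on the condition-A profile; the slope
  is the seed's coupling "scaling factor".  Correlation is sub-linear in
  the underlying coupling, so a doubled coupling produces slopes between
  1 and 2, clearly separated from unchanged seeds (~1).

## Multilevel mediation (`acttime.mediation`)

Per session, OLS regressions give paths a (X→M), b and c′ (Y ~ X + M),
and c (Y ~ X); c = c′ + a·b holds exactly per session.  Estimates are
combined by inverse-variance weighting within animal, then across
animals.  The mediator is intended as the positive epoch peak of an ROI
signal per trial.  Inference on a·b uses a hierarchical bootstrap
(sessions resampled with replacement within animal, then trials within
each resampled session; animals fixed — four are too few to resample),
implemented with batched normal-equation solves.  The default p-value is
the **bias-corrected** bootstrap p: the null distribution of a product
has a point-mass spike at zero that makes the plain percentile test
drastically conservative (measured 0/100 rejections under a complete
null at α = .05, versus 9/100 for the BC p — near nominal), and BC
inference is what the standard mediation software computes.  The plain
tail p `2 min(P(ab* ≤ 0), P(ab* ≥ 0))` is reported alongside
(`p_ab_tail`).

## TUS biophysics (`acttime.bioheat`)

* Property mapping: within bone, density and sound speed are linear in
  HU between (1000 kg/m³, 1500 m/s) and (2200, 3100); porosity
  `(rho_max − rho)/(rho_max − rho_tissue)`; attenuation
  `alpha_min + alpha_max porosity^0.5` with `alpha_min = 0.2 f^1.1`,
  `alpha_max = 8 f^1.1` dB/cm at f = 0.25 MHz; absorption 0.21 f^1.1 in
  tissue, scaling with density up to 2.7 f^1.1 in bone.  A synthetic
  two-compartment skull phantom (spherical shell + water cone) stands in
  for a CT scan; the exact HU calibration is configurable because the
  literature does not pin it.
* Focal field: an anisotropic Gaussian (default axial FWHM 30 mm,
  lateral 6 mm, peak 1.2 MPa — the transducer's calibrated pressure
  range) replaces a full k-space propagation solve, which is out of
  scope.
* Heat source `q = alpha_abs P² / (rho c)` with alpha converted from
  dB/cm to Np/m.  The denominator uses the **sound speed** (standard
  plane-wave absorption); a specific-heat denominator appears in some
  write-ups but is dimensionally inconsistent with a heat source.
* Pennes solver: explicit forward-Euler, 7-point Laplacian, Dirichlet
  faces plus a 24 °C water-cone clamp; initial temperature 37 °C in
  tissue/skull.  The perfusion term is a **sink** −w·rho_b·C_b·(T−T_a)
  (w = 0.008 s⁻¹, rho_b = 1030, C_b = 3620, the standard Pennes form); a
  `perfusion_sign` flag allows the source-form variant, which visibly
  runs away and exists for literal reproduction only.  Time step
  defaults to 0.9× the stability bound `min(rho C dx²/(6 kappa))`.  The
  timeline is 60 s pre, 40 s sonication, 300 s post; the 30%-duty burst
  pattern (30 ms every 100 ms) is applied as a 0.3 factor on the
  time-averaged q, valid because thermal time constants far exceed the
  burst period.  An insulated (zero-flux) test mode conserves total
  rho·C·T to machine precision for oracle checks.

## Numerical choices and degenerate inputs

Cox fits refuse all-censored sessions, constant columns and suspected
separation (|beta| > 50); sessions shorter than the history depth raise.
Schemper's V raises when there are no events or D = 0.  Mediation
rejects zero-variance X or M, fewer than 2 sessions and n_boot < 100;
singular bootstrap replicates are redrawn (counted).  The epoch/PPI GLMs
raise on rank deficiency and constant psychological regressors.  The
bioheat step raises when dt exceeds the stability bound, reporting the
maximum stable dt.

## Known limitations

Cox coefficient recovery on the discrete clipped hazard carries a small
(<0.06) systematic bias for large coefficients — the discrete clipped
form is not exactly proportional-hazards.  The variational logistic
posterior understates uncertainty relative to full ML.  The multilevel
mediation combination is inverse-variance weighting, not the Mediation
Toolbox's exact scheme; equivalence is at the level of operating
characteristics.  The bioheat solver is homogeneous-perfusion Pennes on
a voxel grid — no acoustic propagation, no CEM43 dose reporting.
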