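# acttime

Hazard modelling of *when* a macaque decides to act.

In the dot-counting task a monkey watches dots appear one by one (up to
25, one per 100–300 ms) and may respond at any moment; the probability
that the response is rewarded grows with the number of dots on screen
along a fixed sigmoid (midpoint dot 12, steepness 0.5, i.e. 50% at
12 dots, ~73% at 14, ~92% at 17).  Waiting therefore buys reward
probability at the cost of time.  The scientific question is which
present factors (offered reward, dot speed, inter-trial interval) and
recent-past factors (reward outcomes and action times up to 10 trials
back) shape the moment of action — and which brain structures carry that
computation.

This package implements the complete computational chain for that
question, exercised on synthetic data from its own task simulator:

* **`acttime.task`** — a generative simulator of the task: a ground-truth
  hazard agent produces trials with the experiment's factorial context,
  history dependence, ~16% censored (no-response) trials and 40-minute
  sessions, for cohorts of animals × sessions.
* **`acttime.survival`** — the core model.  actTime (dots at response)
  is a censored discrete time-to-event; per session a Cox
  proportional-hazards model `lambda(t) = lambda0(t) exp(beta.x)` with
  23 covariates is fitted (`CoxActTimeModel(...).fit()` →
  `CoxActTimeResults`).  Each trial's predicted survival curve
  `S_x(t) = exp(-Lambda0(t) exp(beta.x))` integrates (discretely) to the
  **deterministic actTime** — the expected time to act given context —
  with present-only / past-only decompositions, Schemper's V explained
  variation, and the |observed − deterministic| "actTime bias".
* **`acttime.behavior`** — multilevel behavioural GLMs (session nested
  in animal): the actTime factorial model, the odds-of-responding
  logit, and the TUS condition models with planned contrasts.
* **`acttime.fmri`** — macaque HRF (3 s peak), the 15-regressor session
  design matrix, epoched ROI time-course GLMs, PPI regressors,
  leave-one-out peak selection, and connectome-scaling regression.
* **`acttime.mediation`** — multilevel X→M→Y mediation with
  hierarchical bootstrap inference on the indirect effect a·b.
* **`acttime.bioheat`** — CT/phantom → acoustic property mapping,
  parametric focal pressure field, and an explicit finite-difference
  Pennes bioheat simulation of a 40 s transcranial ultrasound
  sonication (60 s pre / 40 s on / 300 s post, 30% duty cycle).

See `docs/methods.md` for the models, assumptions, defaults and
limitations.

## Worked example

```python
import numpy as np
from acttime import TaskConfig, default_agent, generate_cohort
from acttime.survival import CoxActTimeModel

trials = generate_cohort(n_animals=2, sessions_per_animal=3, rng=7)
print("trials:", len(trials), "| censored fraction:",
      round(1 - trials.responded.mean(), 3))

session = trials[trials.session_id == "A1-S1"]
res = CoxActTimeModel(session).fit()
print(res.summary().head(5).round(3))

det = res.deterministic_act_time(which="1back")   # present + 1-back variant
print("deterministic actTime: mean %.2f dots" % det.mean())
print("Schemper V: %.3f" % res.schemper_v().V)
```

prints

```
trials: 1033 | censored fraction: 0.141
             coef     se      z      p
reward      0.379  0.103  3.671  0.000
dot_period -1.123  0.125 -9.019  0.000
iti        -0.390  0.107 -3.648  0.000
past_rew1   0.630  0.105  6.008  0.000
past_rew2   0.023  0.127  0.180  0.857
deterministic actTime: mean 13.32 dots
Schemper V: 0.420
```

Read: a larger offered reward and a larger previous-trial outcome raise
the hazard of responding (shorter waits); slower dots and longer ITIs
lower it — the generator's planted sign pattern, recovered from one
session.  The deterministic actTime (here averaging ~13 dots) is the
expected response time implied by context alone; Schemper's V says the
fitted context explains ~42% of the variation in this session's response
times (this simulated session is less noisy than a real one).

A thin CLI wraps the common steps:

```bash
acttime simulate --seed 1 --animals 4 --sessions 11 --out trials.tsv
acttime fit-cox trials.tsv --variant full --out fits.json
acttime det-acttime trials.tsv --out det.tsv
acttime pev trials.tsv
acttime bioheat --grid 64 --dx 1.0 --out dT.nii.gz
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the task-schedule quantities from the package (the reward
probabilities of the sigmoid schedule at 14 and 17 dots, as rounded
percentages) and writes them as JSON keyed by target id.
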