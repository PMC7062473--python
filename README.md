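# neurochoice

Analysis tools for two-juice economic choice experiments in head-fixed mice:
behavioral model fitting, quantification of optogenetic-inactivation
effects, lesion-to-deficit mapping, and neuronal decision-variable encoding
analysis — together with synthetic-data generators that invert every fitted
model, so the whole pipeline can be exercised and validated against known
ground truth without any recorded data.

## The science

On each trial a mouse chooses between `qA` drops of juice A (preferred) and
`qB` drops of juice B, presented on the left and right; ~40% of trials are
forced choices offering a single juice. Choice behavior is summarized by a
logistic model

    P(choice B) = 1 / (1 + exp(−X)),    X = a0 + a1·log(qB/qA)

whose fit yields the **relative value** ρ = exp(−a0/a1) (the amount of B
equivalent to 1A at indifference) and the **steepness** η = a1 (inverse
temperature; inversely related to choice variability). One-regressor
extensions quantify the **side bias** ε, **choice hysteresis** ξ and
**direction hysteresis** θ, each as −a2/a1. A stimulation-split model
duplicates every term per optogenetic condition, yielding (ρ, η) separately
for stimulation-OFF and -ON trials.

Inactivation effects are summarized per session by the steepness
stimulation index **SSI** = 2(η_ON − η_OFF)/(η_ON + η_OFF) and the lick
stimulation index **LSI** (same contrast on mean licks/trial in the
1.5–4.5 s window), tested per mouse by a two-sided F test on the spread of
log ρ and a paired t test on η, and aggregated into a per-mouse **choice
deficit** CD = −mean(SSI) that an L1-penalized (LASSO) regression maps onto
per-area viral-infection volumes.

On the neural side, a *neuronal response* (one cell × one time window,
firing rate as a function of trial type) is screened for task-relatedness
by ANOVA (p < 0.001), regressed separately against twelve candidate
decision variables (offer value ipsi/contra/A/B, chosen value and its
conditionals, position of A, chosen juice, chosen side — values in units of
juice B via ρ), and a minimal explanatory variable set is identified by a
stepwise procedure (marginal explanatory power ≥ 5%) and an exhaustive
best-subset search.

## Worked example

```python
from neurochoice import synthetic_data as sd, choice_models as cm, perturbation_effects as pe

params = sd.BehaviorGenParams(rho=2.5, eta=1.5, n_trials=1000, seed=17,
                              stim=sd.StimGenParams(rho_ON=1.8, eta_ON=0.75),
                              lick_rate_ON=3.6)
session = sd.gen_session(params)
fit = cm.fit_stim_model(session, "basic")
print(f"rho_OFF = {fit.rho_OFF:.2f}   eta_OFF = {fit.eta_OFF:.2f}")
print(f"rho_ON  = {fit.rho_ON:.2f}   eta_ON  = {fit.eta_ON:.2f}")
print(f"SSI = {pe.compute_SSI(fit.eta_OFF, fit.eta_ON):.3f}")
print(f"LSI = {pe.compute_LSI(session):.3f}")
```

prints

```
rho_OFF = 2.71   eta_OFF = 1.30
rho_ON  = 1.56   eta_ON  = 0.70
SSI = -0.600
LSI = -0.170
```

The OFF-condition estimates recover the generating values (ρ = 2.5,
η = 1.5) within sampling error; the ON-condition fit shows the halved
steepness the generator imposed (η 1.30 → 0.70, hence the negative SSI:
choices became more variable under stimulation), and the LSI reflects the
mildly reduced lick rate (4.3 → 3.6 Hz).

A command-line interface mirrors the library:

```
neurochoice simulate behavior --seed 3 --out demo/
neurochoice fit-behavior demo/session.csv --model basic
neurochoice run-all --seed 0 --out report.json
```

## Layout

- `neurochoice.session_data` — trial/session/spike-table data model and CSV formats
- `neurochoice.choice_models` — logistic choice models and derived parameters
- `neurochoice.perturbation_effects` — SSI/LSI/CD, distribution tests, LASSO lesion map
- `neurochoice.neural_encoding` — responses, ANOVA screen, variable regressions, selection
- `neurochoice.synthetic_data` — ground-truth generators for all of the above
- `neurochoice.pipeline` / `neurochoice.cli` — reports and the `neurochoice` command

See `docs/methods.md` for the modeling assumptions, parameter conventions,
and known limitations.
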