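# ecothresh

Utility-threshold detection for ecosystem-based management.

A *utility threshold* is the level of a human-induced pressure — a fishing
rate, nearshore habitat degradation, pollution — at which small changes in
the pressure produce disproportionately large changes in a whole-ecosystem
attribute such as resilience, Shannon diversity, mean trophic level or the
NPP/Biomass ratio. Because management effort spent near such a threshold
buys far more ecosystem condition than effort spent elsewhere, utility
thresholds are natural anchors for ecosystem-level decision criteria.
`ecothresh` implements the full quantitative workflow for finding them, for
ecologists and analysts who have (or can simulate) pressure–response data.

## The method

For each attribute *y* observed along a rescaled pressure gradient
*P ∈ [0, 1]* (0 = least stressed, 1 = most stressed), candidate response
forms are fitted by least squares:

| form | equation | utility threshold |
|---|---|---|
| linear | y = b₀ + m₀P | none (no objective definition) |
| piecewise (broken-stick) | y = b₁ + m₁·min(P, Pₜ) + m₂·max(P − Pₜ, 0) | the breakpoint Pₜ |
| sigmoidal | y = c₁ + (c₀ − c₁)/(1 + c₂·e^{c₃P}) | the inflection ln(1/c₂)/c₃ |
| negative exponential | y = a₀ + a₁·e^{a₂P} | none |
| parabolic | y = d₀ + d₁P + d₂P² | none |

Candidates are compared with AICc (the error variance counted as a
parameter); across a Monte Carlo ensemble of datasets — generated by
perturbing uncertain inputs with a uniform distribution at 20% coefficient
of variation — the winning form is the modal per-dataset AICc winner.
A nonparametric bootstrap (case resampling, 10,000 replicates per dataset
by default) yields 95% intervals for every parameter and for the threshold;
a threshold is reported as significant only when its own interval excludes
zero and the companion parameters are not all indistinguishable from zero.
Significant thresholds are then translated into the units of a monitorable
indicator (screened by Spearman rank correlation with the attribute), and a
trade-off table contrasts all attributes and fishery yields at
minimum-impact, threshold and maximum-impact pressure levels.

The package also ships a small deterministic consumer–resource food-web
simulator (10 functional groups, logistic producers, Lotka–Volterra
consumers with quadratic closure, a detritus pool, habitat mediation of
prey vulnerability) that generates realistic biomass-by-group gradients
under fishing and habitat pressure for testing the statistics end to end.

## Worked example

Fit the candidate forms to one noisy response curve and to a 100-dataset
Monte Carlo ensemble generated from a known broken-stick truth
(breakpoint 0.33):

```python
import numpy as np
from ecothresh import (make_model, generate_parametric, rescale_pressure,
                       PressureResponseModel, EnsembleThresholdModel)
from ecothresh.synthetic import FISHING_MULTIPLIERS

P = rescale_pressure(np.asarray(FISHING_MULTIPLIERS))   # 15 levels on [0, 1]
truth = make_model("piecewise", 0.33, 1.37, -5.58, -1.22)
curves = generate_parametric(truth, P, noise_sd=0.05, n_replicates=100, seed=0)

res = PressureResponseModel(curves[0].pressure, curves[0].values,
                            name="Shannon diversity").fit(boot_reps=500, seed=0)
print(res.summary())

eres = EnsembleThresholdModel(curves, attribute="Shannon diversity",
                              pressure="fishing").fit(boot_reps=500, seed=0)
print(eres.summary())
```

Output:

```
Pressure-response model competition: Shannon diversity
  n = 15 observations

  form          k           RSS          AICc  threshold
  linear        3       1.22362      -29.4118
  piecewise     5     0.0125935      -89.5727  0.3543 <- best
  sigmoidal     5     0.0616037      -65.7596  -0.2177

  best form: piecewise
    Pt    = 0.354254   95% CI [0.3236, 0.3787]*
    ...
  utility threshold Pt = 0.3543 [0.324, 0.379] (significant)

Ensemble threshold analysis: Shannon diversity vs fishing
  datasets: 100 (excluded: 0)
  best-fit function: Piecewise (97/100)
    median Pt = 0.3324
    ...
  utility threshold Pt = 0.33 [0.26, 0.41] (significant; 50000 pooled draws)
```

The single-curve fit prefers the broken-stick decisively (AICc −89.6 vs
−29.4 for the line) and brackets the true breakpoint; pooling bootstrap
draws over the ensemble recovers the generating threshold (0.33) with a
95% interval reflecting both noise and input uncertainty.

The command line drives the same machinery; the all-in-one analysis on the
shipped food web is

```bash
ecothresh run --pressure-type fishing --mc-sims 25 --boot-reps 500 \
              --seed 0 --out-dir out/ --spider
```

which writes attribute tables, threshold estimates, indicator screening and
translation, the trade-off scenario table and a spider plot.

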