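# Methods

## Threshold definitions and candidate forms

The toolkit operationalizes "utility threshold" through the derivative
structure of fitted pressure–response curves. The continuous broken-stick
model `y = b1 + m1·min(P, Pt) + m2·max(P − Pt, 0)` is the intersection of
two lines; its breakpoint `Pt` is a fitted parameter and is the threshold.
A discontinuous two-line variant is deliberately not offered — the
threshold concept requires the response itself to be continuous in the
pressure. The four-parameter sigmoid
`y = c1 + (c0 − c1)/(1 + c2·exp(c3·P))` has its threshold at the
inflection `ln(1/c2)/c3`, where the slope is extremal and the second
derivative crosses zero; `c2 > 0`, `c3 > 0` are enforced at construction
so the inflection is finite. Linear, negative-exponential and parabolic
forms never switch curvature abruptly and return no threshold; they exist
to let the model competition *reject* a threshold. At exactly `P = Pt`
evaluation uses the right-hand segment (both segments agree there by
continuity) and a first derivative is only returned with an explicit
`side` flag, since the one-sided slopes genuinely differ.

Two closed-form checks pin this parameterization to the published
coefficient tables the package is validated against: the sigmoid
inflection evaluated at the two printed habitat-pressure fits gives 0.41
and 0.32 to two decimals, and the printed indicator models evaluated at
the printed thresholds give 0.155 and 3.10 t km⁻². These are frozen in the
test suite.

## Attributes

Resilience is rendered as a log-ratio reorganization index,
`R = −Σᵢ |log(B₂ᵢ/B₁ᵢ) − log(ΣB₂/ΣB₁)|`: zero iff every functional group
changed by the same factor as the aggregate, increasingly negative as the
response becomes uneven. The log-ratio form satisfies every stated
property of the index (relative to aggregate change, 0 = proportional
response, smaller = less resilient) and is symmetric in increases versus
decreases; it sits behind a single function so an alternative rendering is
a one-line swap. Pre-pressure biomasses must be positive; the simulator
floors end-state biomasses at a trace density (1e-10 t km⁻²) so that
extirpated groups keep the index finite rather than −∞.

Shannon diversity (natural log), the biomass-weighted mean trophic level
and the NPP/biomass ratio all exclude detritus and discard groups from
their denominators. Total landings and total market value use per-group
prices held constant across pressure levels.

Before fitting, each attribute series is oriented so that large values
mean "unstressed" (sign-flip first, where the raw attribute grows under
stress) and then z-scored; the affine transform is recorded so raw units
are recoverable. The flip-then-standardize order is a package choice — the
alternative order differs only in sign conventions, and plots of oriented
attributes read "up = healthy". Pressures are affinely rescaled to [0, 1]
from least to most stressed; inverted gradients (habitat: the *highest*
macrophyte production multiplier is the *lowest* pressure) are supported
with a flag.

## Fitting and model competition

Forms that are conditionally linear given one nonlinear parameter are
fitted by a deterministic profile: the breakpoint (or the negative-
exponential rate) is swept over a fixed grid (default 201 points; the
breakpoint is constrained to the second-smallest…second-largest observed
pressure so both segments always contain data), conditional linear least
squares is solved at each point, and the winner is refined by bounded
scalar minimization inside its grid cell. This is exactly reproducible,
immune to the non-smoothness of the breakpoint objective, and verified in
the tests against an exhaustive dense-grid search to 1e-6 in RSS. The
sigmoid is fitted by bounded trust-region least squares with an analytic
Jacobian in the parameterization `(c0, c1, log c2, log c3)` from a fixed
12-point multistart (inflection location × steepness grid); the lowest-RSS
start wins, deterministically. Non-convergence is reported, not raised, so
a competition proceeds with the survivors.

AICc is `n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)` with `k` counting the error
variance (linear 3, broken-stick and sigmoid 5, negative exponential and
parabolic 4). Counting the error variance is a stated convention, not an
inference; it shifts every candidate by a constant-ish amount and rarely
the winner. A numerically perfect fit (RSS below 1e-24) is assigned −∞ so
noiseless recovery tests behave. Per dataset the winner is the lowest-AICc
converged candidate, ties broken by fewest parameters then a fixed form
order; across an ensemble the winner is the modal per-dataset winner, and
the vote is reported in "Piecewise (93/100)" style. Attribute analyses
compete {linear, piecewise, sigmoidal}; indicator analyses compete
{linear, piecewise, negexp, parabolic} — the two families the workflow
prescribes for each relationship type.

## Uncertainty

Two sources are propagated and pooled:

* **Input (Monte Carlo).** Named simulator parameters are drawn from
  uniform distributions centred on their base values with coefficient of
  variation 0.20 (default, 100 draws). A uniform with mean μ and cv c has
  half-width √3·c·|μ|; cv < 1/√3 keeps draws sign-preserving. Negative
  parameters use the symmetric half-width on |μ|. By default the perturbed
  set is the benthic-invertebrate and detritivore dynamics — the analogue
  of the least-reliable inputs in the kind of trophic model this surrogate
  stands in for.
* **Observation (bootstrap).** Nonparametric case resampling of
  (pressure, value) pairs, refitting per replicate (default 10,000;
  scaled-down runs use 200–500). Pairs resampling is the assumption-free
  default; residual resampling is available behind a flag. Replicates with
  fewer than k+2 distinct pressure levels are redrawn (counted, capped).
  Bootstrap refits of the profiled forms run on the profile grid without
  scalar refinement — grid resolution (≈0.005 in pressure) is far below
  the sampling spread of the draws — implemented as one batched
  normal-equations solve per dataset with a 1e-10 relative ridge guarding
  singular resample designs. Intervals are 2.5/97.5 percentiles, and a
  parameter is "significant" iff its interval excludes zero.

Threshold draws from all datasets' bootstraps are pooled (default) so the
reported median and 95% interval reflect both sources; a
median-of-per-dataset-medians rule is available where a narrower,
bootstrap-dominated interval is wanted. The pooling rule was a genuinely
open choice; pooled draws were chosen because the ensemble exists
precisely to propagate input uncertainty into the interval. A threshold is
declared significant when its own interval excludes zero and not every
companion parameter of the winning model straddles zero — a fit whose
every other coefficient is indistinguishable from zero describes no
believable response, so its breakpoint is reported but not interpreted.

## Indicator translation and trade-offs

Indicators are screened by Spearman rank correlation (midranks on ties)
against each attribute with a significant threshold, per Monte Carlo
dataset, summarized by median and percentile interval across datasets.
Translation evaluates every bootstrap parameter draw of the winning
indicator–pressure model at the single median threshold pressure,
reporting median and 2.5/97.5 percentiles in indicator units; propagating
threshold draws as well is available behind a flag but off by default for
comparability with the fixed-Pt convention. Translation refuses to
extrapolate outside the fitted pressure range.

The trade-off table evaluates each metric's median response, affinely
rescaled over its observed range to [0, 1] with 0 at the stressed extreme,
at three pressures: 0 (minimum impact), the lowest significant median
threshold, and 1 (maximum impact); custom scenario pressures pass through.
With no significant threshold the threshold scenario is omitted with a
warning. Rescaling is per pressure type, so values are comparable within
one gradient but not across gradients.

## The synthetic food web

The simulator is *not* a mass-balance ecosystem model; it is a 10-group
consumer–resource system built to emit the same kind of output (biomass-
by-group equilibria that decline nonlinearly along pressure gradients)
with known qualitative behaviour. Producers grow logistically; consumers
have linear functional responses, assimilation efficiencies, residual
mortality, quadratic closure and optional fishing; a detritus pool
collects mortality, egestion and closure losses, feeds two detritivores
and exports the remainder.

Rather than hand-tuning rates until an equilibrium emerged, the default
web is *balanced*: target baseline biomasses (phytoplankton 20,
macrophytes 12, zooplankton 8, benthic invertebrates 6, juvenile fish 1.5,
planktivore 3, piscivore 0.8, sablefish 1.2, jellyfish 2, detritus 40
t km⁻²), diets, closure strengths and baseline fishing rates are fixed
first, and each consumer's residual mortality, each producer's carrying
capacity and the detritus export rate are solved so the target state is an
exact equilibrium (numerically verified stable; leading eigenvalue
≈ −0.4 yr⁻¹). Rates are scaled so plankton turn over much faster than fish
and every 50-year pressured run settles to the 1e-6/year equilibration
criterion; runs that miss it are flagged but still emitted.

Fishing pressure multiplies all baseline fishing rates by 0–10 (15 levels,
dense below baseline); habitat pressure multiplies macrophyte production
by 1.3 down to 0 (14 levels) and simultaneously raises the vulnerability
of macrophyte-associated prey through a linear mediation function capped
at +90% (strong: juvenile fish), +50% (moderate: benthic invertebrates)
and +25% (weak: planktivore) as production falls to zero. Every pressured
run starts from the baseline equilibrium; the pre-pressure reference state
for the resilience index is the equilibrium at the least-stressed end of
the gradient, so resilience is exactly zero at zero pressure and declines
monotonically.

What the simulator does and does not emulate: it reproduces declining,
saturating attribute–pressure curves, a decaying indicator, mediation-
amplified habitat effects, and Monte Carlo spread from uncertain
invertebrate dynamics. It has no age structure, no spatial structure, no
vulnerability dynamics beyond the linear mediation scaling, no seasonal
forcing and no hysteresis. Tests passing on it therefore demonstrate that
the *statistics* recover known structure from realistic-shaped data — not
that any particular real ecosystem has thresholds at these locations.

The direct parametric generator (`generate_parametric`: known form plus
i.i.d. Gaussian noise) is the ground-truth harness for the fitting and
uncertainty machinery; all stochasticity in the package lives there and in
the Monte Carlo perturbation, with explicit seeds throughout (the
dynamical simulator is deterministic).

## Problem sizes and numerical choices

Default analysis sizes follow the emulated study design (100 Monte Carlo
datasets, 10,000 bootstrap replicates); the shipped tests and the
acceptance script run scaled-down versions (10–100 datasets, 200–500
replicates) chosen so the whole suite completes in a few minutes while
leaving the estimators' behaviour unchanged — the breakpoint-recovery
checks use the full 100 × 500 design. Other fixed choices: breakpoint
profile grid 201 points (bootstrap the same), negative-exponential rate
limited to |a₂| ≤ 25 over a unit pressure range, sigmoid steepness bounded
in [0.01, 1000] per unit range, equilibration tolerance 1e-6/year,
biomass floor 1e-10 t km⁻², degenerate-breakpoint flag when
|m₁ − m₂| < 1e-6 relative to the larger slope.

## Known limitations

* Threshold locations are only as meaningful as the fitted form; a sigmoid
  fitted to data with no interior inflection can place `ln(1/c2)/c3`
  outside the observed pressure range. Such thresholds are reported as
  computed — downstream consumers should check them against the range
  (translation refuses to extrapolate).
* The sigmoid bootstrap refits replicate-by-replicate (warm-started) and
  dominates runtime when the sigmoid wins; the conditionally linear forms
  are two orders of magnitude faster via the batched profile.
* The stationarity and no-hysteresis assumptions of the threshold concept
  itself are inherited: the workflow fits one curve per attribute-pressure
  pair and cannot detect path dependence.
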