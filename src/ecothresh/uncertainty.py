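"""Monte Carlo input-parameter perturbation and threshold aggregation.

Input uncertainty is propagated by drawing ensemble parameter sets from
uniform distributions centred on the base values with a prescribed
coefficient of variation (default 20%), re-running the response simulation
per draw, and carrying every Monte Carlo dataset through the fit/bootstrap
machinery.  Threshold estimates are then aggregated over the Monte Carlo x
bootstrap hierarchy into a median and 95% interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .fitting import BootstrapResult, ModelFit, threshold_is_significant

__all__ = [
    "MonteCarloConfig",
    "ThresholdEstimate",
    "perturb_parameters",
    "aggregate_thresholds",
]

_CV_LIMIT = 1.0 / math.sqrt(3.0)


@dataclass(frozen=True)
class MonteCarloConfig:
    """Settings for the uniform parameter perturbation.

    A uniform distribution with mean mu and coefficient of variation ``cv``
    has half-width sqrt(3)*cv*|mu| (uniform sd = half-width/sqrt(3)).  The
    positivity constraint cv < 1/sqrt(3) keeps draws for positive
    parameters positive.
    """

    n_sims: int = 100
    cv: float = 0.20
    perturbed_parameters: Tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_sims < 1:
            raise ValueError("n_sims must be positive")
        if not (0.0 <= self.cv < _CV_LIMIT):
            raise ValueError(
                f"cv must lie in [0, 1/sqrt(3)) to keep uniform draws sign-preserving; got {self.cv}"
            )


@dataclass(frozen=True)
class ThresholdEstimate:
    """Median and 95% interval of a utility threshold, pooled over the
    Monte Carlo x bootstrap hierarchy."""

    attribute: str
    pressure: str
    form: Optional[str]
    median_Pt: Optional[float]
    ci95: Optional[Tuple[float, float]]
    significant: bool
    n_datasets: int = 0
    n_draws: int = 0

    def __post_init__(self):
        if self.median_Pt is not None and self.ci95 is not None:
            lo, hi = self.ci95
            if not (lo <= self.median_Pt <= hi):
                raise ValueError("threshold CI must bracket the median")

    def bracket_string(self) -> str:
        if self.median_Pt is None:
            return f"{self.attribute}: no utility threshold ({self.form or 'no'} best fit)"
        lo, hi = self.ci95
        return f"{self.attribute}: {self.median_Pt:.2f} [{lo:.2f}, {hi:.2f}]"


def perturb_parameters(
    base: Mapping[str, float], cfg: MonteCarloConfig
) -> List[Dict[str, float]]:
    """Draw ``cfg.n_sims`` parameter sets, each value uniform on
    [mu - sqrt(3)*cv*|mu|, mu + sqrt(3)*cv*|mu|].

    Only names listed in ``cfg.perturbed_parameters`` are perturbed (all of
    ``base`` if that list is empty).  Negative means keep their sign: the
    half-width is computed from |mu|.  Reproducible given ``cfg.seed``.
    """
    for name, v in base.items():
        if not math.isfinite(v):
            raise ValueError(f"base parameter {name!r} is not finite")
    targets = set(cfg.perturbed_parameters) if cfg.perturbed_parameters else set(base)
    unknown = targets - set(base)
    if unknown:
        raise KeyError(f"perturbed parameters not in base set: {sorted(unknown)}")
    rng = np.random.default_rng(cfg.seed)
    half = math.sqrt(3.0) * cfg.cv
    draws = []
    for _ in range(cfg.n_sims):
        d = {}
        for name, mu in base.items():
            if name in targets and mu != 0.0:
                d[name] = mu + abs(mu) * half * (2.0 * rng.random() - 1.0)
            else:
                d[name] = mu
        draws.append(d)
    return draws


def aggregate_thresholds(
    per_dataset: Sequence[Tuple[ModelFit, Optional[BootstrapResult]]],
    attribute: str = "",
    pressure: str = "",
    rule: str = "pooled",
) -> ThresholdEstimate:
    """Aggregate threshold draws across Monte Carlo datasets.

    ``rule='pooled'`` (default) pools every bootstrap threshold draw from
    every dataset, so the interval reflects both bootstrap and Monte Carlo
    variation; ``rule='median_of_medians'`` summarizes each dataset by its
    median first.  Datasets whose winning form defines no threshold yield a
    no-threshold estimate.  The result is invariant to dataset ordering.
    """
    if rule not in ("pooled", "median_of_medians"):
        raise ValueError(f"unknown aggregation rule {rule!r}")
    if not per_dataset:
        raise ValueError("no datasets to aggregate")
    forms = {fit.form for fit, _ in per_dataset if fit.converged}
    form = forms.pop() if len(forms) == 1 else None
    if form not in ("piecewise", "sigmoidal"):
        return ThresholdEstimate(
            attribute=attribute,
            pressure=pressure,
            form=form,
            median_Pt=None,
            ci95=None,
            significant=False,
            n_datasets=len(per_dataset),
        )
    pooled = []
    n_sig = 0
    n_used = 0
    for fit, boot in per_dataset:
        if not fit.converged or boot is None or boot.threshold_draws is None:
            continue
        draws = boot.threshold_draws
        if draws.size == 0:
            continue
        n_used += 1
        if threshold_is_significant(form, boot):
            n_sig += 1
        if rule == "pooled":
            pooled.append(draws)
        else:
            pooled.append(np.array([np.median(draws)]))
    if not pooled:
        raise ValueError("no bootstrap threshold draws available to aggregate")
    alld = np.sort(np.concatenate(pooled))
    med = float(np.median(alld))
    lo, hi = (float(v) for v in np.percentile(alld, [2.5, 97.5]))
    significant = n_sig > n_used / 2.0
    return ThresholdEstimate(
        attribute=attribute,
        pressure=pressure,
        form=form,
        median_Pt=med,
        ci95=(lo, hi),
        significant=significant,
        n_datasets=n_used,
        n_draws=int(alld.size),
    )
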