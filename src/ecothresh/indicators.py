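"""Indicator screening and threshold translation (step 4 of the analysis).

A whole-ecosystem attribute (resilience, diversity ...) is rarely
measurable in the field, so each significant utility threshold is
translated into the units of an empirically tractable indicator (e.g.
sablefish or jellyfish biomass density).  Candidate indicators are first
screened by Spearman rank correlation with the attribute across the Monte
Carlo ensemble; the indicator-pressure relationship of a retained
indicator is then fitted and evaluated at the median threshold pressure,
with the bootstrap parameter draws supplying a 95% interval in indicator
units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import spearmanr

from .fitting import BootstrapResult, ModelFit, ResponseCurve
from .forms import ResponseModel, make_model

__all__ = [
    "IndicatorScreenResult",
    "IndicatorTranslation",
    "ExtrapolationError",
    "screen_indicator",
    "translate_threshold",
]

logger = logging.getLogger(__name__)


class ExtrapolationError(ValueError):
    """Raised when a threshold pressure falls outside the pressure range
    the indicator model was fitted on."""


@dataclass(frozen=True)
class IndicatorScreenResult:
    """Median Spearman correlation of indicator vs attribute across the
    Monte Carlo datasets, with a 95% percentile interval."""

    indicator: str
    attribute: str
    rs_median: float
    rs_ci95: Tuple[float, float]
    significant: bool
    n_datasets: int

    def __post_init__(self):
        lo, hi = self.rs_ci95
        if not (lo <= self.rs_median <= hi):
            raise ValueError("correlation CI must bracket the median")


@dataclass(frozen=True)
class IndicatorTranslation:
    """A utility threshold expressed in indicator units (e.g. t km^-2)."""

    indicator: str
    threshold_source: str
    indicator_value_median: float
    ci95: Tuple[float, float]
    model: ResponseModel
    Pt: float

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= hi):
            raise ValueError("translation CI bounds out of order")

    def bracket_string(self) -> str:
        lo, hi = self.ci95
        return (
            f"{self.indicator} at Pt={self.Pt:.2f} ({self.threshold_source}): "
            f"{self.indicator_value_median:.3f} [{lo:.3f}, {hi:.3f}]"
        )


def screen_indicator(
    indicator_curves: Sequence[ResponseCurve],
    attribute_curves: Sequence[ResponseCurve],
    indicator: str = "",
    attribute: str = "",
) -> IndicatorScreenResult:
    """Spearman rank correlation between an indicator and an attribute,
    computed per Monte Carlo dataset across matched pressure levels and
    summarized by the median and 2.5/97.5 percentiles across datasets.

    Ties are handled by midranks (scipy's default); datasets where either
    series is constant (correlation undefined) are dropped with a log
    message.
    """
    if len(indicator_curves) != len(attribute_curves):
        raise ValueError("indicator and attribute ensembles differ in size")
    if not indicator_curves:
        raise ValueError("empty ensemble")
    rs = []
    dropped = 0
    for ic, ac in zip(indicator_curves, attribute_curves):
        if ic.n != ac.n or not np.allclose(ic.pressure, ac.pressure):
            raise ValueError("indicator and attribute curves must share pressure levels")
        r = spearmanr(ic.values, ac.values).statistic
        if np.isnan(r):
            dropped += 1
            continue
        rs.append(float(r))
    if dropped:
        logger.warning("screen_indicator: dropped %d datasets with undefined correlation", dropped)
    if not rs:
        raise ValueError("correlation undefined on every dataset")
    rs = np.asarray(rs)
    med = float(np.median(rs))
    lo, hi = (float(v) for v in np.percentile(rs, [2.5, 97.5]))
    return IndicatorScreenResult(
        indicator=indicator,
        attribute=attribute,
        rs_median=med,
        rs_ci95=(lo, hi),
        significant=not (lo <= 0.0 <= hi),
        n_datasets=len(rs),
    )


def _models_from_draws(form: str, boot: BootstrapResult) -> list:
    names = sorted(boot.param_draws)
    n = len(boot.param_draws[names[0]])
    order = {
        "linear": ("b0", "m0"),
        "piecewise": ("Pt", "b1", "m1", "m2"),
        "sigmoidal": ("c0", "c1", "c2", "c3"),
        "negexp": ("a0", "a1", "a2"),
        "parabolic": ("d0", "d1", "d2"),
    }[form]
    models = []
    for i in range(n):
        try:
            models.append(make_model(form, *(float(boot.param_draws[nm][i]) for nm in order)))
        except ValueError:
            continue  # e.g. a sigmoid draw with c2 <= 0
    return models


def translate_threshold(
    indicator_fit: ModelFit,
    boot: BootstrapResult,
    Pt: float,
    indicator: str = "",
    threshold_source: str = "",
    pressure_range: Optional[Tuple[float, float]] = None,
    Pt_draws: Optional[np.ndarray] = None,
) -> IndicatorTranslation:
    """Evaluate the indicator-pressure model at a utility threshold.

    By default each bootstrap parameter draw is evaluated at the single
    median threshold ``Pt``, yielding a distribution of indicator values
    whose median and 2.5/97.5 percentiles are reported in indicator units.
    Passing ``Pt_draws`` additionally propagates threshold uncertainty by
    pairing parameter draws with threshold draws.
    """
    if not indicator_fit.converged or indicator_fit.model is None:
        raise ValueError("indicator-pressure fit did not converge")
    if pressure_range is not None:
        lo, hi = pressure_range
        if not (lo <= Pt <= hi):
            raise ExtrapolationError(
                f"threshold Pt={Pt:.3f} lies outside the fitted pressure range [{lo:.3f}, {hi:.3f}]"
            )
    models = _models_from_draws(indicator_fit.model.form, boot)
    if not models:
        raise ValueError("no valid bootstrap parameter draws to translate")
    if Pt_draws is not None:
        rng = np.random.default_rng(0)
        pts = rng.choice(np.asarray(Pt_draws, dtype=float), size=len(models))
        vals = np.array([m.evaluate(p) for m, p in zip(models, pts)])
    else:
        vals = np.array([m.evaluate(Pt) for m in models])
    med = float(np.median(vals))
    lo_v, hi_v = (float(v) for v in np.percentile(vals, [2.5, 97.5]))
    return IndicatorTranslation(
        indicator=indicator,
        threshold_source=threshold_source,
        indicator_value_median=med,
        ci95=(lo_v, hi_v),
        model=indicator_fit.model,
        Pt=float(Pt),
    )
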