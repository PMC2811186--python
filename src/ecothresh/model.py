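"""Model / results classes tying fitting, selection and uncertainty together.

:class:`PressureResponseModel` is built from one (pressure, value) curve;
its :meth:`~PressureResponseModel.fit` runs the AICc competition among the
candidate forms and (optionally) bootstraps the winner, returning a
:class:`PressureResponseResults` with estimates, intervals and a
``summary()`` table.

:class:`EnsembleThresholdModel` is the Monte Carlo analogue: built from an
ensemble of curves (one per Monte Carlo dataset), its ``fit`` votes on the
winning form across datasets, bootstraps the winner on every dataset, and
aggregates the utility threshold into a median and 95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fitting import (
    DEFAULT_OPTIONS,
    BootstrapResult,
    FitOptions,
    ModelFit,
    ModelSelection,
    ResponseCurve,
    bootstrap_fit,
    fit_all,
    select_model,
    threshold_is_significant,
)
from .forms import FORM_ORDER
from .uncertainty import ThresholdEstimate, aggregate_thresholds

__all__ = [
    "PressureResponseModel",
    "PressureResponseResults",
    "EnsembleThresholdModel",
    "EnsembleThresholdResults",
    "ATTRIBUTE_FORMS",
    "INDICATOR_FORMS",
]

#: Candidate families used for attribute-pressure and indicator-pressure
#: relationships respectively.
ATTRIBUTE_FORMS = ("linear", "piecewise", "sigmoidal")
INDICATOR_FORMS = ("linear", "piecewise", "negexp", "parabolic")


class PressureResponseModel:
    """One response curve confronted with a family of candidate forms."""

    def __init__(
        self,
        pressure,
        values,
        forms: Sequence[str] = ATTRIBUTE_FORMS,
        name: str = "",
        options: FitOptions = DEFAULT_OPTIONS,
    ):
        self.curve = ResponseCurve(pressure=pressure, values=values, name=name)
        unknown = set(forms) - set(FORM_ORDER)
        if unknown:
            raise ValueError(f"unknown candidate forms: {sorted(unknown)}")
        self.forms = tuple(forms)
        self.options = options

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        pressure: str = "pressure",
        value: str = "value",
        **kwargs,
    ) -> "PressureResponseModel":
        for col in (pressure, value):
            if col not in df.columns:
                raise ValueError(f"dataframe is missing column {col!r}")
        return cls(df[pressure].to_numpy(), df[value].to_numpy(), **kwargs)

    def fit(self, boot_reps: int = 0, seed: int = 0, boot_method: str = "case") -> "PressureResponseResults":
        fits = fit_all(self.curve, self.forms, self.options)
        ranked = sorted(
            ((f, m) for f, m in fits.items() if m.converged),
            key=lambda kv: (kv[1].aicc, kv[1].k, FORM_ORDER.index(kv[0])),
        )
        if not ranked:
            raise RuntimeError("no candidate form converged")
        best_form = ranked[0][0]
        boot = None
        if boot_reps:
            boot = bootstrap_fit(
                self.curve, best_form, boot_reps, seed=seed, options=self.options, method=boot_method
            )
        return PressureResponseResults(model=self, fits=fits, best_form=best_form, bootstrap=boot)


@dataclass
class PressureResponseResults:
    """Fitted candidates, the AICc winner and its bootstrap uncertainty."""

    model: PressureResponseModel
    fits: Dict[str, ModelFit]
    best_form: str
    bootstrap: Optional[BootstrapResult] = None

    @property
    def best(self) -> ModelFit:
        return self.fits[self.best_form]

    @property
    def threshold(self) -> Optional[float]:
        """Utility threshold of the winning form (None if undefined)."""
        return self.best.model.threshold()

    @property
    def threshold_ci(self) -> Optional[Tuple[float, float]]:
        if self.bootstrap is None or self.bootstrap.threshold_draws is None:
            return None
        lo, hi = np.percentile(self.bootstrap.threshold_draws, [2.5, 97.5])
        return float(lo), float(hi)

    @property
    def threshold_significant(self) -> bool:
        if self.bootstrap is None:
            return False
        return threshold_is_significant(self.best_form, self.bootstrap)

    def predict(self, pressure):
        return self.best.model.evaluate(pressure)

    def summary(self) -> str:
        name = self.model.curve.name or "response"
        lines = [
            f"Pressure-response model competition: {name}",
            f"  n = {self.model.curve.n} observations",
            "",
            f"  {'form':<12}{'k':>3}{'RSS':>14}{'AICc':>14}  threshold",
        ]
        for form in self.model.forms:
            f = self.fits[form]
            if not f.converged:
                lines.append(f"  {form:<12}{f.k:>3}{'--':>14}{'(failed)':>14}")
                continue
            thr = f.model.threshold()
            mark = " <- best" if form == self.best_form else ""
            lines.append(
                f"  {form:<12}{f.k:>3}{f.rss:>14.6g}{f.aicc:>14.6g}  "
                f"{'' if thr is None else format(thr, '.4f')}{mark}"
            )
        best = self.best
        lines.append("")
        lines.append(f"  best form: {self.best_form}")
        for nm, v in zip(best.model.param_names(), best.model.param_values()):
            ci = ""
            if self.bootstrap is not None and nm in self.bootstrap.ci95:
                lo, hi = self.bootstrap.ci95[nm]
                star = "*" if self.bootstrap.significant[nm] else ""
                ci = f"   95% CI [{lo:.4g}, {hi:.4g}]{star}"
            lines.append(f"    {nm:<6}= {v:.6g}{ci}")
        if self.threshold is not None:
            ci = self.threshold_ci
            tail = "" if ci is None else f" [{ci[0]:.3f}, {ci[1]:.3f}]"
            sig = " (significant)" if self.threshold_significant else ""
            lines.append(f"  utility threshold Pt = {self.threshold:.4f}{tail}{sig}")
        else:
            lines.append("  no utility threshold (form admits none)")
        return "\n".join(lines)


class EnsembleThresholdModel:
    """Monte Carlo ensemble of response curves for one attribute-pressure
    pair, fitted and voted on as in the four-step threshold analysis."""

    def __init__(
        self,
        curves: Sequence[ResponseCurve],
        forms: Sequence[str] = ATTRIBUTE_FORMS,
        attribute: str = "",
        pressure: str = "",
        options: FitOptions = DEFAULT_OPTIONS,
    ):
        if not curves:
            raise ValueError("ensemble needs at least one curve")
        self.curves = list(curves)
        self.forms = tuple(forms)
        self.attribute = attribute
        self.pressure = pressure
        self.options = options

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        dataset: str = "dataset",
        pressure: str = "pressure",
        value: str = "value",
        **kwargs,
    ) -> "EnsembleThresholdModel":
        for col in (dataset, pressure, value):
            if col not in df.columns:
                raise ValueError(f"dataframe is missing column {col!r}")
        curves = [
            ResponseCurve(sub[pressure].to_numpy(), sub[value].to_numpy(), name=str(ds))
            for ds, sub in df.groupby(dataset, sort=True)
        ]
        return cls(curves, **kwargs)

    def fit(
        self,
        boot_reps: int = 500,
        seed: int = 0,
        aggregation: str = "pooled",
        boot_method: str = "case",
    ) -> "EnsembleThresholdResults":
        """Fit all candidates on every dataset, vote with AICc, bootstrap
        the winning form per dataset, and pool the threshold draws."""
        fits_by_ds = [fit_all(c, self.forms, self.options) for c in self.curves]
        selection = select_model(fits_by_ds)
        winner = selection.winner
        seeds = np.random.SeedSequence(seed).generate_state(len(self.curves))
        per_dataset: List[Tuple[ModelFit, Optional[BootstrapResult]]] = []
        for i, curve in enumerate(self.curves):
            fit = fits_by_ds[i][winner]
            boot = None
            if boot_reps and fit.converged:
                boot = bootstrap_fit(
                    curve,
                    winner,
                    boot_reps,
                    seed=int(seeds[i] % (2**31)),
                    options=self.options,
                    method=boot_method,
                )
            per_dataset.append((fit, boot))
        estimate = aggregate_thresholds(
            per_dataset, attribute=self.attribute, pressure=self.pressure, rule=aggregation
        )
        return EnsembleThresholdResults(
            model=self,
            fits_by_dataset=fits_by_ds,
            selection=selection,
            per_dataset=per_dataset,
            estimate=estimate,
        )


@dataclass
class EnsembleThresholdResults:
    """Vote tally, per-dataset fits/bootstraps and the pooled threshold."""

    model: EnsembleThresholdModel
    fits_by_dataset: List[Dict[str, ModelFit]]
    selection: ModelSelection
    per_dataset: List[Tuple[ModelFit, Optional[BootstrapResult]]]
    estimate: ThresholdEstimate

    @property
    def winning_form(self) -> str:
        return self.selection.winner

    def median_parameters(self) -> Dict[str, float]:
        """Median of each winning-form parameter over datasets and
        bootstrap draws (Table-style point estimates)."""
        pooled: Dict[str, List[np.ndarray]] = {}
        for fit, boot in self.per_dataset:
            if boot is None:
                continue
            for nm, arr in boot.param_draws.items():
                pooled.setdefault(nm, []).append(arr)
        return {nm: float(np.median(np.concatenate(v))) for nm, v in pooled.items()}

    def summary(self) -> str:
        s = self.selection
        lines = [
            f"Ensemble threshold analysis: {self.model.attribute or 'attribute'}"
            f" vs {self.model.pressure or 'pressure'}",
            f"  datasets: {s.n_datasets} (excluded: {len(s.excluded)})",
            f"  best-fit function: {s.tally_string()}",
        ]
        for nm, v in sorted(self.median_parameters().items()):
            lines.append(f"    median {nm} = {v:.4g}")
        e = self.estimate
        if e.median_Pt is None:
            lines.append("  no utility threshold (winning form admits none)")
        else:
            sig = "significant" if e.significant else "not significant"
            lines.append(
                f"  utility threshold Pt = {e.median_Pt:.2f} "
                f"[{e.ci95[0]:.2f}, {e.ci95[1]:.2f}] ({sig}; "
                f"{e.n_draws} pooled draws)"
            )
        return "\n".join(lines)
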