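"""End-to-end four-step threshold analysis over the synthetic food web.

Step 1 fixes the attributes and the pressure (config).  Step 2 simulates
the pressure gradient under Monte Carlo input uncertainty and fits the
candidate response forms to every Monte Carlo dataset.  Step 3 selects the
winning form by AICc vote, bootstraps it, and aggregates utility
thresholds.  Step 4 screens the indicator group against attributes with
significant thresholds and translates the lowest threshold into indicator
units.  A trade-off scenario table closes the analysis.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .attributes import ATTRIBUTE_ORIENTATION, compute_attributes, standardize_series
from .fitting import FitOptions, ResponseCurve
from .indicators import IndicatorScreenResult, IndicatorTranslation, screen_indicator, _models_from_draws
from .model import ATTRIBUTE_FORMS, INDICATOR_FORMS, EnsembleThresholdModel
from .synthetic import (
    DEFAULT_PERTURBED_PARAMETERS,
    FISHING_MULTIPLIERS,
    HABITAT_MULTIPLIERS,
    FoodWebSpec,
    GradientDesign,
    default_foodweb,
    simulate_gradient,
)
from .tradeoffs import scenario_table
from .uncertainty import MonteCarloConfig, ThresholdEstimate, perturb_parameters

__all__ = ["AnalysisConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)

CORE_ATTRIBUTES = ("resilience", "npp_over_biomass", "shannon", "mean_trophic_level")
YIELD_METRICS = ("total_landings", "total_market_value")


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one full threshold analysis.

    Defaults mirror the emulated study design: 100 Monte Carlo simulations
    at 20% coefficient of variation, 10,000 bootstrap replicates.  Reduce
    ``mc_sims`` and ``boot_reps`` for desk-scale runs.
    """

    pressure_type: str = "fishing"
    mc_sims: int = 100
    cv: float = 0.20
    boot_reps: int = 10_000
    seed: int = 0
    indicator: Optional[str] = None  # default: sablefish (fishing) / jellyfish (habitat)
    perturbed_parameters: Tuple[str, ...] = DEFAULT_PERTURBED_PARAMETERS
    aggregation: str = "pooled"
    spec_path: Optional[str] = None
    out_dir: Optional[str] = None
    fit_options: FitOptions = field(default_factory=FitOptions)

    def __post_init__(self):
        if self.pressure_type not in ("fishing", "habitat"):
            raise ValueError("pressure_type must be 'fishing' or 'habitat'")
        if self.mc_sims < 1 or self.boot_reps < 100:
            raise ValueError("mc_sims must be >= 1 and boot_reps >= 100")

    @property
    def indicator_group(self) -> str:
        if self.indicator:
            return self.indicator
        return "sablefish" if self.pressure_type == "fishing" else "jellyfish"


@dataclass
class PipelineResult:
    """Bundle of every stage's output plus per-stage status."""

    config: AnalysisConfig
    pressures: np.ndarray
    attribute_table: pd.DataFrame
    selections: Dict[str, str]
    vote_tallies: Dict[str, str]
    thresholds: Dict[str, ThresholdEstimate]
    screens: List[IndicatorScreenResult]
    translation: Optional[IndicatorTranslation]
    scenarios: pd.DataFrame
    status: Dict[str, str]
    log: Dict[str, object]

    def summary(self) -> str:
        lines = [
            f"Utility threshold analysis ({self.config.pressure_type} pressure)",
            f"  Monte Carlo datasets: {self.log['n_datasets_ok']}"
            f" (failed: {self.log['n_datasets_failed']}), bootstrap reps: {self.config.boot_reps}",
            "",
            "  Best-fit functions and utility thresholds:",
        ]
        for attr in self.selections:
            est = self.thresholds[attr]
            lines.append(f"    {attr:20s} {self.vote_tallies[attr]:20s} {est.bracket_string()}")
        if self.screens:
            lines.append("")
            lines.append(f"  Indicator screening ({self.config.indicator_group}):")
            for s in self.screens:
                star = "*" if s.significant else ""
                lines.append(
                    f"    vs {s.attribute:20s} rs = {s.rs_median:.2f} "
                    f"[{s.rs_ci95[0]:.2f}, {s.rs_ci95[1]:.2f}]{star}"
                )
        if self.translation is not None:
            lines.append("")
            lines.append(f"  Threshold in indicator units: {self.translation.bracket_string()}")
        return "\n".join(lines)


def _gradient_metrics(spec: FoodWebSpec, design: GradientDesign) -> pd.DataFrame:
    """One Monte Carlo dataset: every attribute, yield metric and group
    biomass at every gradient level."""
    res = simulate_gradient(spec, design)
    ref = res.reference
    P = res.pressures()
    rows = []
    for p, snap, ok in zip(P, res.snapshots, res.equilibrated):
        av = compute_attributes(ref, snap, spec.groups)
        for attr, val in av.as_dict().items():
            rows.append({"pressure": p, "metric": attr, "value": val, "equilibrated": ok})
        for g, b in snap.biomass.items():
            rows.append({"pressure": p, "metric": f"biomass:{g}", "value": b, "equilibrated": ok})
    return pd.DataFrame(rows)


def run_pipeline(config: AnalysisConfig) -> PipelineResult:
    """Run the four-step analysis; returns the result bundle and, when
    ``config.out_dir`` is set, writes CSV/JSON artifacts plus a run log."""
    from . import io as eio  # local import to avoid cycle at module load

    t_start = time.time()
    status: Dict[str, str] = {}
    rng_root = np.random.SeedSequence(config.seed)
    seeds = rng_root.generate_state(4)

    # -- step 2a: Monte Carlo ensemble of simulated gradients ----------
    spec = eio.load_foodweb_spec(config.spec_path) if config.spec_path else default_foodweb()
    design = GradientDesign(
        config.pressure_type,
        FISHING_MULTIPLIERS if config.pressure_type == "fishing" else HABITAT_MULTIPLIERS,
    )
    mc = MonteCarloConfig(
        n_sims=config.mc_sims,
        cv=config.cv,
        perturbed_parameters=config.perturbed_parameters,
        seed=int(seeds[0] % (2**31)),
    )
    draws = perturb_parameters(spec.parameters(), mc)
    datasets: List[pd.DataFrame] = []
    n_failed = 0
    for i, draw in enumerate(draws):
        sub = {k: draw[k] for k in config.perturbed_parameters} if config.perturbed_parameters else draw
        try:
            df = _gradient_metrics(spec.with_parameters(sub), design)
        except (ValueError, RuntimeError) as exc:
            n_failed += 1
            logger.warning("Monte Carlo dataset %d failed: %s", i, exc)
            continue
        df["dataset"] = i
        datasets.append(df)
    if not datasets:
        raise RuntimeError("every Monte Carlo dataset failed to simulate")
    status["simulate"] = "ok"
    table = pd.concat(datasets, ignore_index=True)
    P = np.sort(table["pressure"].unique())

    # -- step 2b: standardized attribute curves per dataset ------------
    attr_rows = []
    ensembles: Dict[str, List[ResponseCurve]] = {a: [] for a in CORE_ATTRIBUTES}
    raw_ensembles: Dict[str, List[ResponseCurve]] = {a: [] for a in CORE_ATTRIBUTES}
    for ds, sub in table.groupby("dataset"):
        for attr in CORE_ATTRIBUTES:
            s = sub[sub["metric"] == attr].sort_values("pressure")
            raw = s["value"].to_numpy()
            z, _ = standardize_series(raw, unstressed_is_high=ATTRIBUTE_ORIENTATION[attr])
            pr = s["pressure"].to_numpy()
            ensembles[attr].append(ResponseCurve(pr, z, name=f"{attr}[{ds}]"))
            raw_ensembles[attr].append(ResponseCurve(pr, raw, name=f"{attr}[{ds}]"))
            for p, vr, vz in zip(pr, raw, z):
                attr_rows.append(
                    {
                        "pressure": p,
                        "replicate": ds,
                        "attribute": attr,
                        "value_raw": vr,
                        "value_standardized": vz,
                    }
                )
    attribute_table = pd.DataFrame(attr_rows)
    status["attributes"] = "ok"

    # -- step 3: competition, bootstrap, threshold aggregation ---------
    selections: Dict[str, str] = {}
    tallies: Dict[str, str] = {}
    thresholds: Dict[str, ThresholdEstimate] = {}
    ens_results = {}
    for j, attr in enumerate(CORE_ATTRIBUTES):
        em = EnsembleThresholdModel(
            ensembles[attr],
            forms=ATTRIBUTE_FORMS,
            attribute=attr,
            pressure=config.pressure_type,
            options=config.fit_options,
        )
        r = em.fit(
            boot_reps=config.boot_reps,
            seed=int((seeds[1] + j) % (2**31)),
            aggregation=config.aggregation,
        )
        ens_results[attr] = r
        selections[attr] = r.winning_form
        tallies[attr] = r.selection.tally_string()
        thresholds[attr] = r.estimate
    status["thresholds"] = "ok"

    # -- step 4: indicator screening and translation -------------------
    ind_group = config.indicator_group
    ind_curves: List[ResponseCurve] = []
    for ds, sub in table.groupby("dataset"):
        s = sub[sub["metric"] == f"biomass:{ind_group}"].sort_values("pressure")
        ind_curves.append(ResponseCurve(s["pressure"].to_numpy(), s["value"].to_numpy()))
    screens: List[IndicatorScreenResult] = []
    for attr in CORE_ATTRIBUTES:
        if thresholds[attr].significant:
            screens.append(
                screen_indicator(ind_curves, raw_ensembles[attr], indicator=ind_group, attribute=attr)
            )
    translation = None
    sig = {a: t for a, t in thresholds.items() if t.significant and t.median_Pt is not None}
    if sig and any(s.significant for s in screens):
        lowest_attr = min(sig, key=lambda a: sig[a].median_Pt)
        Pt = sig[lowest_attr].median_Pt
        ind_model = EnsembleThresholdModel(
            ind_curves,
            forms=INDICATOR_FORMS,
            attribute=ind_group,
            pressure=config.pressure_type,
            options=config.fit_options,
        )
        ind_res = ind_model.fit(boot_reps=config.boot_reps, seed=int(seeds[2] % (2**31)))
        vals = []
        for fit, boot in ind_res.per_dataset:
            if boot is None:
                continue
            for mdl in _models_from_draws(ind_res.winning_form, boot):
                vals.append(float(mdl.evaluate(Pt)))
        vals = np.asarray(vals)
        translation = IndicatorTranslation(
            indicator=ind_group,
            threshold_source=lowest_attr,
            indicator_value_median=float(np.median(vals)),
            ci95=(float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))),
            model=ind_res.per_dataset[0][0].model,
            Pt=float(Pt),
        )
        status["indicators"] = "ok"
    else:
        status["indicators"] = "skipped: no significant threshold or indicator"

    # -- trade-off scenarios -------------------------------------------
    med = (
        table[~table["metric"].str.startswith("biomass:")]
        .groupby(["metric", "pressure"])["value"]
        .median()
        .reset_index()
    )
    metric_curves = {}
    for metric in CORE_ATTRIBUTES + YIELD_METRICS:
        s = med[med["metric"] == metric].sort_values("pressure")
        vals = s["value"].to_numpy()
        if ATTRIBUTE_ORIENTATION.get(metric, True) is False:
            vals = -vals
        metric_curves[metric] = (s["pressure"].to_numpy(), vals)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        scenarios = scenario_table(metric_curves, list(thresholds.values()))
    status["tradeoffs"] = "ok"

    log = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": [int(s) for s in seeds],
        "mc_sims": config.mc_sims,
        "cv": config.cv,
        "boot_reps": config.boot_reps,
        "pressure_type": config.pressure_type,
        "indicator": ind_group,
        "n_datasets_ok": len(datasets),
        "n_datasets_failed": n_failed,
        "tie_breaks": {a: ens_results[a].selection.tie_breaks for a in CORE_ATTRIBUTES},
        "runtime_s": round(time.time() - t_start, 2),
    }
    result = PipelineResult(
        config=config,
        pressures=P,
        attribute_table=attribute_table,
        selections=selections,
        vote_tallies=tallies,
        thresholds=thresholds,
        screens=screens,
        translation=translation,
        scenarios=scenarios,
        status=status,
        log=log,
    )
    if config.out_dir:
        _write_bundle(result, Path(config.out_dir))
    return result


def _write_bundle(result: PipelineResult, out: Path) -> None:
    from . import io as eio

    out.mkdir(parents=True, exist_ok=True)
    eio.write_attribute_table(result.attribute_table, out / "attributes.csv")
    result.scenarios.to_csv(out / "scenarios.csv", index=False)
    eio.write_json(
        {
            a: {
                "best_fit": result.selections[a],
                "vote": result.vote_tallies[a],
                "threshold": dataclasses.asdict(result.thresholds[a]),
            }
            for a in result.selections
        },
        out / "thresholds.json",
    )
    eio.write_json([dataclasses.asdict(s) for s in result.screens], out / "indicator_screens.json")
    if result.translation is not None:
        d = dataclasses.asdict(result.translation)
        d["model"] = result.translation.model.to_dict()
        eio.write_json(d, out / "indicator_translation.json")
    eio.write_json({"status": result.status, **result.log}, out / "run_log.json")
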