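"""Trade-off scenarios: attributes and yields on a common [0, 1] scale.

The spider-plot comparison contrasts the ecosystem attributes and fisheries
yield metrics at three pressure levels: a minimum-impact scenario (no
utility threshold breached), a threshold scenario at the lowest significant
utility threshold (median), and a maximum-impact scenario at the highest
pressure considered.  Every metric is affinely re-scaled over its observed
range so 0 marks its stressed extreme and 1 its unstressed extreme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .uncertainty import ThresholdEstimate

__all__ = [
    "TradeoffScenario",
    "rescale_unit_interval",
    "scenario_table",
    "plot_spider",
]


@dataclass(frozen=True)
class TradeoffScenario:
    """One named pressure level with every metric on the [0, 1] scale."""

    name: str
    pressure: float
    values: Dict[str, float]

    def __post_init__(self):
        for metric, v in self.values.items():
            if not (-1e-9 <= v <= 1 + 1e-9):
                raise ValueError(f"scenario value for {metric!r} outside [0, 1]: {v}")


def rescale_unit_interval(series, stressed_is: str = "min") -> np.ndarray:
    """Affine map of a metric series onto [0, 1].

    ``stressed_is='min'`` sends the series minimum to 0 (stressed) and the
    maximum to 1; ``'max'`` flips the orientation.  Constant series are
    rejected (no range to scale over).
    """
    if stressed_is not in ("min", "max"):
        raise ValueError("stressed_is must be 'min' or 'max'")
    x = np.asarray(series, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise ValueError("cannot rescale a constant metric series")
    scaled = (x - lo) / (hi - lo)
    return scaled if stressed_is == "min" else 1.0 - scaled


def scenario_table(
    metric_curves: Mapping[str, Tuple[np.ndarray, np.ndarray]],
    thresholds: Sequence[ThresholdEstimate],
    stressed_is: Optional[Mapping[str, str]] = None,
    min_pressure: float = 0.0,
    max_pressure: float = 1.0,
    custom_scenarios: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Evaluate each re-scaled metric at the scenario pressures.

    ``metric_curves`` maps a metric name to its ``(pressure, median value)``
    series on the [0, 1] pressure axis.  The threshold scenario sits at the
    lowest *significant* median utility threshold; when no threshold is
    significant it is omitted with a warning.  Returns a long table with
    columns ``scenario, pressure, metric, value01``, one row per metric per
    scenario, every value in [0, 1].
    """
    stressed_is = dict(stressed_is or {})
    scenarios: Dict[str, float] = {"minimum_impact": float(min_pressure)}
    sig = [t.median_Pt for t in thresholds if t.significant and t.median_Pt is not None]
    if sig:
        scenarios["threshold"] = float(min(sig))
    else:
        warnings.warn(
            "no significant utility threshold: omitting the threshold scenario", stacklevel=2
        )
    scenarios["maximum_impact"] = float(max_pressure)
    for name, p in (custom_scenarios or {}).items():
        scenarios[name] = float(p)

    rows = []
    for metric, (P, v) in metric_curves.items():
        P = np.asarray(P, dtype=float)
        v = np.asarray(v, dtype=float)
        order = np.argsort(P)
        P, v = P[order], v[order]
        v01 = rescale_unit_interval(v, stressed_is.get(metric, "min"))
        for scen, p in scenarios.items():
            val = float(np.interp(p, P, v01))
            rows.append(
                {
                    "scenario": scen,
                    "pressure": p,
                    "metric": metric,
                    "value01": min(max(val, 0.0), 1.0),
                }
            )
    return pd.DataFrame(rows)


def plot_spider(table: pd.DataFrame, path: Optional[str] = None):
    """Radar/spider plot of a scenario table (presentation helper).

    One polygon per scenario over the metric axes.  Returns the matplotlib
    figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = list(dict.fromkeys(table["metric"]))
    angles = np.linspace(0, 2 * np.pi, len(metrics), endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    for scen, sub in table.groupby("scenario", sort=False):
        vals = sub.set_index("metric").loc[metrics, "value01"].to_numpy()
        th = np.concatenate([angles, angles[:1]])
        vv = np.concatenate([vals, vals[:1]])
        ax.plot(th, vv, label=f"{scen} (P={sub['pressure'].iloc[0]:.2f})")
        ax.fill(th, vv, alpha=0.15)
    ax.set_xticks(angles)
    ax.set_xticklabels(metrics, fontsize=8)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=8)
    if path:
        fig.savefig(path, bbox_inches="tight")
    return fig
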