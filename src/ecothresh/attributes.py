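"""Ecosystem attributes and fisheries yield metrics from biomass tables.

Four whole-system attributes are computed from biomass-by-functional-group
snapshots of a food web:

* **resilience** ``R`` — a nonpositive index of biomass reorganization: how
  differently individual groups changed relative to the aggregate biomass
  change between a pre-pressure and a post-pressure state.  ``R = 0`` means
  every group changed by exactly the aggregate factor (a proportional,
  resilient response); more negative values mean lower resilience.
* **NPP/Biomass** — net primary production over total living biomass
  (detritus and fishery discards excluded); an ecosystem maintenance cost.
* **Shannon diversity** ``H`` — evenness of the biomass distribution among
  living groups (natural log).
* **mean trophic level** — biomass-weighted mean trophic level of living
  groups.

Two fisheries yield metrics, total landings and total market value (landings
priced at fixed per-group market prices), complete the trade-off analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "FunctionalGroup",
    "BiomassSnapshot",
    "AttributeVector",
    "resilience_index",
    "shannon_diversity",
    "mean_trophic_level",
    "npp_biomass_ratio",
    "yield_metrics",
    "compute_attributes",
    "standardize_series",
    "standardize_attributes",
    "rescale_pressure",
    "ATTRIBUTE_ORIENTATION",
]


@dataclass(frozen=True)
class FunctionalGroup:
    """Metadata for one functional group of the food web.

    ``price_per_tonne`` is the modal gear-specific market price, held
    constant across pressure levels.  Detritus and discard groups are
    excluded from diversity, mean-trophic-level and biomass denominators.
    """

    name: str
    trophic_level: float = 1.0
    price_per_tonne: float = 0.0
    is_detritus: bool = False
    is_discard: bool = False
    is_primary_producer: bool = False
    fished: bool = False

    def __post_init__(self):
        if self.trophic_level < 1.0:
            raise ValueError(f"trophic level of {self.name!r} must be >= 1")
        if self.price_per_tonne < 0:
            raise ValueError(f"price of {self.name!r} must be nonnegative")

    @property
    def is_living(self) -> bool:
        return not (self.is_detritus or self.is_discard)


@dataclass
class BiomassSnapshot:
    """System state at one time: biomass (t km^-2) and landings by group,
    plus net primary production (t km^-2 yr^-1)."""

    biomass: Dict[str, float]
    npp: float = 0.0
    landings: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not any(b > 0 for b in self.biomass.values()):
            raise ValueError("snapshot needs at least one group with positive biomass")
        if any(b < 0 for b in self.biomass.values()):
            raise ValueError("biomass must be nonnegative")
        if self.npp < 0:
            raise ValueError("npp must be nonnegative")


@dataclass(frozen=True)
class AttributeVector:
    """The four ecosystem attributes plus the two yield metrics."""

    resilience: float
    npp_over_biomass: float
    shannon: float
    mean_trophic_level: float
    total_landings: float
    total_market_value: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "resilience": self.resilience,
            "npp_over_biomass": self.npp_over_biomass,
            "shannon": self.shannon,
            "mean_trophic_level": self.mean_trophic_level,
            "total_landings": self.total_landings,
            "total_market_value": self.total_market_value,
        }


def _living_groups(groups: Mapping[str, FunctionalGroup], names: Iterable[str]):
    out = []
    for n in names:
        g = groups.get(n)
        if g is None:
            raise KeyError(f"no metadata for functional group {n!r}")
        if g.is_living:
            out.append(n)
    return out


# ----------------------------------------------------------------------
def resilience_index(before: BiomassSnapshot, after: BiomassSnapshot) -> float:
    """Resilience index R between a pre-pressure and post-pressure snapshot.

    R = -sum_i | log(B2_i/B1_i) - log(sum B2 / sum B1) |

    Each group's log biomass ratio is compared with the aggregate log ratio;
    the summed absolute deviations, negated, measure how unevenly the system
    reorganized.  R = 0 iff every group changed by the aggregate factor.
    """
    if set(before.biomass) != set(after.biomass):
        raise ValueError("snapshots must share the same group set")
    for name, b in before.biomass.items():
        if b <= 0:
            raise ValueError(f"pre-pressure biomass of group {name!r} must be positive")
    names = sorted(before.biomass)
    b1 = np.array([before.biomass[n] for n in names])
    b2 = np.array([after.biomass[n] for n in names])
    with np.errstate(divide="ignore"):
        log_ratio = np.log(b2) - np.log(b1)
        agg = math.log(b2.sum()) - math.log(b1.sum())
    return float(-np.abs(log_ratio - agg).sum())


def shannon_diversity(s: BiomassSnapshot, groups: Mapping[str, FunctionalGroup]) -> float:
    """Shannon diversity H = -sum p_i ln p_i over living-group biomass shares."""
    names = _living_groups(groups, s.biomass)
    b = np.array([s.biomass[n] for n in names])
    total = b.sum()
    if total <= 0:
        raise ValueError("total living biomass must be positive")
    p = b[b > 0] / total
    return float(-(p * np.log(p)).sum())


def mean_trophic_level(s: BiomassSnapshot, groups: Mapping[str, FunctionalGroup]) -> float:
    """Biomass-weighted mean trophic level over living groups."""
    names = _living_groups(groups, s.biomass)
    b = np.array([s.biomass[n] for n in names])
    tl = np.array([groups[n].trophic_level for n in names])
    total = b.sum()
    if total <= 0:
        raise ValueError("total living biomass must be positive")
    return float((b * tl).sum() / total)


def npp_biomass_ratio(s: BiomassSnapshot, groups: Mapping[str, FunctionalGroup]) -> float:
    """Net primary production over total living biomass (detritus and
    discards excluded from the denominator)."""
    names = _living_groups(groups, s.biomass)
    total = sum(s.biomass[n] for n in names)
    if total <= 0:
        raise ValueError("living biomass denominator must be positive")
    return float(s.npp / total)


def yield_metrics(
    s: BiomassSnapshot, groups: Mapping[str, FunctionalGroup]
) -> Tuple[float, float]:
    """(total landings, total market value); prices fixed across pressures."""
    landings = 0.0
    value = 0.0
    for name, l in s.landings.items():
        g = groups.get(name)
        if g is None:
            raise KeyError(f"no metadata for functional group {name!r}")
        if l < 0:
            raise ValueError(f"negative landings for {name!r}")
        landings += l
        value += l * g.price_per_tonne
    return landings, value


def compute_attributes(
    before: BiomassSnapshot,
    after: BiomassSnapshot,
    groups: Mapping[str, FunctionalGroup],
) -> AttributeVector:
    """All four attributes of ``after`` (resilience relative to ``before``)
    plus the yield metrics."""
    tl, tv = yield_metrics(after, groups)
    return AttributeVector(
        resilience=resilience_index(before, after),
        npp_over_biomass=npp_biomass_ratio(after, groups),
        shannon=shannon_diversity(after, groups),
        mean_trophic_level=mean_trophic_level(after, groups),
        total_landings=tl,
        total_market_value=tv,
    )


# ----------------------------------------------------------------------
#: Whether the raw attribute is larger when the system is *unstressed*.
#: Attributes whose raw value grows under stress are sign-flipped before
#: standardization so that, uniformly, small = stressed and large =
#: unstressed.  The flip choices here describe the shipped simulator's
#: behaviour; callers may override per attribute.
ATTRIBUTE_ORIENTATION: Dict[str, bool] = {
    "resilience": True,  # R <= 0, 0 = most resilient
    "npp_over_biomass": True,
    "shannon": True,
    "mean_trophic_level": True,
    "total_landings": True,
    "total_market_value": True,
}


@dataclass(frozen=True)
class AffineTransform:
    """Records ``z = (flip*x - mean)/sd`` so raw units can be recovered."""

    flip: float
    mean: float
    sd: float

    def apply(self, x):
        return (self.flip * np.asarray(x, dtype=float) - self.mean) / self.sd

    def invert(self, z):
        return (np.asarray(z, dtype=float) * self.sd + self.mean) / self.flip


def standardize_series(values, *, unstressed_is_high: bool = True):
    """Orient a series so large = unstressed, then z-score it.

    Returns ``(standardized array, AffineTransform)``.  Raises on constant
    input (zero variance leaves the z-score undefined).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("standardization needs at least 2 distinct values")
    flip = 1.0 if unstressed_is_high else -1.0
    ox = flip * x
    mean = float(ox.mean())
    sd = float(ox.std(ddof=0))
    if sd == 0:
        raise ValueError("zero variance: cannot standardize a constant series")
    t = AffineTransform(flip=flip, mean=mean, sd=sd)
    return t.apply(x), t


def standardize_attributes(
    df: pd.DataFrame,
    orientation: Optional[Mapping[str, bool]] = None,
) -> Tuple[pd.DataFrame, Dict[str, AffineTransform]]:
    """Standardize a long attribute table (columns ``attribute``,
    ``value_raw``) to zero mean / unit variance per attribute, flipping
    orientation first where the raw attribute increases under stress.

    Returns the table with a ``value_standardized`` column added, plus the
    per-attribute affine transforms for recovering raw units.
    """
    for col in ("attribute", "value_raw"):
        if col not in df.columns:
            raise ValueError(f"attribute table is missing column {col!r}")
    orientation = dict(ATTRIBUTE_ORIENTATION, **(orientation or {}))
    out = df.copy()
    out["value_standardized"] = np.nan
    transforms: Dict[str, AffineTransform] = {}
    for attr, sub in df.groupby("attribute"):
        z, t = standardize_series(
            sub["value_raw"].to_numpy(),
            unstressed_is_high=orientation.get(attr, True),
        )
        out.loc[sub.index, "value_standardized"] = z
        transforms[attr] = t
    return out, transforms


def rescale_pressure(raw, *, invert: bool = False) -> np.ndarray:
    """Affine rescaling of raw pressure values onto [0, 1].

    0 marks the least-stressed end and 1 the most-stressed end.  With
    ``invert=True`` the *largest* raw value maps to 0 (e.g. nearshore
    habitat: the highest macrophyte production multiplier is the lowest
    habitat pressure).
    """
    x = np.asarray(raw, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise ValueError("cannot rescale a constant pressure series")
    scaled = (x - lo) / (hi - lo)
    return 1.0 - scaled if invert else scaled
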