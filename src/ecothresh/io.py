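"""File I/O: biomass tables, group metadata, attribute tables, food-web
specs and result bundles.

CSV schemas
-----------
BiomassTable (long): ``pressure_level, replicate, group, biomass, landings``.
Group metadata: ``group, trophic_level, price_per_tonne, is_detritus,
is_discard, is_primary_producer, fished``.
Attribute table (long): ``pressure, replicate, attribute, value_raw``
(+ ``value_standardized`` once standardized).
Scenario table: ``scenario, pressure, metric, value01``.

All floats round-trip at full precision (write -> read is identity to
better than 1e-12).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Dict, Union

import numpy as np
import pandas as pd
import yaml

from .attributes import FunctionalGroup
from .synthetic import ConsumerSpec, FoodWebSpec, ProducerSpec

__all__ = [
    "read_biomass_table",
    "write_biomass_table",
    "read_group_metadata",
    "write_group_metadata",
    "read_attribute_table",
    "write_attribute_table",
    "read_json",
    "write_json",
    "spec_to_dict",
    "spec_from_dict",
    "load_foodweb_spec",
    "save_foodweb_spec",
]

PathLike = Union[str, Path]

_BIOMASS_COLUMNS = ["pressure_level", "replicate", "group", "biomass", "landings"]
_GROUP_COLUMNS = [
    "group",
    "trophic_level",
    "price_per_tonne",
    "is_detritus",
    "is_discard",
    "is_primary_producer",
    "fished",
]
_ATTRIBUTE_COLUMNS = ["pressure", "replicate", "attribute", "value_raw"]


def _check_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing column(s) {missing}; found {list(df.columns)}")


def write_biomass_table(df: pd.DataFrame, path: PathLike) -> None:
    _check_columns(df, _BIOMASS_COLUMNS, "BiomassTable")
    df[_BIOMASS_COLUMNS].to_csv(path, index=False)


def read_biomass_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, _BIOMASS_COLUMNS, f"BiomassTable {path}")
    return df


def write_group_metadata(groups: Dict[str, FunctionalGroup], path: PathLike) -> None:
    rows = [
        {
            "group": g.name,
            "trophic_level": g.trophic_level,
            "price_per_tonne": g.price_per_tonne,
            "is_detritus": g.is_detritus,
            "is_discard": g.is_discard,
            "is_primary_producer": g.is_primary_producer,
            "fished": g.fished,
        }
        for g in groups.values()
    ]
    pd.DataFrame(rows, columns=_GROUP_COLUMNS).to_csv(path, index=False)


def read_group_metadata(path: PathLike) -> Dict[str, FunctionalGroup]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, _GROUP_COLUMNS, f"group metadata {path}")
    out = {}
    for _, row in df.iterrows():
        out[row["group"]] = FunctionalGroup(
            name=row["group"],
            trophic_level=float(row["trophic_level"]),
            price_per_tonne=float(row["price_per_tonne"]),
            is_detritus=bool(row["is_detritus"]),
            is_discard=bool(row["is_discard"]),
            is_primary_producer=bool(row["is_primary_producer"]),
            fished=bool(row["fished"]),
        )
    return out


def write_attribute_table(df: pd.DataFrame, path: PathLike) -> None:
    _check_columns(df, _ATTRIBUTE_COLUMNS, "attribute table")
    df.to_csv(path, index=False)


def read_attribute_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, _ATTRIBUTE_COLUMNS, f"attribute table {path}")
    return df


# ----------------------------------------------------------------------
class _NumpyEncoder(json.JSONEncoder):
    def default(self, o: Any):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(obj: Any, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, cls=_NumpyEncoder, indent=2, allow_nan=True) + "\n")


def read_json(path: PathLike) -> Any:
    return json.loads(Path(path).read_text())


# ----------------------------------------------------------------------
def spec_to_dict(spec: FoodWebSpec) -> dict:
    return {
        "groups": {
            n: {
                "trophic_level": g.trophic_level,
                "price_per_tonne": g.price_per_tonne,
                "is_detritus": g.is_detritus,
                "is_discard": g.is_discard,
                "is_primary_producer": g.is_primary_producer,
                "fished": g.fished,
            }
            for n, g in spec.groups.items()
        },
        "producers": {
            n: {"r": p.r, "K": p.K, "mu": p.mu, "habitat_forced": p.habitat_forced}
            for n, p in spec.producers.items()
        },
        "consumers": {
            n: {"m": c.m, "q": c.q, "eps": c.eps, "diet": dict(c.diet), "F_base": c.F_base}
            for n, c in spec.consumers.items()
        },
        "detritus_name": spec.detritus_name,
        "detritus_export": spec.detritus_export,
        "mediation": dict(spec.mediation),
        "initial_biomass": dict(spec.initial_biomass),
    }


def spec_from_dict(d: dict) -> FoodWebSpec:
    groups = {n: FunctionalGroup(name=n, **g) for n, g in d["groups"].items()}
    producers = {n: ProducerSpec(**p) for n, p in d["producers"].items()}
    consumers = {n: ConsumerSpec(**c) for n, c in d["consumers"].items()}
    return FoodWebSpec(
        groups=groups,
        producers=producers,
        consumers=consumers,
        detritus_name=d.get("detritus_name", "detritus"),
        detritus_export=float(d["detritus_export"]),
        mediation=dict(d.get("mediation", {})),
        initial_biomass={k: float(v) for k, v in d.get("initial_biomass", {}).items()},
    )


def save_foodweb_spec(spec: FoodWebSpec, path: PathLike) -> None:
    """YAML or JSON by extension."""
    p = Path(path)
    d = spec_to_dict(spec)
    if p.suffix in (".yaml", ".yml"):
        p.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        write_json(d, p)


def load_foodweb_spec(path: PathLike) -> FoodWebSpec:
    p = Path(path)
    if p.suffix in (".yaml", ".yml"):
        d = yaml.safe_load(p.read_text())
    else:
        d = read_json(p)
    return spec_from_dict(d)
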