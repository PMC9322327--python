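"""Domain types, tabular I/O and run configuration.

The common currency of the pipeline is the :class:`ObservationTable`: one row
per plant in a nested on-farm design (farm > plot ≡ variety > subplot >
plant), carrying raw morphological measurements, gas-exchange triplicates,
subplot-level soil chemistry and farm-level climate covariates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ObservationTable",
    "RunConfig",
    "SchemaError",
    "IntegrityError",
    "read_observations",
    "write_table",
    "read_table",
]


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class IntegrityError(ValueError):
    """The nested structure of the table is violated."""


#: identifier columns, outermost level first
ID_COLUMNS = ("farm_id", "variety_id", "subplot_id", "plant_id")

#: per-plant raw measurements (missing values allowed, flagged downstream)
MEASUREMENT_COLUMNS = (
    "LA",              # leaf area, cm^2
    "leaf_dry_mass",   # g
    "PD",              # petiole diameter, mm
    "RL",              # taproot length, cm
    "RD",              # taproot diameter, mm
    "taproot_dry_mass",  # g
)

#: gas-exchange triplicates (Asat umol CO2 m-2 s-1; gs, TR mmol m-2 s-1)
GAS_REP_COLUMNS = tuple(
    f"{var}_rep{i}" for var in ("Asat", "gs", "TR") for i in (1, 2, 3)
)

#: subplot-level soil chemistry
SOIL_COLUMNS = ("SN", "SC", "SP")  # total N, total C (mg g-1); Bray-1 P (mg kg-1)

#: farm-level climate covariates
CLIMATE_COLUMNS = ("temp", "precip")  # degC; mm

REQUIRED_COLUMNS = ID_COLUMNS + MEASUREMENT_COLUMNS + GAS_REP_COLUMNS + SOIL_COLUMNS + CLIMATE_COLUMNS


@dataclass
class RunConfig:
    """Configuration shared across pipeline stages.

    Defaults mirror the analysis conventions of the study design this
    package emulates: log transforms for density-like and soil variables,
    square roots for size traits and the photosynthesis response, a 0.6
    collinearity screen, and Kenward-Roger small-sample tests at alpha=0.05.
    """

    transform_map: dict[str, str] = field(default_factory=lambda: {
        "LA": "sqrt",
        "LMA": "log",
        "PD": "sqrt",
        "TTD": "log",
        "SN": "log",
        "SC": "log",
        "SP": "log",
        "Asat": "sqrt",
        "WUE": "log",
        "temp": "identity",
        "precip": "identity",
    })
    collinearity_threshold: float = 0.6
    outlier_z_threshold: float = 4.0
    alpha: float = 0.05
    df_method: str = "kenward_roger"      # or "satterthwaite"
    aic_likelihood: str = "reml"          # or "ml"
    reference_variety: str | None = None  # None -> first level encountered
    use_radius: bool = False              # halve RD before the taproot-volume formula
    taproot_shape: str = "truncated_cone"  # or "cylinder"
    rename_map: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.collinearity_threshold < 1.0):
            raise ValueError("collinearity_threshold must be in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.df_method not in ("kenward_roger", "satterthwaite", "residual"):
            raise ValueError(f"unknown df_method {self.df_method!r}")
        if self.aic_likelihood not in ("reml", "ml"):
            raise ValueError(f"unknown aic_likelihood {self.aic_likelihood!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        if "transform_map" in raw:
            merged = dict(base.transform_map)
            merged.update(raw.pop("transform_map"))
            raw["transform_map"] = merged
        return dataclasses.replace(base, **raw)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


@dataclass
class ObservationTable:
    """A validated plant-level observation table.

    Wraps a :class:`pandas.DataFrame` whose rows are uniquely keyed by
    (farm, variety, subplot, plant). Soil values are constant within a
    subplot and climate values constant within a farm; derived per-plant
    means (Asat, gs, TR) and derived traits (LMA, TTD, WUE) are added by
    the preprocessing stage, not on read.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        if len(self.df) == 0:
            return
        key = list(ID_COLUMNS)
        dups = self.df.duplicated(subset=key)
        if dups.any():
            bad = self.df.loc[dups, key].iloc[0].tolist()
            raise IntegrityError(f"duplicate nested key {tuple(bad)}")
        # soil constant within (farm, variety, subplot)
        sub = self.df.groupby(["farm_id", "variety_id", "subplot_id"], sort=False, observed=True)
        for col in SOIL_COLUMNS:
            if (sub[col].nunique(dropna=False) > 1).any():
                raise IntegrityError(f"soil variable {col!r} varies within a subplot")
        farm = self.df.groupby("farm_id", sort=False, observed=True)
        for col in CLIMATE_COLUMNS:
            if (farm[col].nunique(dropna=False) > 1).any():
                raise IntegrityError(f"climate variable {col!r} varies within a farm")
        # same subplot label must not recur under two plots of one farm is
        # impossible by keying; but a plant label reused across subplots is fine.
        for col in MEASUREMENT_COLUMNS + SOIL_COLUMNS:
            vals = self.df[col].to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] <= 0):
                raise IntegrityError(f"non-positive value in {col!r}")

    # -- convenience -------------------------------------------------------
    def missing_physiology(self) -> pd.Series:
        """Rows without any gas-exchange reading (flagged, never auto-dropped)."""
        reps = self.df[[c for c in GAS_REP_COLUMNS if c.startswith("Asat")]]
        return reps.isna().all(axis=1)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_farms(self) -> int:
        return self.df["farm_id"].nunique()

    @property
    def n_varieties(self) -> int:
        return self.df["variety_id"].nunique()

    def variety_levels(self, reference: str | None = None) -> list[str]:
        """Variety levels in order of first appearance, reference first."""
        levels = list(dict.fromkeys(self.df["variety_id"].astype(str)))
        if reference is not None:
            if reference not in levels:
                raise ValueError(f"reference variety {reference!r} not present")
            levels.remove(reference)
            levels.insert(0, reference)
        return levels

    def copy(self) -> "ObservationTable":
        return ObservationTable(self.df.copy())


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_observations(path: str | Path, config: RunConfig | None = None) -> ObservationTable:
    """Read a comma- or tab-separated plant-level file into a validated table.

    Rows with missing physiological readings are kept (flagged and removed
    only by an explicit preprocessing step).
    """
    config = config or RunConfig()
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if config.rename_map:
        df = df.rename(columns=config.rename_map)
    for col in ID_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(str)
    return ObservationTable(df)


def write_table(table: pd.DataFrame | ObservationTable, path: str | Path) -> Path:
    """Write any result table as tab-separated text (round-trip safe)."""
    df = table.df if isinstance(table, ObservationTable) else table
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
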