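"""Trait and performance derivation, transformation, standardization, screening.

Turns a raw :class:`~traitenv.data_model.ObservationTable` into the
analysis-ready frame the models consume: per-plant gas-exchange means,
water-use efficiency, leaf mass per area, taproot volume/tissue density,
normality transforms, z-standardized predictors, a pairwise-correlation
collinearity screen and a standardized-score outlier filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .data_model import ObservationTable, RunConfig

__all__ = [
    "PreprocessReport",
    "average_gas_triplicates",
    "compute_wue",
    "taproot_volume",
    "compute_ttd",
    "transform_standardize",
    "screen_collinearity",
    "remove_outliers",
    "preprocess",
    "PreprocessError",
]

TRAITS = ("LA", "LMA", "PD", "TTD")
SOILS = ("SN", "SC", "SP")
COVARIATES = ("temp", "precip")
RESPONSES = ("Asat", "WUE")


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessReport:
    n_input: int = 0
    n_dropped_missing_phys: int = 0
    n_dropped_outliers: int = 0
    n_final: int = 0
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    transforms_applied: dict[str, str] = field(default_factory=dict)
    standardization_params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        assert self.n_final == self.n_input - self.n_dropped_missing_phys - self.n_dropped_outliers

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_dropped_missing_phys": self.n_dropped_missing_phys,
            "n_dropped_outliers": self.n_dropped_outliers,
            "n_final": self.n_final,
            "flagged_pairs": [[a, b, float(r)] for a, b, r in self.flagged_pairs],
            "transforms_applied": self.transforms_applied,
            "standardization_params": {
                k: [float(m), float(s)] for k, (m, s) in self.standardization_params.items()
            },
        }


def average_gas_triplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Average the (up to three) gas-exchange readings per plant.

    Adds per-plant means ``Asat``, ``gs``, ``TR`` plus an ``n_gas_reps``
    count and a ``missing_phys`` flag for plants with no readings at all.
    Plants with 1-2 readings are averaged with a warning.
    """
    out = df.copy()
    counts = None
    for var in ("Asat", "gs", "TR"):
        reps = out[[f"{var}_rep{i}" for i in (1, 2, 3)]].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            out[var] = np.nanmean(reps, axis=1)
        c = np.isfinite(reps).sum(axis=1)
        counts = c if counts is None else np.minimum(counts, c)
    out["n_gas_reps"] = counts
    out["missing_phys"] = counts == 0
    incomplete = int(((counts > 0) & (counts < 3)).sum())
    if incomplete:
        warnings.warn(f"{incomplete} plant(s) with fewer than 3 gas-exchange reps; "
                      "averaged available readings")
    return out


def compute_wue(Asat, TR):
    """Instantaneous water-use efficiency Asat / TR (umol CO2 per mmol H2O).

    Non-positive transpiration yields NaN (flagged, not an exception).
    """
    Asat = np.asarray(Asat, dtype=float)
    TR = np.asarray(TR, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        wue = np.where(TR > 0, Asat / TR, np.nan)
    return wue


def taproot_volume(RL, RD, r: float = 0.05, shape: str = "truncated_cone"):
    """Taproot volume (cm^3) from length RL (cm) and diameter RD (cm).

    The truncated-cone form is V = 1/3 * pi * RL * (RD^2 + r^2 + RD*r) with
    tip size r = 0.05 cm (the threshold at which root length is measured);
    ``shape='cylinder'`` gives the V = pi * RL * RD^2 alternative for
    sensitivity runs. At RD = r the truncated cone reduces to the cylinder
    of the same cross-section (continuity of the formula).
    """
    RL = np.asarray(RL, dtype=float)
    RD = np.asarray(RD, dtype=float)
    if np.any(RD[np.isfinite(RD)] <= r) and shape == "truncated_cone":
        raise PreprocessError(f"taproot diameter must exceed the tip size r={r} cm")
    if shape == "truncated_cone":
        return np.pi / 3.0 * RL * (RD ** 2 + r ** 2 + RD * r)
    if shape == "cylinder":
        return np.pi * RL * RD ** 2
    raise ValueError(f"unknown taproot shape {shape!r}")


def compute_ttd(dry_mass, volume):
    """Taproot tissue density: dry mass / volume (g cm^-3)."""
    dry_mass = np.asarray(dry_mass, dtype=float)
    volume = np.asarray(volume, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(volume > 0, dry_mass / volume, np.nan)


_TRANSFORMS = {
    "log": np.log,
    "sqrt": np.sqrt,
    "identity": lambda x: x,
}


def apply_transform(values: np.ndarray, transform: str, name: str = "") -> np.ndarray:
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    values = np.asarray(values, dtype=float)
    if transform in ("log", "sqrt"):
        bad = np.where(np.isfinite(values) & (values <= 0) if transform == "log"
                       else np.isfinite(values) & (values < 0))[0]
        if bad.size:
            raise PreprocessError(
                f"non-positive value for {transform}({name or 'variable'}) at row {bad[0]}"
            )
    return _TRANSFORMS[transform](values)


def transform_standardize(
    df: pd.DataFrame,
    transform_map: dict[str, str],
    predictors: tuple[str, ...],
    responses: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Transform predictors and responses; z-standardize predictors only.

    Responses are modeled on their transformed scale but keep their units
    (standardized slopes then refer to SD changes in the predictors). The
    per-variable (mean, sd) on the transformed scale is returned so that
    surfaces can be annotated in original units.
    """
    out = df.copy()
    params: dict[str, tuple[float, float]] = {}
    for var in predictors:
        tr = transform_map.get(var, "identity")
        t = apply_transform(out[var].to_numpy(), tr, var)
        finite = t[np.isfinite(t)]
        mu, sd = float(np.mean(finite)), float(np.std(finite))
        if sd < 1e-12:
            raise PreprocessError(f"zero-variance predictor {var!r}")
        out[var] = (t - mu) / sd
        params[var] = (mu, sd)
    for var in responses:
        tr = transform_map.get(var, "identity")
        t = apply_transform(out[var].to_numpy(), tr, var)
        name = response_column(var, tr)
        out[name] = t
        finite = t[np.isfinite(t)]
        params[name] = (float(np.mean(finite)), float(np.std(finite)))
    return out, params


def response_column(var: str, transform: str) -> str:
    return var if transform == "identity" else f"{transform}_{var}"


def screen_collinearity(
    df: pd.DataFrame,
    variables: tuple[str, ...],
    threshold: float = 0.6,
) -> list[tuple[str, str, float]]:
    """Pairs with Pearson |r| strictly above the threshold.

    Run on the transformed, standardized variables; a pair at exactly the
    threshold is not flagged.
    """
    flagged = []
    for a, b in combinations(variables, 2):
        sub = df[[a, b]].dropna()
        if len(sub) < 3:
            continue
        r = float(np.corrcoef(sub[a], sub[b])[0, 1])
        if abs(r) > threshold:
            flagged.append((a, b, r))
    return flagged


def alternative_env_sets(
    environments: tuple[str, ...],
    flagged: list[tuple[str, str, float]],
) -> list[tuple[str, ...]]:
    """Alternative environment sets: one per member of each flagged pair.

    A flagged pair among the environments spawns one candidate set per
    member (keeping everything else); with no flags the original set is the
    only candidate. Soil N vs soil C is the canonical case.
    """
    env_flags = [(a, b) for a, b, _ in flagged if a in environments and b in environments]
    sets = [tuple(environments)]
    for a, b in env_flags:
        sets = [
            tuple(v for v in s if v != b) for s in sets
        ] + [
            tuple(v for v in s if v != a) for s in sets
        ]
    # drop duplicates, keep order
    seen, out = set(), []
    for s in sets:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def remove_outliers(
    df: pd.DataFrame,
    variable: str,
    z_threshold: float = 4.0,
) -> tuple[pd.DataFrame, int]:
    """Drop rows whose standardized score on ``variable`` exceeds the cutoff."""
    z = df[variable].to_numpy(dtype=float)
    keep = ~(np.abs(z) > z_threshold)
    keep |= ~np.isfinite(z)  # missing values are not outliers
    return df.loc[keep].copy(), int((~keep).sum())


def preprocess(
    table: ObservationTable,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Full preprocessing path: derive, drop missing physiology, transform,
    standardize, screen, filter outliers.

    Returns the analysis-ready frame (standardized predictors; transformed
    responses named e.g. ``sqrt_Asat``, ``log_WUE``) and a report whose
    counts reconcile exactly with the input size.
    """
    config = config or RunConfig()
    report = PreprocessReport(n_input=len(table))
    df = average_gas_triplicates(table.df)

    # explicit removal of plants without physiological measurements
    report.n_dropped_missing_phys = int(df["missing_phys"].sum())
    df = df.loc[~df["missing_phys"]].copy()

    df["WUE"] = compute_wue(df["Asat"], df["TR"])
    df["LMA"] = df["leaf_dry_mass"].to_numpy(dtype=float) / df["LA"].to_numpy(dtype=float)
    rd_cm = df["RD"].to_numpy(dtype=float) / 10.0
    if config.use_radius:
        rd_cm = rd_cm / 2.0
    df["taproot_volume"] = taproot_volume(
        df["RL"].to_numpy(dtype=float), rd_cm, shape=config.taproot_shape
    )
    df["TTD"] = compute_ttd(df["taproot_dry_mass"], df["taproot_volume"])

    predictors = TRAITS + SOILS + COVARIATES
    df, params = transform_standardize(df, config.transform_map, predictors, RESPONSES)
    report.transforms_applied = {
        v: config.transform_map.get(v, "identity") for v in predictors + RESPONSES
    }
    report.standardization_params = params

    report.flagged_pairs = screen_collinearity(
        df, TRAITS + SOILS, config.collinearity_threshold
    )

    df, n_out = remove_outliers(df, "LA", config.outlier_z_threshold)
    report.n_dropped_outliers = n_out
    report.n_final = len(df)
    report.validate()
    return df.reset_index(drop=True), report
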