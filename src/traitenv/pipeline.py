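"""End-to-end orchestration: preprocess -> dual full models -> selection ->
AIC choice -> ANOVA -> slopes / surfaces / R2, with a reproducible manifest.

The pipeline is a pure function of (input table, configuration): rerunning
with identical inputs writes byte-identical machine-readable outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import ObservationTable, RunConfig, write_table
from .inference import backward_select, compare_alternatives, type2_anova
from .lmm_engine import FittedLMM, information_criterion
from .model_design import ModelSpec, build_term_graph, expand_design, random_design
from .preprocess import (COVARIATES, RESPONSES, SOILS, TRAITS,
                         alternative_env_sets, preprocess, response_column)
from .trait_env import r2_nakagawa, response_surface, slope_table

__all__ = ["RunManifest", "run_pipeline", "diagnostics"]


@dataclass
class RunManifest:
    config_hash: str
    input_hash: str
    version: str
    seed: int
    timings: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def diagnostics(fit: FittedLMM) -> dict:
    """Residual summaries for the usual mixed-model diagnostic plots.

    Conditional residuals (observed minus fixed and random predictions),
    fitted values, normal-quantile pairs, and a Shapiro-Wilk statistic as a
    single-number normality summary.
    """
    from scipy import stats

    resid = fit.conditional_residuals()
    fitted = fit.fitted_fixed + (fit._problem.y - fit.fitted_fixed - resid)
    order = np.argsort(resid)
    qq_theoretical = stats.norm.ppf((np.arange(1, len(resid) + 1) - 0.375) / (len(resid) + 0.25))
    sw_stat, sw_p = stats.shapiro(resid) if 3 <= len(resid) <= 5000 else (np.nan, np.nan)
    return {
        "fitted": fitted,
        "residuals": resid,
        "qq_sample": resid[order],
        "qq_theoretical": qq_theoretical,
        "shapiro_W": float(sw_stat),
        "shapiro_p": float(sw_p),
    }


def run_pipeline(
    observations: ObservationTable,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> tuple[RunManifest, dict]:
    """Run the full analysis on one observation table.

    For each performance response (sqrt Asat, log WUE): fit the full
    polynomial-interaction model once per alternative soil set (the
    collinearity screen decides the alternatives, canonically soil N vs
    soil C), simplify each by marginality-respecting backward elimination,
    pick the final model by AIC, and extract the type-II ANOVA, the
    trait-environment slope table, response surfaces for retained pairs,
    R2 and residual diagnostics.
    """
    config = config or RunConfig()
    t_start = time.time()
    timings: dict[str, float] = {}

    df, report = preprocess(observations, config)
    timings["preprocess"] = time.time() - t_start

    variety_levels = tuple(
        observations.variety_levels(config.reference_variety)
    )
    env_sets = alternative_env_sets(SOILS, report.flagged_pairs)
    Z_list = random_design(df)

    results: dict = {"preprocess": report.to_dict(), "responses": {}}
    for response in RESPONSES:
        t0 = time.time()
        col = response_column(response, config.transform_map.get(response, "identity"))
        fits, designs, traces, labels = [], [], [], []
        for envs in env_sets:
            spec = ModelSpec(
                response=col,
                traits=TRAITS,
                environments=tuple(envs),
                variety_levels=variety_levels,
                covariates=COVARIATES,
            )
            graph = build_term_graph(spec)
            trace, fit, design = backward_select(
                df, col, graph, Z_list,
                alpha=config.alpha, method=config.df_method,
                aic_likelihood=config.aic_likelihood,
            )
            fits.append(fit)
            designs.append(design)
            traces.append(trace)
            labels.append("+".join(envs))
        best, aic_table = compare_alternatives(fits, labels, config.aic_likelihood)
        fit, design, trace = fits[best], designs[best], traces[best]
        anova = type2_anova(fit, design, alpha=config.alpha, method=config.df_method)
        envs = env_sets[best]
        slopes = slope_table(fit, design, TRAITS, tuple(envs), method=config.df_method)
        surfaces = {}
        for _, row in slopes.iterrows():
            if row["retained"] and (row["trait"], row["env"]) not in surfaces:
                surfaces[(row["trait"], row["env"])] = response_surface(
                    fit, design, row["trait"], row["env"], None,
                    standardization_params=report.standardization_params,
                    transform_map=config.transform_map,
                    env_original_values=observations.df[row["env"]].to_numpy(),
                )
        r2m, r2c = r2_nakagawa(fit)
        diag = diagnostics(fit)
        results["responses"][response] = {
            "response_column": col,
            "alternatives": aic_table,
            "chosen": labels[best],
            "trace": trace,
            "fit": fit,
            "design": design,
            "anova": anova,
            "slopes": slopes,
            "surfaces": surfaces,
            "r2_marginal": r2m,
            "r2_conditional": r2c,
            "aic": information_criterion(fit, config.aic_likelihood),
            "shapiro_W": diag["shapiro_W"],
            "theta": fit.theta.tolist(),
        }
        timings[f"model_{response}"] = time.time() - t0

    manifest = RunManifest(
        config_hash=_hash(config.to_json()),
        input_hash=_hash(observations.df.to_csv(index=False)),
        version=__version__,
        seed=config.seed,
        timings=timings,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_outputs(results, manifest, outdir)
    return manifest, results


def _json_summary(results: dict) -> dict:
    """Machine-readable mirror of every number in the human tables."""
    out = {"preprocess": results["preprocess"], "responses": {}}
    for resp, r in results["responses"].items():
        anova = r["anova"].to_frame()
        out["responses"][resp] = {
            "response_column": r["response_column"],
            "chosen_soil_set": r["chosen"],
            "aic": r["aic"],
            "aic_alternatives": r["alternatives"].to_dict(orient="records"),
            "final_terms": [t.label for t in r["design"].graph.terms],
            "k_fixed": int(r["fit"].k_fixed),
            "beta": dict(zip(r["design"].labels(), map(float, r["fit"].beta))),
            "theta": r["theta"],
            "anova": anova.to_dict(orient="records"),
            "selection_trace": r["trace"].to_frame().to_dict(orient="records"),
            "slopes": r["slopes"].to_dict(orient="records"),
            "r2_marginal": r["r2_marginal"],
            "r2_conditional": r["r2_conditional"],
            "shapiro_W": r["shapiro_W"],
        }
    return out


def _write_outputs(results: dict, manifest: RunManifest, outdir: Path) -> None:
    summary = _json_summary(results)
    for resp, r in results["responses"].items():
        write_table(r["anova"].to_frame(), outdir / f"anova_{resp}.tsv")
        write_table(r["slopes"], outdir / f"slopes_{resp}.tsv")
        write_table(r["trace"].to_frame(), outdir / f"selection_{resp}.tsv")
        for (trait, env), grid in r["surfaces"].items():
            write_table(grid.to_frame(), outdir / f"surface_{resp}_{trait}_{env}.tsv")
        manifest.outputs[f"anova_{resp}"] = str(outdir / f"anova_{resp}.tsv")
    (outdir / "results.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest.outputs["results"] = str(outdir / "results.json")
    (outdir / "manifest.json").write_text(manifest.to_json())
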