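"""Synthetic nested field-study generator.

Emulates a participatory on-farm trial: 9 farms x 5 varieties (one plot per
variety per farm) x 3 subplots x 3 plants = 405 plants. Soil N and C are
correlated log-normal variables measured at subplot level, soil P varies
independently, climate covariates sit at farm level, and four morphological
traits vary at farm, subplot and plant level with mild pairwise
correlations (all |r| < 0.6). Performance (light-saturated photosynthesis
and water-use efficiency) is generated from the quadratic
trait x environment x variety fixed-effect surface plus nested random
intercepts with variance ordering farm > plot > subplot, then
back-transformed to raw units so the preprocessing path (derive, log/sqrt
transform, z-score) recovers the modeling scale exactly on complete tables.

Raw measurements are made mutually consistent: leaf dry mass = LMA * LA and
taproot dry mass = TTD * volume(RL, RD), so the pipeline's derived traits
reproduce the generative ones. Gas-exchange triplicates are drawn with
zero-sum deviations, so their average is the generative per-plant value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ObservationTable
from .model_design import VARIETY, Design, ModelSpec, TermGraph, build_term_graph, expand_design, random_design

__all__ = ["GeneratorConfig", "generate", "recovery_experiment", "default_beta_asat", "default_beta_wue"]

VARIETIES = ("H1", "H2", "OP1", "OP2", "OP3")
TRAITS = ("LA", "LMA", "PD", "TTD")
ENVS = ("SP", "SN")

# transformed-scale location/spread of the raw variables
_TRAIT_SCALE = {
    "LA": (12.0, 1.8),     # sqrt cm^2  -> LA ~ 100-260 cm^2
    "LMA": (-5.6, 0.25),   # log g cm^-2 -> ~ 0.004
    "PD": (2.3, 0.35),     # sqrt mm    -> ~ 4-8 mm
    "TTD": (-2.0, 0.30),   # log g cm^-3 -> ~ 0.14
}
# mild plant-level trait correlations (all below the 0.6 screen)
_TRAIT_CORR = np.array([
    [1.00, -0.20, 0.45, 0.10],
    [-0.20, 1.00, 0.00, 0.25],
    [0.45, 0.00, 1.00, 0.10],
    [0.10, 0.25, 0.10, 1.00],
])


def default_beta_asat() -> dict[str, float]:
    """Fixed effects for sqrt(Asat): a negative TTD x soil-P interaction and
    variety-dependent soil-P slopes, everything else null."""
    b = {
        "(Intercept)": 3.9,
        "TTD": -0.04,
        "SP": 0.06,
        "SP x TTD": -0.105,   # the trait x environment slope
        "variety[H2]": 0.05,
        "variety[OP1]": -0.03,
        "variety[OP2]": 0.02,
        "variety[OP3]": -0.06,
        "SP x variety[H2]": -0.10,
        "SP x variety[OP1]": -0.08,
        "SP x variety[OP2]": -0.16,
        "SP x variety[OP3]": -0.22,
    }
    return b


def default_beta_wue() -> dict[str, float]:
    """Fixed effects for log(WUE): petiole-diameter slopes along soil N that
    flip sign across varieties (reference H1 at -0.144, OP2 at +0.211)."""
    b = {
        "(Intercept)": 1.10,
        "LA": 0.01,
        "PD": 0.02,
        "SP": -0.02,
        "SN": 0.01,
        "SN^2": -0.03,
        "SP^2": 0.02,
        "PD x SN": -0.144,
        "PD x SN x variety[H2]": 0.084,   # slope -0.06
        "PD x SN x variety[OP1]": 0.234,  # slope +0.09
        "PD x SN x variety[OP2]": 0.355,  # slope +0.211
        "PD x SN x variety[OP3]": 0.114,  # slope -0.03
        "PD x variety[H2]": 0.05,
        "PD x variety[OP1]": -0.04,
        "PD x variety[OP2]": 0.08,
        "PD x variety[OP3]": -0.02,
        "SP x variety[H2]": -0.08,
        "SP x variety[OP1]": 0.05,
        "SP x variety[OP2]": 0.10,
        "SP x variety[OP3]": -0.05,
        "LA x SP": 0.02,
        "LA x SP x variety[H2]": 0.10,
        "LA x SP x variety[OP1]": -0.10,
        "LA x SP x variety[OP2]": 0.12,
        "LA x SP x variety[OP3]": -0.06,
    }
    return b


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic trial."""

    n_farms: int = 9
    n_varieties: int = 5
    n_subplots: int = 3
    n_plants: int = 3
    # variance components on the transformed response scale, ordered
    # farm > plot > subplot (the ordering the field study reports)
    theta_asat: tuple[float, float, float, float] = (0.30, 0.12, 0.06, 0.25)
    theta_wue: tuple[float, float, float, float] = (0.18, 0.07, 0.035, 0.035)
    beta_asat: dict[str, float] = field(default_factory=default_beta_asat)
    beta_wue: dict[str, float] = field(default_factory=default_beta_wue)
    soil_nc_correlation: float = 0.8
    temp_range: tuple[float, float] = (16.6, 20.5)    # degC, farm level
    precip_range: tuple[float, float] = (97.2, 237.9)  # mm, farm level
    missing_phys_count: int = 5
    la_outlier_count: int = 2
    la_outlier_factor: float = 6.0
    variety_trait_shift: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_farms, self.n_varieties, self.n_subplots, self.n_plants) < 1:
            raise ValueError("design counts must be >= 1")
        if not (-1.0 < self.soil_nc_correlation < 1.0):
            raise ValueError("soil_nc_correlation must be in (-1, 1)")

    @property
    def n_plants_total(self) -> int:
        return self.n_farms * self.n_varieties * self.n_subplots * self.n_plants


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _beta_vector(design: Design, beta_map: dict[str, float]) -> np.ndarray:
    labels = design.labels()
    unknown = set(beta_map) - set(labels)
    if unknown:
        raise ValueError(f"beta entries not in the term graph: {sorted(unknown)}")
    return np.array([beta_map.get(lab, 0.0) for lab in labels])


def generate(config: GeneratorConfig | None = None) -> tuple[ObservationTable, dict]:
    """Generate one synthetic observation table plus the generating truth.

    The truth record carries the fixed-effect vectors on the analysis scale
    (standardized predictors), the variance components, the analysis-ready
    frame before attrition, and the injected row indices.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    farms = [f"F{i+1}" for i in range(cfg.n_farms)]
    varieties = [VARIETIES[i] if i < len(VARIETIES) else f"V{i+1}" for i in range(cfg.n_varieties)]
    rows = [
        (f, v, f"S{s+1}", f"P{p+1}")
        for f in farms for v in varieties
        for s in range(cfg.n_subplots) for p in range(cfg.n_plants)
    ]
    df = pd.DataFrame(rows, columns=["farm_id", "variety_id", "subplot_id", "plant_id"])
    n = len(df)
    fi = df["farm_id"].map({f: i for i, f in enumerate(farms)}).to_numpy()
    plot_key = df["farm_id"] + ":" + df["variety_id"]
    pi, _ = pd.factorize(plot_key)
    sub_key = plot_key + ":" + df["subplot_id"]
    si, _ = pd.factorize(sub_key)

    # climate: farm level
    temp_f = rng.uniform(*cfg.temp_range, cfg.n_farms)
    precip_f = rng.uniform(*cfg.precip_range, cfg.n_farms)
    df["temp"] = temp_f[fi]
    df["precip"] = precip_f[fi]

    # soils: correlated log N / log C at farm and subplot level, log P apart
    rho = cfg.soil_nc_correlation
    cov2 = np.array([[1.0, rho], [rho, 1.0]])
    chol2 = np.linalg.cholesky(cov2)
    nsub = si.max() + 1
    nc_farm = (chol2 @ rng.standard_normal((2, cfg.n_farms))) * 0.15
    nc_sub = (chol2 @ rng.standard_normal((2, nsub))) * 0.15
    log_sn = 1.25 + nc_farm[0][fi] + nc_sub[0][si]
    log_sc = 3.40 + nc_farm[1][fi] + nc_sub[1][si]
    log_sp = 3.70 + 0.35 * rng.standard_normal(cfg.n_farms)[fi] + 0.20 * rng.standard_normal(nsub)[si]
    df["SN"], df["SC"], df["SP"] = np.exp(log_sn), np.exp(log_sc), np.exp(log_sp)

    # traits: farm + subplot + correlated plant-level variation, then shifted
    # to realistic transformed-scale locations
    cholT = np.linalg.cholesky(_TRAIT_CORR)
    plant_lat = rng.standard_normal((n, 4)) @ cholT.T
    farm_lat = 0.4 * rng.standard_normal((cfg.n_farms, 4))
    sub_lat = 0.2 * rng.standard_normal((nsub, 4))
    total_sd = np.sqrt(1.0 + 0.4 ** 2 + 0.2 ** 2)
    latent = (plant_lat + farm_lat[fi] + sub_lat[si]) / total_sd
    vmap = {v: i for i, v in enumerate(varieties)}
    for (trait, variety), shift in cfg.variety_trait_shift.items():
        j = TRAITS.index(trait)
        latent[:, j] += shift * (df["variety_id"] == variety).to_numpy()
    transformed = {}
    for j, trait in enumerate(TRAITS):
        mu, sd = _TRAIT_SCALE[trait]
        transformed[trait] = mu + sd * latent[:, j]
    LA = transformed["LA"] ** 2
    LMA = np.exp(transformed["LMA"])
    PD = transformed["PD"] ** 2
    TTD = np.exp(transformed["TTD"])
    df["LA"], df["PD"] = LA, PD
    df["leaf_dry_mass"] = LMA * LA
    df["RL"] = np.exp(rng.normal(np.log(15.0), 0.15, n))
    df["RD"] = np.exp(rng.normal(np.log(25.0), 0.20, n))  # mm
    rd_cm = df["RD"].to_numpy() / 10.0
    volume = np.pi / 3.0 * df["RL"].to_numpy() * (rd_cm ** 2 + 0.05 ** 2 + rd_cm * 0.05)
    df["taproot_dry_mass"] = TTD * volume

    # analysis-scale predictors: z-scores of the transformed values
    std = pd.DataFrame({
        "farm_id": df["farm_id"], "variety_id": df["variety_id"],
        "subplot_id": df["subplot_id"], "plant_id": df["plant_id"],
    })
    for trait in TRAITS:
        std[trait] = _zscore(transformed[trait])
    std["SP"] = _zscore(log_sp)
    std["SN"] = _zscore(log_sn)
    std["SC"] = _zscore(log_sc)
    std["temp"] = _zscore(df["temp"].to_numpy())
    std["precip"] = _zscore(df["precip"].to_numpy())

    spec = ModelSpec(
        response="", traits=TRAITS, environments=ENVS,
        variety_levels=tuple(varieties), covariates=("temp", "precip"),
    )
    graph = build_term_graph(spec)
    design = expand_design(std, graph, check_rank=False)
    Z_list = random_design(df)

    def draw_response(beta_map: dict[str, float], theta: tuple[float, ...]) -> np.ndarray:
        beta = _beta_vector(design, beta_map)
        y = design.X @ beta
        for Z, s2 in zip(Z_list, theta[:-1]):
            y = y + Z @ rng.normal(0.0, np.sqrt(s2), Z.shape[1])
        return y + rng.normal(0.0, np.sqrt(theta[-1]), n)

    y_asat = draw_response(cfg.beta_asat, cfg.theta_asat)
    y_wue = draw_response(cfg.beta_wue, cfg.theta_wue)
    std["sqrt_Asat"], std["log_WUE"] = y_asat, y_wue

    Asat = np.maximum(y_asat, 0.05) ** 2
    WUE = np.exp(y_wue)
    TR = Asat / WUE
    gs = TR * rng.normal(55.0, 3.0, n)

    def reps(target: np.ndarray, rel_sd: float = 0.02) -> np.ndarray:
        d1 = rng.normal(0.0, rel_sd * np.abs(target))
        d2 = rng.normal(0.0, rel_sd * np.abs(target))
        return np.column_stack([target + d1, target + d2, target - d1 - d2])

    for var, vals in (("Asat", Asat), ("gs", gs), ("TR", TR)):
        r3 = reps(vals)
        for i in (1, 2, 3):
            df[f"{var}_rep{i}"] = r3[:, i - 1]

    # attrition injection
    pick = rng.choice(n, size=cfg.missing_phys_count + cfg.la_outlier_count, replace=False)
    missing_rows = np.sort(pick[:cfg.missing_phys_count])
    outlier_rows = np.sort(pick[cfg.missing_phys_count:])
    for col in [f"{v}_rep{i}" for v in ("Asat", "gs", "TR") for i in (1, 2, 3)]:
        df.loc[missing_rows, col] = np.nan
    df.loc[outlier_rows, "LA"] *= cfg.la_outlier_factor
    df.loc[outlier_rows, "leaf_dry_mass"] *= cfg.la_outlier_factor  # LMA unchanged

    truth = {
        "seed": cfg.seed,
        "beta_asat": {lab: cfg.beta_asat.get(lab, 0.0) for lab in design.labels()},
        "beta_wue": {lab: cfg.beta_wue.get(lab, 0.0) for lab in design.labels()},
        "theta_asat": list(cfg.theta_asat),
        "theta_wue": list(cfg.theta_wue),
        "labels": design.labels(),
        "analysis_frame": std,
        "missing_rows": missing_rows.tolist(),
        "outlier_rows": outlier_rows.tolist(),
    }
    return ObservationTable(df), truth


def recovery_experiment(
    config: GeneratorConfig | None = None,
    n_reps: int = 100,
    base_seed: int = 1,
    response: str = "asat",
) -> dict:
    """Bias / coverage report for the full-model fit over simulated trials.

    Each replicate draws a complete table (no attrition), runs the actual
    preprocessing path, fits the full term graph by REML and records
    coefficient estimates, adjusted-SE confidence intervals (Satterthwaite
    df) and variance components. Deterministic given ``base_seed``.
    """
    from .lmm_engine import fit_reml, satterthwaite_ddf_all
    from .preprocess import preprocess
    from scipy import stats

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = config or GeneratorConfig()
    beta_map = cfg.beta_asat if response == "asat" else cfg.beta_wue
    theta_true = np.array(cfg.theta_asat if response == "asat" else cfg.theta_wue)
    col = "sqrt_Asat" if response == "asat" else "log_WUE"

    est = cover = None
    theta_est = []
    warm = None
    for rep in range(n_reps):
        rcfg = dataclasses.replace(
            cfg, seed=base_seed + rep, missing_phys_count=0, la_outlier_count=0
        )
        table, truth = generate(rcfg)
        df, _ = preprocess(table)
        spec = ModelSpec(
            response=col, traits=TRAITS, environments=ENVS,
            variety_levels=tuple(dict.fromkeys(table.df["variety_id"])),
            covariates=("temp", "precip"),
        )
        design = expand_design(df, build_term_graph(spec))
        Z_list = random_design(df)
        fit = fit_reml(design.X, Z_list, df[col].to_numpy(), compute_ml=False,
                       starts=[warm] if warm is not None else None)
        warm = np.maximum(fit.gamma, 1e-2)
        beta_true = _beta_vector(design, {k: v for k, v in beta_map.items()})
        if est is None:
            est = np.zeros((n_reps, design.k))
            cover = np.zeros((n_reps, design.k), dtype=bool)
            truth_beta = beta_true
        est[rep] = fit.beta
        se = np.sqrt(np.diag(fit.vcov_beta_adj))
        ddf = satterthwaite_ddf_all(fit)
        tq = stats.t.ppf(0.975, np.maximum(ddf, 1.0))
        cover[rep] = np.abs(fit.beta - beta_true) <= tq * se
        theta_est.append(fit.theta)
    theta_est = np.array(theta_est)
    return {
        "labels": design.labels(),
        "beta_true": truth_beta,
        "bias": est.mean(axis=0) - truth_beta,
        "rmse": np.sqrt(((est - truth_beta) ** 2).mean(axis=0)),
        "coverage": cover.mean(axis=0),
        "theta_true": theta_true,
        "theta_mean": theta_est.mean(axis=0),
        "theta_rel_bias": (theta_est.mean(axis=0) - theta_true) / theta_true,
        "n_reps": n_reps,
    }


def selection_experiment(
    n_reps: int = 200,
    base_seed: int = 1,
    effect_two_way: float = 0.3,
    effect_three_way: float = 0.3,
    alpha: float = 0.05,
    method: str = "satterthwaite",
) -> dict:
    """Retention rates of backward selection over seeded replicates.

    Simulates the full nested design with exactly one true trait x soil
    effect (SP x TTD) and one true trait x soil x variety effect
    (PD x SP x variety[OP2]), both of the given size in response-SD units
    per predictor SD, then runs marginality-respecting backward elimination
    from the quadratic-interaction graph on the traits (TTD, PD) and soil P.
    Reports how often each true term survives and how often free null terms
    (terms with no effect that no true term contains) are retained.
    """
    import dataclasses as _dc

    from .inference import backward_select
    from .model_design import Term, contains
    from .preprocess import preprocess

    beta = {
        "(Intercept)": 3.9,
        "SP x TTD": effect_two_way,
        "PD x SP x variety[OP2]": effect_three_way,
    }
    true_terms = {Term(["SP", "TTD"]), Term(["PD", "SP", VARIETY])}
    kept_two = kept_three = 0
    null_kept, null_possible = 0, 0
    for rep in range(n_reps):
        cfg = GeneratorConfig(seed=base_seed + rep, missing_phys_count=0,
                              la_outlier_count=0)
        table, _ = generate(cfg)
        df, _ = preprocess(table)
        spec = ModelSpec(
            response="sqrt_Asat", traits=("TTD", "PD"), environments=("SP",),
            variety_levels=tuple(dict.fromkeys(table.df["variety_id"])),
        )
        graph = build_term_graph(spec)
        design = expand_design(df, graph)
        beta_vec = _beta_vector(design, beta)
        Z_list = random_design(df)
        rng = np.random.default_rng(10_000_019 + base_seed + rep)
        y = design.X @ beta_vec
        for Z, s2 in zip(Z_list, (0.30, 0.12, 0.06)):
            y = y + Z @ rng.normal(0.0, np.sqrt(s2), Z.shape[1])
        y = y + rng.normal(0.0, np.sqrt(0.25), len(df))
        df = df.assign(sqrt_Asat=y)
        trace, _, _ = backward_select(df, "sqrt_Asat", graph, Z_list,
                                      alpha=alpha, method=method)
        final = set(trace.final_graph.terms)
        kept_two += Term(["SP", "TTD"]) in final
        kept_three += Term(["PD", "SP", VARIETY]) in final
        for t in graph.terms:
            if t.is_intercept or t in true_terms:
                continue
            if any(contains(t, tt) for tt in true_terms):
                continue  # forced by marginality when the true term is kept
            null_possible += 1
            null_kept += t in final
    return {
        "n_reps": n_reps,
        "retention_two_way": kept_two / n_reps,
        "retention_three_way": kept_three / n_reps,
        "null_retention": null_kept / max(null_possible, 1),
    }
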