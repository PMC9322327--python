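"""Environment-dependent trait-performance slopes, surfaces and R2.

The namesake quantity is the trait-environment relationship

    phi(E) = b_T + b_TxE * E

for one trait T and one environment E: the slope of the trait's effect on
performance as a linear function of the (standardized) environment. Under
treatment coding the reference variety's phi is assembled from the base
coefficients; other varieties add their interaction offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm_engine import FittedLMM, f_test
from .model_design import Design, DesignError, Term, VARIETY

__all__ = [
    "TraitEnvSlope",
    "SurfaceGrid",
    "phi_slope",
    "slope_table",
    "response_surface",
    "stationary_point",
    "r2_nakagawa",
    "plot_surface_panel",
]


@dataclass
class TraitEnvSlope:
    """phi(E) = intercept + slope * E for one (trait, environment, variety)."""

    trait: str
    env: str
    variety: str | None
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    ci_slope: tuple[float, float]
    p_slope: float
    retained: bool  # False when the trait x env interaction was eliminated

    def phi_at(self, E) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(E, dtype=float)


def _combo(fit: FittedLMM, design: Design, entries: list[tuple[Term, str | None]]):
    """Estimate, adjusted SE and contrast vector for a sum of coefficients.

    Terms absent from the model contribute zero.
    """
    c = np.zeros(design.k)
    present = False
    for term, level in entries:
        if term in design.graph.terms:
            c[design.column_index(term, level)] = 1.0
            present = True
    est = float(c @ fit.beta)
    se = float(np.sqrt(c @ fit.vcov_beta_adj @ c)) if present else 0.0
    return est, se, c, present


def phi_slope(
    fit: FittedLMM,
    design: Design,
    trait: str,
    env: str,
    variety: str | None = None,
    method: str = "kenward_roger",
    level: float = 0.95,
) -> TraitEnvSlope:
    """Assemble phi for one trait-environment pair (and variety).

    The intercept is the trait's linear coefficient, the slope the
    trait x environment coefficient, each plus the given variety's offset
    when those interactions are in the model. Standard errors are
    linear-combination variances under the small-sample-adjusted covariance.
    """
    graph = design.graph
    if Term([trait]) not in graph.terms:
        raise DesignError(f"trait {trait!r} not in model")
    ref = graph.variety_levels[0] if graph.g else None
    is_ref = variety is None or (ref is not None and variety == ref)

    ents_int = [(Term([trait]), None)]
    ents_slope = [(Term([trait, env]), None)]
    if not is_ref:
        ents_int.append((Term([trait, VARIETY]), variety))
        ents_slope.append((Term([trait, env, VARIETY]), variety))
    intercept, se_i, _, _ = _combo(fit, design, ents_int)
    slope, se_s, c, present = _combo(fit, design, ents_slope)

    if present:
        res = f_test(fit, c[None, :], method=method)
        tq = stats.t.ppf(0.5 + level / 2.0, res.ddf) if np.isfinite(res.ddf) else stats.norm.ppf(0.5 + level / 2.0)
        ci = (slope - tq * se_s, slope + tq * se_s)
        p = res.p
    else:
        ci, p = (0.0, 0.0), 1.0
    return TraitEnvSlope(
        trait=trait, env=env, variety=variety,
        intercept=intercept, slope=slope,
        se_intercept=se_i, se_slope=se_s,
        ci_slope=ci, p_slope=p, retained=present,
    )


def slope_table(
    fit: FittedLMM,
    design: Design,
    traits: tuple[str, ...],
    envs: tuple[str, ...],
    method: str = "kenward_roger",
) -> pd.DataFrame:
    """All trait x environment phi lines, one row per variety.

    Pairs whose interaction was eliminated report slope 0 with
    ``retained=False``; models without variety interactions yield identical
    slopes across varieties.
    """
    graph = design.graph
    varieties = list(graph.variety_levels) or [None]
    recs = []
    for trait in traits:
        if Term([trait]) not in graph.terms:
            continue
        for env in envs:
            for v in varieties:
                s = phi_slope(fit, design, trait, env, v, method=method)
                recs.append({
                    "trait": trait, "env": env, "variety": v,
                    "intercept": s.intercept, "slope": s.slope,
                    "se_intercept": s.se_intercept, "se_slope": s.se_slope,
                    "ci_low": s.ci_slope[0], "ci_high": s.ci_slope[1],
                    "p": s.p_slope, "retained": s.retained,
                })
    return pd.DataFrame(recs)


@dataclass
class SurfaceGrid:
    """Predicted response over a (trait, environment) grid for one variety."""

    trait: str
    env: str
    variety: str | None
    trait_grid: np.ndarray          # standardized units
    env_grid: np.ndarray
    predicted: np.ndarray           # shape (len(trait_grid), len(env_grid))
    stationary: tuple[float, float] | None
    stationary_class: str
    trait_grid_original: np.ndarray | None = None
    env_grid_original: np.ndarray | None = None
    env_original_range: tuple[float, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        T, E = np.meshgrid(self.trait_grid, self.env_grid, indexing="ij")
        out = pd.DataFrame({
            "trait_value": T.ravel(), "env_value": E.ravel(),
            "predicted": self.predicted.ravel(),
        })
        out["trait"], out["env"], out["variety"] = self.trait, self.env, self.variety
        return out


def _poly_coeffs(fit: FittedLMM, design: Design, trait: str, env: str,
                 variety: str | None) -> tuple[float, ...]:
    """(b0, b1..b5) of the quadratic surface for one variety, absent terms 0."""
    graph = design.graph
    ref = graph.variety_levels[0] if graph.g else None
    is_ref = variety is None or variety == ref

    def coef(term: Term, level=None) -> float:
        if term in graph.terms:
            return float(fit.beta[design.column_index(term, level)])
        return 0.0

    b0 = coef(Term([]))
    b1 = coef(Term([trait]))
    b2 = coef(Term([trait, trait]))
    b3 = coef(Term([env]))
    b4 = coef(Term([env, env]))
    b5 = coef(Term([trait, env]))
    if not is_ref:
        b0 += coef(Term([VARIETY]), variety)
        b1 += coef(Term([trait, VARIETY]), variety)
        b3 += coef(Term([env, VARIETY]), variety)
        b5 += coef(Term([trait, env, VARIETY]), variety)
    return b0, b1, b2, b3, b4, b5


def response_surface(
    fit: FittedLMM,
    design: Design,
    trait: str,
    env: str,
    variety: str | None = None,
    grid_sd: float = 2.0,
    n_grid: int = 41,
    standardization_params: dict[str, tuple[float, float]] | None = None,
    transform_map: dict[str, str] | None = None,
    env_original_values: np.ndarray | None = None,
) -> SurfaceGrid:
    """Predicted response over a +/- ``grid_sd`` SD grid, others held at 0.

    Non-focal predictors and covariates sit at their standardized mean (0),
    so only the focal quadratic surface and the variety offsets contribute.
    Axis values in original units are annotated when standardization
    parameters are supplied.
    """
    b0, b1, b2, b3, b4, b5 = _poly_coeffs(fit, design, trait, env, variety)
    tg = np.linspace(-grid_sd, grid_sd, n_grid)
    eg = np.linspace(-grid_sd, grid_sd, n_grid)
    T, E = np.meshgrid(tg, eg, indexing="ij")
    pred = b0 + b1 * T + b2 * T ** 2 + b3 * E + b4 * E ** 2 + b5 * T * E
    st, cls = stationary_point((b1, b2, b3, b4, b5))

    def back(var, grid):
        if not standardization_params or var not in standardization_params:
            return None
        mu, sd = standardization_params[var]
        t = mu + sd * grid
        tr = (transform_map or {}).get(var, "identity")
        if tr == "log":
            return np.exp(t)
        if tr == "sqrt":
            return t ** 2
        return t

    rng_orig = None
    if env_original_values is not None:
        vals = np.asarray(env_original_values, dtype=float)
        rng_orig = (float(np.nanmin(vals)), float(np.nanmax(vals)))
    return SurfaceGrid(
        trait=trait, env=env, variety=variety,
        trait_grid=tg, env_grid=eg, predicted=pred,
        stationary=st, stationary_class=cls,
        trait_grid_original=back(trait, tg),
        env_grid_original=back(env, eg),
        env_original_range=rng_orig,
    )


def stationary_point(beta_quintet) -> tuple[tuple[float, float] | None, str]:
    """Stationary point and class of the quadratic surface.

    Solves grad = 0 for b1 + 2 b2 T + b5 E and b3 + 2 b4 E + b5 T; the class
    follows the eigenvalue signs of the Hessian [[2 b2, b5], [b5, 2 b4]]
    (maximum, minimum, saddle) with singular Hessians reported degenerate
    along the flat eigendirection.
    """
    b1, b2, b3, b4, b5 = (float(b) for b in beta_quintet)
    H = np.array([[2.0 * b2, b5], [b5, 2.0 * b4]])
    g = np.array([b1, b3])
    scale = max(np.abs(H).max(), 1.0)
    if abs(np.linalg.det(H)) < 1e-12 * scale ** 2:
        w, v = np.linalg.eigh(H)
        flat = v[:, int(np.argmin(np.abs(w)))]
        return None, f"degenerate (flat along trait={flat[0]:+.3f}, env={flat[1]:+.3f})"
    pt = np.linalg.solve(H, -g)
    w = np.linalg.eigvalsh(H)
    if w[0] > 0 and w[1] > 0:
        cls = "minimum"
    elif w[0] < 0 and w[1] < 0:
        cls = "maximum"
    else:
        cls = "saddle"
    return (float(pt[0]), float(pt[1])), cls


def plot_surface_panel(
    grid: SurfaceGrid,
    slope: TraitEnvSlope | None = None,
    path: str | None = None,
):
    """Render the response surface plus the phi(E) line (optional output file).

    Mirrors the usual two-panel layout: left, the predicted surface over the
    standardized trait/environment grid; right, the trait-environment
    relationship with the environment's original range shaded when known.
    Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    T, E = np.meshgrid(grid.trait_grid, grid.env_grid, indexing="ij")
    cs = axes[0].contourf(T, E, grid.predicted, levels=20, cmap="viridis")
    fig.colorbar(cs, ax=axes[0], label="predicted response")
    if grid.stationary is not None:
        axes[0].plot(*grid.stationary, "r+", markersize=10)
    axes[0].set_xlabel(f"{grid.trait} (SD units)")
    axes[0].set_ylabel(f"{grid.env} (SD units)")
    axes[0].set_title(f"surface ({grid.stationary_class})")
    if slope is not None:
        e = grid.env_grid
        axes[1].plot(e, slope.phi_at(e), "k-")
        axes[1].axhline(0.0, color="gray", lw=0.5)
        axes[1].set_xlabel(f"{grid.env} (SD units)")
        axes[1].set_ylabel(f"effect of {grid.trait}")
        axes[1].set_title(
            f"phi(E) = {slope.intercept:+.3f} {slope.slope:+.3f} E"
            + ("" if slope.variety is None else f"  [{slope.variety}]")
        )
    if grid.env_original_range is not None and grid.env_grid_original is not None:
        lo, hi = grid.env_original_range
        inside = (grid.env_grid_original >= lo) & (grid.env_grid_original <= hi)
        if inside.any():
            axes[1].axvspan(grid.env_grid[inside].min(), grid.env_grid[inside].max(),
                            color="tan", alpha=0.25, label="observed range")
            axes[1].legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def r2_nakagawa(fit: FittedLMM) -> tuple[float, float]:
    """Marginal and conditional R2 for a Gaussian identity-link mixed model.

    The fixed-effect variance is the population variance of the linear
    predictor X beta over the data; for Gaussian identity models the
    delta-method, lognormal and trigamma variants of the observation-level
    variance all collapse to the residual component, so

        R2_m = s2_f / (s2_f + sum(s2_random) + s2_e)
        R2_c = (s2_f + sum(s2_random)) / (s2_f + sum(s2_random) + s2_e).
    """
    s2_f = float(np.var(fit.fitted_fixed))  # population variance
    s2_rand = float(np.sum(fit.theta[:-1]))
    s2_e = float(fit.theta[-1])
    tot = s2_f + s2_rand + s2_e
    return s2_f / tot, (s2_f + s2_rand) / tot
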