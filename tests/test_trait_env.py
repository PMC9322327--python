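import numpy as np
import pandas as pd
import pytest

from traitenv.lmm_engine import fit_reml
from traitenv.model_design import (
    DesignError,
    ModelSpec,
    Term,
    build_term_graph,
    expand_design,
    random_design,
)
from traitenv.trait_env import (
    phi_slope,
    r2_nakagawa,
    response_surface,
    slope_table,
    stationary_point,
)


def _exact_fit(df, graph, y):
    design = expand_design(df, graph)
    fit = fit_reml(design.X, [], y)
    return fit, design


def test_phi_is_constant_when_no_interaction():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({"T": rng.normal(size=50)})
    y = 3.0 + 2.0 * df["T"].to_numpy() + rng.normal(0, 1e-9, 50)
    graph = build_term_graph(ModelSpec(response="y", traits=("T",),
                                       include_quadratics=False))
    fit, design = _exact_fit(df, graph, y)
    s = phi_slope(fit, design, "T", "E")
    assert s.intercept == pytest.approx(2.0, abs=1e-6)
    assert s.slope == 0.0 and not s.retained
    np.testing.assert_allclose(s.phi_at([-3.0, 0.0, 7.0]), 2.0)


def test_phi_line_crosses_zero_where_algebra_says():
    rng = np.random.default_rng(4)
    df = pd.DataFrame({"T": rng.normal(size=80), "E": rng.normal(size=80)})
    y = 1.0 - 1.0 * df["T"] + 0.5 * df["T"] * df["E"] + rng.normal(0, 1e-9, 80)
    graph = build_term_graph(ModelSpec(response="y", traits=("T",),
                                       environments=("E",), include_quadratics=False))
    fit, design = _exact_fit(df, graph, y.to_numpy())
    s = phi_slope(fit, design, "T", "E")
    assert s.phi_at(2.0) == pytest.approx(0.0, abs=1e-6)
    assert s.slope == pytest.approx(0.5, abs=1e-6)
    with pytest.raises(DesignError):
        phi_slope(fit, design, "missing_trait", "E")


def test_phi_equals_finite_difference_of_the_predicted_surface(analysis_frame):
    df, _ = analysis_frame
    graph = build_term_graph(ModelSpec(
        response="sqrt_Asat", traits=("LA", "LMA", "PD", "TTD"),
        environments=("SP", "SN"), variety_levels=("H1", "H2", "OP1", "OP2", "OP3"),
        covariates=("temp", "precip"),
    ))
    design = expand_design(df, graph)
    Z = random_design(df)
    fit = fit_reml(design.X, Z, df["sqrt_Asat"].to_numpy())
    from traitenv.trait_env import _poly_coeffs

    h = 1e-4
    for variety in ("H1", "OP2"):
        for env_val in (-1.3, 0.0, 2.0):
            s = phi_slope(fit, design, "TTD", "SP", variety)
            b0, b1, b2, b3, b4, b5 = _poly_coeffs(fit, design, "TTD", "SP", variety)

            def pred(T, E):
                return b0 + b1 * T + b2 * T ** 2 + b3 * E + b4 * E ** 2 + b5 * T * E

            fd = (pred(h, env_val) - pred(-h, env_val)) / (2 * h)
            assert abs(s.phi_at(env_val) - fd) < 1e-8


def test_slope_table_enumerates_all_pairs_per_variety(analysis_frame):
    df, _ = analysis_frame
    graph = build_term_graph(ModelSpec(
        response="sqrt_Asat", traits=("LA", "LMA", "PD", "TTD"),
        environments=("SP", "SN", "SC"), variety_levels=("H1", "H2", "OP1", "OP2", "OP3"),
    ))
    design = expand_design(df, graph)
    fit = fit_reml(design.X, random_design(df), df["sqrt_Asat"].to_numpy())
    table = slope_table(fit, design, ("LA", "LMA", "PD", "TTD"), ("SP", "SN", "SC"),
                        method="satterthwaite")
    assert len(table) == 4 * 3 * 5  # 12 trait-environment pairs x 5 varieties
    assert set(zip(table.trait, table.env)) == {
        (t, e) for t in ("LA", "LMA", "PD", "TTD") for e in ("SP", "SN", "SC")
    }


def test_eliminated_pairs_report_zero_slope_and_shared_slopes_without_three_way():
    rng = np.random.default_rng(9)
    n = 240
    df = pd.DataFrame({
        "variety_id": np.tile(["V1", "V2"], n // 2),
        "T": rng.normal(size=n), "E": rng.normal(size=n),
    })
    y = 1 + 0.5 * df["T"] + 0.4 * df["T"] * df["E"] + rng.normal(0, 0.1, n)
    graph = build_term_graph(ModelSpec(
        response="y", traits=("T",), environments=("E",),
        variety_levels=("V1", "V2"), include_quadratics=False, include_three_way=False,
    ))
    design = expand_design(df, graph)
    fit = fit_reml(design.X, [], y.to_numpy())
    table = slope_table(fit, design, ("T",), ("E", "E2_not_in_model"))
    by_pair = table.groupby("env")
    assert by_pair.get_group("E")["retained"].all()
    slopes = by_pair.get_group("E")["slope"]
    assert slopes.nunique() == 1  # no three-way: identical across varieties
    gone = by_pair.get_group("E2_not_in_model")
    assert (gone["slope"] == 0).all() and (~gone["retained"]).all()


@pytest.mark.parametrize(
    "quintet, expected_point, expected_class",
    [
        ((0.0, -1.0, 0.0, -1.0, 0.0), (0.0, 0.0), "maximum"),
        ((0.0, -1.0, 0.0, 1.0, 0.0), (0.0, 0.0), "saddle"),
        ((0.0, 1.0, 0.0, 1.0, 0.0), (0.0, 0.0), "minimum"),
        ((1.0, -1.0, 1.0, -1.0, 1.0), (1.0, 1.0), "maximum"),
    ],
)
def test_stationary_point_solves_the_gradient_system(quintet, expected_point, expected_class):
    point, cls = stationary_point(quintet)
    assert cls == expected_class
    np.testing.assert_allclose(point, expected_point, atol=1e-12)


def test_singular_hessian_is_degenerate():
    point, cls = stationary_point((0.5, 0.0, 0.2, 0.0, 0.0))
    assert point is None and cls.startswith("degenerate")


def test_flat_surface_and_polynomial_oracle():
    rng = np.random.default_rng(14)
    df = pd.DataFrame({"T": rng.normal(size=60), "E": rng.normal(size=60)})
    graph = build_term_graph(ModelSpec(response="y", traits=("T",), environments=("E",)))
    # flat: only the intercept is nonzero
    y_flat = np.full(60, 2.5)
    fit, design = _exact_fit(df, graph, y_flat)
    grid = response_surface(fit, design, "T", "E")
    np.testing.assert_allclose(grid.predicted, 2.5, atol=1e-8)
    # general quadratic: surface equals direct polynomial evaluation
    b = dict(b0=0.3, b1=-0.7, b2=0.2, b3=0.4, b4=-0.1, b5=0.6)
    y = (b["b0"] + b["b1"] * df["T"] + b["b2"] * df["T"] ** 2 + b["b3"] * df["E"]
         + b["b4"] * df["E"] ** 2 + b["b5"] * df["T"] * df["E"]).to_numpy()
    fit, design = _exact_fit(df, graph, y)
    grid = response_surface(fit, design, "T", "E", grid_sd=2.0, n_grid=11)
    rng2 = np.random.default_rng(1)
    for _ in range(5):
        i, j = rng2.integers(0, 11, 2)
        T, E = grid.trait_grid[i], grid.env_grid[j]
        direct = (b["b0"] + b["b1"] * T + b["b2"] * T ** 2 + b["b3"] * E
                  + b["b4"] * E ** 2 + b["b5"] * T * E)
        assert grid.predicted[i, j] == pytest.approx(direct, abs=1e-8)


def test_ruled_saddle_peaks_in_the_low_trait_high_env_corner():
    # no quadratic curvature, negative interaction: a ruled saddle whose
    # maximum over the grid corners sits at (low T, high E)
    rng = np.random.default_rng(15)
    df = pd.DataFrame({"T": rng.normal(size=80), "E": rng.normal(size=80)})
    y = (1.0 - 0.4 * df["T"] * df["E"]).to_numpy()
    graph = build_term_graph(ModelSpec(response="y", traits=("T",), environments=("E",)))
    fit, design = _exact_fit(df, graph, y)
    grid = response_surface(fit, design, "T", "E")
    assert grid.stationary_class == "saddle"
    corners = {(i, j): grid.predicted[i, j] for i in (0, -1) for j in (0, -1)}
    best = max(corners, key=corners.get)
    assert best in {(0, -1), (-1, 0)}  # low-T/high-E (or mirrored) corners
    assert grid.predicted[0, -1] == pytest.approx(grid.predicted[-1, 0], abs=1e-9)
    assert max(corners.values()) == pytest.approx(grid.predicted[0, -1], abs=1e-9)


def test_phi_se_matches_parametric_bootstrap():
    rng = np.random.default_rng(19)
    rows = [(f"F{f}", "V1", f"S{s}", f"P{i}")
            for f in range(9) for s in range(3) for i in range(3)]
    df = pd.DataFrame(rows, columns=["farm_id", "variety_id", "subplot_id", "plant_id"])
    n = len(df)
    df["T"] = rng.normal(size=n)
    df["E"] = rng.normal(size=n)
    graph = build_term_graph(ModelSpec(response="y", traits=("T",),
                                       environments=("E",), include_quadratics=False))
    design = expand_design(df, graph)
    Zf, _, Zs = random_design(df)
    Z = [Zf, Zs]
    beta_true = np.array([1.0, 0.4, 0.2, -0.3])
    theta = (0.4, 0.2, 0.5)

    def draw(r):
        return (design.X @ beta_true + Zf @ r.normal(0, np.sqrt(theta[0]), 9)
                + Zs @ r.normal(0, np.sqrt(theta[1]), 27)
                + r.normal(0, np.sqrt(theta[2]), n))

    fit = fit_reml(design.X, Z, draw(np.random.default_rng(100)))
    s = phi_slope(fit, design, "T", "E")

    # parametric bootstrap from the fitted model
    def draw_fitted(r):
        return (design.X @ fit.beta + Zf @ r.normal(0, np.sqrt(fit.theta[0]), 9)
                + Zs @ r.normal(0, np.sqrt(fit.theta[1]), 27)
                + r.normal(0, np.sqrt(fit.theta[2]), n))

    boots = []
    from traitenv.lmm_engine import _Problem
    pr = _Problem(design.X, Z, draw(np.random.default_rng(0)))
    j = design.column_index(Term(["E", "T"]))
    warm = np.maximum(fit.gamma, 0.05)
    for b in range(1000):
        pr.update_y(draw_fitted(np.random.default_rng(1000 + b)))
        bfit = fit_reml(None, Z, None, problem=pr, compute_ml=False, starts=[warm])
        boots.append(bfit.beta[j])
    assert s.se_slope == pytest.approx(np.std(boots, ddof=1), rel=0.10)


def test_r2_nakagawa_identities_and_closed_form():
    rng = np.random.default_rng(20)
    # no random effects: marginal equals conditional
    n = 200
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ [1.0, 0.8] + rng.normal(size=n)
    fit = fit_reml(X, [], y)
    r2m, r2c = r2_nakagawa(fit)
    assert r2m == pytest.approx(r2c)
    assert 0 < r2m <= 1
    # intercept-only fixed part: marginal R2 is zero
    groups = np.repeat(np.arange(20), 10)
    Z = np.zeros((n, 20))
    Z[np.arange(n), groups] = 1.0
    y2 = Z @ rng.normal(0, 1.0, 20) + rng.normal(0, 1.0, n)
    fit2 = fit_reml(np.ones((n, 1)), [Z], y2)
    r2m2, r2c2 = r2_nakagawa(fit2)
    assert r2m2 == pytest.approx(0.0, abs=1e-12)
    assert 0 <= r2m2 <= r2c2 <= 1


def test_surface_panel_renders_to_file(tmp_path):
    rng = np.random.default_rng(2)
    df = pd.DataFrame({"T": rng.normal(size=90), "E": rng.normal(size=90)})
    y = (1 - 0.3 * df["T"] * df["E"]).to_numpy() + rng.normal(0, 0.3, 90)
    graph = build_term_graph(ModelSpec(response="y", traits=("T",), environments=("E",)))
    design = expand_design(df, graph)
    fit = fit_reml(design.X, [], y)
    from traitenv.trait_env import plot_surface_panel

    grid = response_surface(fit, design, "T", "E",
                            standardization_params={"E": (3.0, 0.4), "T": (0.0, 1.0)},
                            transform_map={"E": "log"},
                            env_original_values=np.exp(rng.normal(3, 0.4, 90)))
    s = phi_slope(fit, design, "T", "E")
    out = tmp_path / "panel.png"
    plot_surface_panel(grid, s, str(out))
    assert out.stat().st_size > 1000
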