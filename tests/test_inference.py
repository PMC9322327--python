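import numpy as np
import pandas as pd
import pytest

from traitenv.inference import (
    backward_select,
    compare_alternatives,
    trait_by_variety_models,
    type2_anova,
    type2_contrast,
    variety_slope_contrasts,
)
from traitenv.lmm_engine import fit_reml, information_criterion
from traitenv.model_design import (
    DesignError,
    ModelSpec,
    Term,
    build_term_graph,
    expand_design,
    random_design,
)


def _ols_type1_ss(X_blocks, y):
    """Sequential sums of squares by model comparison (independent oracle)."""
    ss = []
    rss_prev = float(np.sum((y - y.mean()) ** 2))
    X = np.ones((len(y), 1))
    for block in X_blocks:
        X = np.column_stack([X, block])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(resid @ resid)
        ss.append(rss_prev - rss)
        rss_prev = rss
    return ss


def test_type2_equals_type1_on_balanced_orthogonal_design():
    # balanced 2x2 with interaction, 8 replicates per cell
    a = np.repeat([0, 1], 32)
    b = np.tile(np.repeat([0, 1], 16), 2)
    rng = np.random.default_rng(23)
    y = 1.0 + 0.8 * a + 0.5 * b + 0.4 * a * b + rng.normal(0, 1, 64)
    df = pd.DataFrame({"A": a - a.mean(), "B": b - b.mean()})
    graph = build_term_graph(ModelSpec(response="y", traits=("A",),
                                       environments=("B",), include_quadratics=False))
    design = expand_design(df, graph)
    fit = fit_reml(design.X, [], y)
    table = type2_anova(fit, design, method="residual")
    ss1 = _ols_type1_ss(
        [design.X[:, design.column_index(Term(["A"]))],
         design.X[:, design.column_index(Term(["B"]))],
         design.X[:, design.column_index(Term(["A", "B"]))]],
        y,
    )
    np.testing.assert_allclose(
        table.rows.loc[["A", "B", "A x B"], "sum_sq"], ss1, rtol=1e-8
    )


def test_type2_matches_model_comparison_on_unbalanced_ols():
    # with correlated predictors, type-II SS for t = RSS(no t, no containing) - RSS(+t)
    rng = np.random.default_rng(29)
    n = 120
    A = rng.normal(size=n)
    B = 0.5 * A + rng.normal(size=n)
    y = 1 + 0.5 * A + 0.3 * B + 0.2 * A * B + rng.normal(size=n)
    df = pd.DataFrame({"A": A, "B": B})
    graph = build_term_graph(ModelSpec(response="y", traits=("A",),
                                       environments=("B",), include_quadratics=False))
    design = expand_design(df, graph)
    fit = fit_reml(design.X, [], y)
    table = type2_anova(fit, design, method="residual")

    def rss(cols):
        Xs = design.X[:, cols]
        return float(np.sum((y - Xs @ np.linalg.lstsq(Xs, y, rcond=None)[0]) ** 2))

    iA = design.column_index(Term(["A"]))
    iB = design.column_index(Term(["B"]))
    iAB = design.column_index(Term(["A", "B"]))
    # A is adjusted for {1, B}, ignoring the containing A x B
    ss_A = rss([0, iB]) - rss([0, iB, iA])
    ss_B = rss([0, iA]) - rss([0, iA, iB])
    ss_AB = rss([0, iA, iB]) - rss([0, iA, iB, iAB])
    assert table.rows.loc["A", "sum_sq"] == pytest.approx(ss_A, rel=1e-8)
    assert table.rows.loc["B", "sum_sq"] == pytest.approx(ss_B, rel=1e-8)
    assert table.rows.loc["A x B", "sum_sq"] == pytest.approx(ss_AB, rel=1e-8)


def test_single_predictor_table_reduces_to_overall_regression_f():
    rng = np.random.default_rng(31)
    n = 40
    df = pd.DataFrame({"T": rng.normal(size=n)})
    y = 0.5 * df["T"].to_numpy() + rng.normal(size=n)
    graph = build_term_graph(ModelSpec(response="y", traits=("T",),
                                       include_quadratics=False))
    design = expand_design(df, graph)
    fit = fit_reml(design.X, [], y)
    table = type2_anova(fit, design, method="residual")
    assert len(table.rows) == 1
    beta = np.linalg.lstsq(design.X, y, rcond=None)[0]
    rss = np.sum((y - design.X @ beta) ** 2)
    tss = np.sum((y - y.mean()) ** 2)
    assert table.rows["F"].iloc[0] == pytest.approx((tss - rss) / (rss / (n - 2)), rel=1e-8)


@pytest.fixture(scope="module")
def selection_setup():
    """Synthetic trial with known sqrt(Asat) structure, preprocessed."""
    from traitenv import GeneratorConfig, generate, preprocess

    table, truth = generate(GeneratorConfig(seed=77))
    df, _ = preprocess(table)
    spec = ModelSpec(
        response="sqrt_Asat", traits=("LA", "LMA", "PD", "TTD"),
        environments=("SP", "SN"), variety_levels=("H1", "H2", "OP1", "OP2", "OP3"),
        covariates=("temp", "precip"),
    )
    graph = build_term_graph(spec)
    return df, graph, random_design(df)


def test_backward_selection_invariants(selection_setup):
    df, graph, Z = selection_setup
    trace, fit, design = backward_select(df, "sqrt_Asat", graph, Z,
                                         method="satterthwaite")
    final = trace.final_graph
    # dropped terms were removable when dropped and p exceeded alpha
    assert all(p > 0.05 for _, _, p, _ in trace.steps)
    # marginality: no retained term contains a dropped one at the end
    from traitenv.model_design import contains
    for t in final.terms:
        for other in final.terms:
            if t != other and contains(t, other):
                assert t in final.terms  # contained terms are present
    # every removable term in the final model is significant
    table = type2_anova(fit, design, method="satterthwaite", terms=final.removable())
    assert (table.rows["p"] <= 0.05).all()
    # replaying the trace reproduces the final model bit-for-bit
    g = graph
    for _, label, _, _ in trace.steps:
        term = next(t for t in g.terms if t.label == label)
        g = g.drop(term)
    design2 = expand_design(df, g)
    refit = fit_reml(design2.X, Z, df["sqrt_Asat"].to_numpy())
    np.testing.assert_array_equal(refit.beta, fit.beta)


def test_variety_main_effect_shielded_while_interactions_present(selection_setup):
    _, graph, _ = selection_setup
    removable = graph.removable()
    assert Term(["variety"]) not in removable
    assert all(not t.is_intercept for t in removable)


def test_selection_keeps_everything_when_all_terms_matter():
    rng = np.random.default_rng(37)
    n = 400
    df = pd.DataFrame({"T": rng.normal(size=n), "E": rng.normal(size=n)})
    y = 1 + 1.0 * df["T"] + 0.8 * df["E"] + 0.9 * df["T"] * df["E"] + rng.normal(0, 0.3, n)
    graph = build_term_graph(ModelSpec(response="y", traits=("T",),
                                       environments=("E",), include_quadratics=False))
    df["y"] = y
    trace, fit, design = backward_select(df, "y", graph, [], method="residual")
    assert trace.steps == []
    assert len(trace.final_graph.terms) == len(graph.terms)


def test_aic_comparison_semantics(selection_setup):
    df, graph, Z = selection_setup
    spec_small = ModelSpec(response="sqrt_Asat", traits=("TTD",),
                           environments=("SP",),
                           variety_levels=("H1", "H2", "OP1", "OP2", "OP3"))
    d1 = expand_design(df, build_term_graph(spec_small))
    d2 = expand_design(df, graph)
    f1 = fit_reml(d1.X, Z, df["sqrt_Asat"].to_numpy())
    f2 = fit_reml(d2.X, Z, df["sqrt_Asat"].to_numpy())
    best, table = compare_alternatives([f1, f2], ["small", "full"])
    aics = [information_criterion(f) for f in (f1, f2)]
    assert best == int(np.argmin(aics))
    assert table.loc[best, "chosen"]
    # single candidate returned unchanged; ties -> first by input order
    assert compare_alternatives([f1])[0] == 0
    b, t = compare_alternatives([f1, f1], ["a", "b"])
    assert b == 0 and t.attrs.get("tie") == ["a", "b"]
    # differing row sets are rejected
    d1b = expand_design(df.iloc[:-1], build_term_graph(spec_small))
    Zb = random_design(df.iloc[:-1])
    f1b = fit_reml(d1b.X, Zb, df["sqrt_Asat"].to_numpy()[:-1])
    with pytest.raises(ValueError, match="row sets"):
        compare_alternatives([f1, f1b])


def test_variety_slope_contrasts_reference_and_recovery():
    rng = np.random.default_rng(41)
    n_per = 200
    g = 3
    offs = {"V1": 0.0, "V2": 0.2, "V3": -0.2}
    df = pd.DataFrame({
        "variety_id": np.repeat(list(offs), n_per),
        "T": rng.normal(size=g * n_per),
        "E": rng.normal(size=g * n_per),
    })
    slope = 0.5 + df["variety_id"].map(offs).to_numpy()
    y = 1 + 0.3 * df["T"] + (slope * df["T"] * df["E"]) + rng.normal(0, 0.5, g * n_per)
    df["y"] = y
    graph = build_term_graph(ModelSpec(
        response="y", traits=("T",), environments=("E",),
        variety_levels=("V1", "V2", "V3"), include_quadratics=False,
    ))
    design = expand_design(df, graph)
    fit = fit_reml(design.X, [], y)
    out = variety_slope_contrasts(fit, design, env="E", trait="T",
                                  method="satterthwaite")
    ref = out[out.variety == "V1"].iloc[0]
    assert ref.delta_slope == 0.0 and ref.p == 1.0
    for v, d_true in (("V2", 0.2), ("V3", -0.2)):
        row = out[out.variety == v].iloc[0]
        assert abs(row.delta_slope - d_true) < 2.5 * row.se
        assert row.p < 0.05


def test_slopes_forced_equal_without_three_way_term():
    rng = np.random.default_rng(43)
    n = 300
    df = pd.DataFrame({
        "variety_id": np.tile(["V1", "V2", "V3"], n // 3),
        "T": rng.normal(size=n),
        "E": rng.normal(size=n),
    })
    df["y"] = 1 + 0.4 * df["T"] * df["E"] + rng.normal(0, 0.5, n)
    graph = build_term_graph(ModelSpec(
        response="y", traits=("T",), environments=("E",),
        variety_levels=("V1", "V2", "V3"), include_quadratics=False,
        include_three_way=False,
    ))
    design = expand_design(df, graph)
    fit = fit_reml(design.X, [], df["y"].to_numpy())
    out = variety_slope_contrasts(fit, design, env="E", trait="T")
    assert (out.delta_slope == 0.0).all()
    with pytest.raises(DesignError):
        variety_slope_contrasts(fit, design, env="missing", trait="T")


def test_trait_by_variety_models_detect_a_shifted_variety():
    from traitenv import GeneratorConfig, generate, preprocess

    cfg = GeneratorConfig(seed=53, missing_phys_count=0, la_outlier_count=0,
                          variety_trait_shift={("PD", "OP2"): 2.0})
    table, _ = generate(cfg)
    df, _ = preprocess(table)
    Z = random_design(df)
    res = trait_by_variety_models(df, ("PD", "LA"), ("H1", "H2", "OP1", "OP2", "OP3"), Z)
    fit_pd, test_pd = res["PD"]
    assert test_pd.p < 1e-4  # +2 SD shift is detected
    _, test_la = res["LA"]
    assert test_la.p > 1e-4  # no shift injected on LA
    with pytest.raises(DesignError):
        trait_by_variety_models(df, ("PD",), ("H1",), Z)
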