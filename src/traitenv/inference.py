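"""Type-II marginality ANOVA, backward elimination and contrasts.

Type-II tests follow the principle of marginality: each term is tested
after every term that does not contain it, ignoring its higher-order
relatives. The hypothesis matrix for a term is built by the classical
forward-elimination (Doolittle) construction on X'X with the columns
ordered [terms not containing t | t | terms containing t]; on balanced
orthogonal designs these sums of squares coincide with sequential (type-I)
sums of squares, and in the OLS case they equal the model-comparison
quantity RSS(others) - RSS(others + t).

Backward elimination removes, one at a time, the least significant
removable term (a term is removable when no other term still in the model
contains it; the intercept never is) until every removable term is
significant at ``alpha``. The random part is never selected over.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm_engine import FTestResult, FittedLMM, f_test, fit_reml, information_criterion
from .model_design import Design, DesignError, Term, TermGraph, contains, expand_design

__all__ = [
    "AnovaTable",
    "SelectionTrace",
    "type2_contrast",
    "type2_anova",
    "backward_select",
    "compare_alternatives",
    "variety_slope_contrasts",
    "trait_by_variety_models",
]


@dataclass
class AnovaTable:
    """Per-term type-II F table shaped like a mixed-model ANOVA printout."""

    rows: pd.DataFrame  # index: term label; columns: sum_sq, mean_sq, ndf, ddf, F, p
    alpha: float = 0.05
    method: str = "kenward_roger"

    def significant(self) -> list[str]:
        return list(self.rows.index[self.rows["p"] < self.alpha])

    def to_frame(self) -> pd.DataFrame:
        out = self.rows.copy()
        out.insert(0, "term", out.index)
        return out.reset_index(drop=True)


@dataclass
class SelectionTrace:
    steps: list[tuple[int, str, float, float]] = field(default_factory=list)
    final_graph: TermGraph | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["step", "term_dropped", "p_at_drop", "model_aic"]
        )


def _doolittle_rows(M: np.ndarray) -> np.ndarray:
    """Unit-diagonal row-echelon form of a symmetric PD matrix.

    Row i tests column i adjusted for all earlier columns; for PD M this is
    diag(R)^-1 R with R the upper Cholesky factor.
    """
    R = np.linalg.cholesky(M).T
    return R / np.diag(R)[:, None]


def type2_contrast(design: Design, term: Term) -> np.ndarray:
    """Type-II hypothesis matrix L (q x k) for one term."""
    graph = design.graph
    if term not in graph.terms:
        raise DesignError(f"term {term.label} not in model")
    others, containing = [], []
    for t in graph.terms:
        if t == term:
            continue
        (containing if contains(term, t) else others).append(t)
    order = others + [term] + containing
    idx = [i for t in order for i in design.term_columns(t)]
    if "xtx" not in design.__dict__:
        design.__dict__["xtx"] = design.X.T @ design.X
    M = design.__dict__["xtx"][np.ix_(idx, idx)]
    # tiny ridge guards near-singular crossproducts without moving the test
    M = M + np.eye(M.shape[0]) * (1e-12 * np.trace(M) / M.shape[0])
    U = _doolittle_rows(M)
    start = sum(len(design.term_columns(t)) for t in others)
    q = len(design.term_columns(term))
    Lp = U[start:start + q]
    L = np.zeros((q, design.k))
    L[:, idx] = Lp
    return L


def type2_anova(
    fit: FittedLMM,
    design: Design,
    alpha: float = 0.05,
    method: str = "kenward_roger",
    terms: list[Term] | None = None,
) -> AnovaTable:
    """Type-II F tests for every non-intercept term (or the given subset).

    Sum Sq and Mean Sq columns are reconstructed from the F statistic and
    the residual variance (mean_sq = F * s2_e) for layout parity with
    mixed-model ANOVA tables; they are presentational, the tests are the
    F/ddf/p columns.
    """
    graph = design.graph
    targets = [t for t in (terms or graph.terms) if not t.is_intercept]
    recs = []
    for term in targets:
        L = type2_contrast(design, term)
        res = f_test(fit, L, method=method)
        mean_sq = res.F * fit.sigma2
        recs.append(
            (term.label, mean_sq * res.ndf, mean_sq, res.ndf, res.ddf, res.F, res.p)
        )
    rows = pd.DataFrame(
        recs, columns=["term", "sum_sq", "mean_sq", "ndf", "ddf", "F", "p"]
    ).set_index("term")
    return AnovaTable(rows=rows, alpha=alpha, method=method)


def _fit_graph(
    df: pd.DataFrame,
    response: str,
    graph: TermGraph,
    Z_list: list[np.ndarray],
    compute_ml: bool = True,
) -> tuple[FittedLMM, Design]:
    design = expand_design(df, graph)
    fit = fit_reml(design.X, Z_list, df[response].to_numpy(dtype=float),
                   column_labels=design.labels(), compute_ml=compute_ml)
    return fit, design


def backward_select(
    df: pd.DataFrame,
    response: str,
    graph: TermGraph,
    Z_list: list[np.ndarray],
    alpha: float = 0.05,
    method: str = "kenward_roger",
    aic_likelihood: str = "reml",
) -> tuple[SelectionTrace, FittedLMM, Design]:
    """Marginality-respecting backward elimination of fixed-effect terms.

    At each step the removable terms (not contained in any term still
    present) are tested by type-II F; the one with the largest p-value above
    ``alpha`` is dropped and the model refitted. Ties are broken toward the
    higher-order term, then lexicographically, making the path
    deterministic. The random part is untouched.
    """
    trace = SelectionTrace()
    step = 0
    design_full = expand_design(df, graph)
    y = df[response].to_numpy(dtype=float)
    problem_full = None
    fit, design = None, None

    def refit(g: TermGraph, warm):
        nonlocal problem_full
        from .lmm_engine import _Problem

        if problem_full is None:
            problem_full = _Problem(design_full.X, Z_list, y)
        keep = [i for i, (t, _) in enumerate(design_full.columns) if t in g.terms]
        design_g = Design(
            design_full.X[:, keep],
            [design_full.columns[i] for i in keep],
            g,
        )
        starts = [warm] if warm is not None else None
        fit_g = fit_reml(
            None, Z_list, None,
            column_labels=design_g.labels(),
            problem=problem_full.subset(keep),
            starts=starts,
            compute_ml=False,
        )
        return fit_g, design_g

    fit, design = refit(graph, None)
    while True:
        removable = graph.removable()
        if not removable:
            break
        table = type2_anova(fit, design, alpha=alpha, method=method, terms=removable)
        pvals = table.rows["p"]
        worst_p = float(pvals.max())
        if not (worst_p > alpha):
            break
        # tie-break: highest order first, then label
        cand = [t for t in removable if pvals[t.label] >= worst_p - 1e-12]
        cand.sort(key=lambda t: (-t.order, t.label))
        drop = cand[0]
        graph = graph.drop(drop)
        step += 1
        fit, design = refit(graph, np.maximum(fit.gamma, 1e-3))
        trace.steps.append(
            (step, drop.label, worst_p, information_criterion(fit, aic_likelihood))
        )
    trace.final_graph = graph
    # final refit with the ML likelihood available for AIC comparisons
    fit, design = _fit_graph(df, response, graph, Z_list, compute_ml=True)
    # post-hoc invariant: every removable term in the final model is significant
    final_table = type2_anova(fit, design, alpha=alpha, method=method,
                              terms=graph.removable())
    assert not (final_table.rows["p"] > alpha).any(), "selection left a removable nonsignificant term"
    return trace, fit, design


def compare_alternatives(
    fits: list[FittedLMM],
    labels: list[str] | None = None,
    likelihood: str = "reml",
) -> tuple[int, pd.DataFrame]:
    """Pick the fit with the smallest AIC among alternative final models.

    All candidates must be fits of the same response on the same rows.
    Ties go to the first candidate in input order and are reported.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits use different row sets: n = {sorted(ns)}")
    labels = labels or [f"model_{i}" for i in range(len(fits))]
    aics = [information_criterion(f, likelihood) for f in fits]
    best = int(np.argmin(aics))
    table = pd.DataFrame({
        "model": labels,
        "aic": aics,
        "k_fixed": [f.k_fixed for f in fits],
        "chosen": [i == best for i in range(len(fits))],
    })
    tied = [i for i, a in enumerate(aics) if i != best and abs(a - aics[best]) < 1e-9]
    if tied:
        table.attrs["tie"] = [labels[best]] + [labels[i] for i in tied]
    return best, table


def variety_slope_contrasts(
    fit: FittedLMM,
    design: Design,
    env: str,
    trait: str | None = None,
    method: str = "kenward_roger",
) -> pd.DataFrame:
    """Per-variety slope differences against the reference variety.

    For a trait-environment pair the contrast is the trait x env x variety
    coefficient (the per-variety offset of the interaction slope); with
    ``trait=None`` it is the env x variety coefficient (environment-response
    slopes). The reference variety's contrast is identically zero. A model
    without the variety interaction forces equal slopes: all contrasts 0.
    """
    from .model_design import VARIETY

    graph = design.graph
    if not graph.g:
        raise DesignError("model has no variety factor")
    base = [trait, env] if trait is not None else [env]
    term = Term(base + [VARIETY])
    if Term(base) not in graph.terms and term not in graph.terms:
        raise DesignError(f"interaction for {' x '.join(base)} absent from model")
    recs = [{"variety": graph.variety_levels[0], "delta_slope": 0.0,
             "se": 0.0, "p": 1.0}]
    for lev in graph.variety_levels[1:]:
        if term in graph.terms:
            j = design.column_index(term, lev)
            L = np.zeros((1, design.k))
            L[0, j] = 1.0
            res = f_test(fit, L, method=method)
            se = float(np.sqrt(fit.vcov_beta_adj[j, j]))
            recs.append({"variety": lev, "delta_slope": float(fit.beta[j]),
                         "se": se, "p": res.p})
        else:
            recs.append({"variety": lev, "delta_slope": 0.0, "se": 0.0, "p": 1.0})
    return pd.DataFrame(recs)


def trait_by_variety_models(
    df: pd.DataFrame,
    traits: tuple[str, ...],
    variety_levels: tuple[str, ...],
    Z_list: list[np.ndarray],
    method: str = "kenward_roger",
) -> dict[str, tuple[FittedLMM, FTestResult]]:
    """One nested LMM per trait: trait ~ variety + (farm/plot/subplot).

    Used to judge whether varieties differ in the traits the performance
    models retain.
    """
    from .model_design import ModelSpec, build_term_graph

    if len(variety_levels) < 2:
        raise DesignError("trait-by-variety models need at least two varieties")
    out = {}
    for trait in traits:
        spec = ModelSpec(response=trait, variety_levels=variety_levels)
        graph = build_term_graph(spec)
        fit, design = _fit_graph(df, trait, graph, Z_list)
        L = type2_contrast(design, Term(["variety"]))
        out[trait] = (fit, f_test(fit, L, method=method))
    return out
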