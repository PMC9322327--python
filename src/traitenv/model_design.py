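"""Fixed-effect term graph and design matrices.

The model family is the polynomial-interaction surface

    y = b0 + sum_t (b1t T + b2t T^2) + sum_e (b3e E + b4e E^2)
        + sum_te b5te T*E + variety offsets on every linear term
        + farm-level covariates,

i.e. degree-<=2 polynomials in standardized traits and environments, all
trait x environment interactions, a single categorical (variety) entering
main effects and interactions with every linear trait/environment term and
with trait x environment products, plus linear covariates. Quadratic terms
do not interact with variety, and trait quadratics do not interact with
environments: under treatment coding this yields

    1 + (g-1) + 2p + 2q + c + pq + p(g-1) + q(g-1) + pq(g-1)

columns for p traits, q environments, g varieties and c covariates
(83 for p=4, q=2, g=5, c=2).

Terms are factor *multisets*: {T, T} is the quadratic, {T, E, V} the
three-way interaction. Containment (the principle of marginality) is
multiset inclusion, so T is contained in T^2, T*E and T*E*V, but T^2 is not
contained in T*E.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Term",
    "TermGraph",
    "ModelSpec",
    "build_term_graph",
    "contains",
    "expand_design",
    "random_design",
    "DesignError",
]

VARIETY = "variety"


class DesignError(ValueError):
    """Invalid model specification or rank-deficient design."""


@dataclass(frozen=True)
class Term:
    """A fixed-effect term: a multiset of factor names.

    ``factors`` is stored as a sorted tuple with repetitions (a quadratic
    repeats its factor). The empty term is the intercept.
    """

    factors: tuple[str, ...]

    def __init__(self, factors: Iterable[str] = ()):  # normalizing ctor
        object.__setattr__(self, "factors", tuple(sorted(factors)))

    @property
    def order(self) -> int:
        return len(self.factors)

    @property
    def has_variety(self) -> bool:
        return VARIETY in self.factors

    @property
    def continuous_factors(self) -> tuple[str, ...]:
        return tuple(f for f in self.factors if f != VARIETY)

    @property
    def is_intercept(self) -> bool:
        return not self.factors

    @property
    def label(self) -> str:
        if self.is_intercept:
            return "(Intercept)"
        counts = Counter(self.factors)
        parts = []
        for f in dict.fromkeys(self.factors):
            parts.append(f"{f}^2" if counts[f] == 2 else f)
        return " x ".join(parts)

    def __repr__(self) -> str:
        return f"Term({self.label})"


def contains(term_a: Term, term_b: Term) -> bool:
    """True iff ``term_a`` is (weakly) contained in ``term_b``.

    Multiset inclusion: every factor of ``a`` occurs in ``b`` with at least
    the same multiplicity. Every term contains the intercept; a term
    contains itself.
    """
    a, b = term_a.factors, term_b.factors
    if len(a) > len(b):
        return False
    # two-pointer walk over the sorted factor tuples
    j = 0
    for f in a:
        while j < len(b) and b[j] < f:
            j += 1
        if j >= len(b) or b[j] != f:
            return False
        j += 1
    return True


@dataclass
class ModelSpec:
    """Declarative description of one model."""

    response: str
    traits: tuple[str, ...] = ()
    environments: tuple[str, ...] = ()
    variety_levels: tuple[str, ...] = ()   # reference level first; () = no variety
    covariates: tuple[str, ...] = ()
    random_nesting: tuple[str, ...] = ("farm_id", "variety_id", "subplot_id")
    include_quadratics: bool = True
    include_three_way: bool = True

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        self.environments = tuple(self.environments)
        self.variety_levels = tuple(str(v) for v in self.variety_levels)
        self.covariates = tuple(self.covariates)
        if VARIETY in self.covariates:
            raise DesignError("variety must not appear among covariates")
        if len(self.variety_levels) == 1:
            raise DesignError("variety requires at least 2 levels")

    @property
    def g(self) -> int:
        return len(self.variety_levels)


@dataclass
class TermGraph:
    """The set of fixed-effect terms of a model with marginality relations."""

    terms: list[Term]
    g: int = 0  # number of variety levels (0 = no variety factor)
    variety_levels: tuple[str, ...] = ()

    def n_columns(self, term: Term) -> int:
        return self.g - 1 if term.has_variety else 1

    @property
    def total_columns(self) -> int:
        return sum(self.n_columns(t) for t in self.terms)

    def contains_map(self) -> dict[Term, list[Term]]:
        """term -> other terms in the graph that strictly contain it."""
        out: dict[Term, list[Term]] = {}
        for a in self.terms:
            out[a] = [b for b in self.terms if b != a and contains(a, b)]
        return out

    def removable(self) -> list[Term]:
        """Terms not strictly contained in any other term (intercept excluded)."""
        cmap = self.contains_map()
        return [t for t in self.terms if not t.is_intercept and not cmap[t]]

    def drop(self, term: Term) -> "TermGraph":
        if term not in self.terms:
            raise DesignError(f"term {term.label} not in graph")
        return TermGraph([t for t in self.terms if t != term], self.g, self.variety_levels)

    def to_json(self) -> str:
        return json.dumps(
            {
                "g": self.g,
                "variety_levels": list(self.variety_levels),
                "terms": [
                    {"factors": list(t.factors), "label": t.label,
                     "order": t.order, "columns": self.n_columns(t)}
                    for t in self.terms
                ],
                "total_columns": self.total_columns,
            },
            indent=2,
        )


def build_term_graph(spec: ModelSpec) -> TermGraph:
    """Enumerate the fixed-effect terms of the polynomial-interaction model."""
    terms: list[Term] = [Term()]
    g = spec.g
    if g:
        terms.append(Term([VARIETY]))
    for t in spec.traits:
        terms.append(Term([t]))
        if spec.include_quadratics:
            terms.append(Term([t, t]))
    for e in spec.environments:
        terms.append(Term([e]))
        if spec.include_quadratics:
            terms.append(Term([e, e]))
    for c in spec.covariates:
        terms.append(Term([c]))
    for t in spec.traits:
        for e in spec.environments:
            terms.append(Term([t, e]))
    if g:
        for t in spec.traits:
            terms.append(Term([t, VARIETY]))
        for e in spec.environments:
            terms.append(Term([e, VARIETY]))
        if spec.include_three_way:
            for t in spec.traits:
                for e in spec.environments:
                    terms.append(Term([t, e, VARIETY]))
    return TermGraph(terms, g=g, variety_levels=spec.variety_levels)


@dataclass
class Design:
    """A realized fixed-effect design matrix with its column map."""

    X: np.ndarray
    columns: list[tuple[Term, str | None]]  # (term, variety level or None)
    graph: TermGraph

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def term_columns(self, term: Term) -> list[int]:
        cache = self.__dict__.setdefault("_term_cols", None)
        if cache is None:
            cache = {}
            for i, (t, _) in enumerate(self.columns):
                cache.setdefault(t, []).append(i)
            self.__dict__["_term_cols"] = cache
        return cache.get(term, [])

    def column_index(self, term: Term, level: str | None = None) -> int:
        for i, (t, lev) in enumerate(self.columns):
            if t == term and lev == level:
                return i
        raise KeyError(f"no column for term {term.label} level {level}")

    def labels(self) -> list[str]:
        return [
            t.label if lev is None else f"{t.label}[{lev}]"
            for t, lev in self.columns
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.labels())


def expand_design(table: pd.DataFrame, graph: TermGraph, check_rank: bool = True) -> Design:
    """Build the fixed-effect matrix X under treatment (reference) coding.

    Columns are ordered term by term; variety-bearing terms get one column
    per non-reference level (reference = first element of
    ``graph.variety_levels``). Raises :class:`DesignError` when the result
    is rank deficient, naming the aliased columns.
    """
    n = len(table)
    cols: list[np.ndarray] = []
    cmap: list[tuple[Term, str | None]] = []
    if graph.g:
        v = table["variety_id"].astype(str).to_numpy()
        dummies = {
            lev: (v == lev).astype(float) for lev in graph.variety_levels[1:]
        }
    for term in graph.terms:
        cont = np.ones(n)
        for f in term.continuous_factors:
            cont = cont * table[f].to_numpy(dtype=float)
        if term.has_variety:
            for lev in graph.variety_levels[1:]:
                cols.append(cont * dummies[lev])
                cmap.append((term, lev))
        else:
            cols.append(cont)
            cmap.append((term, None))
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    if check_rank and X.shape[1]:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name the aliased columns via pivoted QR
            from scipy.linalg import qr as _qr

            _, R, piv = _qr(X, mode="economic", pivoting=True)
            diag = np.abs(np.diag(R))
            tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
            labels = Design(X, cmap, graph).labels()
            bad = [labels[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
            raise DesignError(f"rank-deficient design; aliased columns: {bad}")
    return Design(X, cmap, graph)


def random_design(
    table: pd.DataFrame,
    nesting: Sequence[str] = ("farm_id", "variety_id", "subplot_id"),
) -> list[np.ndarray]:
    """Indicator matrices for nested random intercepts, outermost first.

    Labels are compounded down the hierarchy (plot = farm:variety,
    subplot = farm:variety:subplot) so that identically named inner units
    under different outer units are distinct, and a broken nesting (one
    inner label under two outer labels) cannot arise silently.
    """
    Zs: list[np.ndarray] = []
    compound = None
    for level in nesting:
        lab = table[level].astype(str)
        compound = lab if compound is None else compound + ":" + lab
        codes, _ = pd.factorize(compound, sort=False)
        m = codes.max() + 1 if len(codes) else 0
        Z = np.zeros((len(table), m))
        Z[np.arange(len(table)), codes] = 1.0
        Zs.append(Z)
    for level, Z in zip(nesting, Zs):
        if Z.shape[1] == 1:
            import warnings

            warnings.warn(
                f"random level {level!r} has a single unit; it is confounded "
                "with the intercept",
                stacklevel=2,
            )
        if Z.shape[1] == len(table):
            import warnings

            warnings.warn(
                f"random level {level!r} has one unit per row; it is "
                "confounded with the residual",
                stacklevel=2,
            )
    return Zs
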