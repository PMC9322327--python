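"""Gaussian linear mixed models with nested random intercepts.

Fits y = X b + Z_1 u_1 + ... + Z_r u_r + e by restricted maximum likelihood,
where each Z is a 0/1 indicator matrix for one grouping level and
u_j ~ N(0, s2_j I), e ~ N(0, s2_e I). The covariance V = s2_e W with
W = I + sum_j g_j Z_j Z_j' is handled through the Woodbury identity on the
stacked random-effect design, so every criterion evaluation costs
O(m^3 + m^2 k) with m total group levels rather than O(n^3).

The profiled -2 restricted log-likelihood minimized over the variance
ratios g_j = s2_j / s2_e is

    log|W| + log|X' W^-1 X| + (n - k) [log(2 pi s2_hat) + 1],

with s2_hat = r' W^-1 r / (n - k); this matches the lme4 convention for
REML log-likelihoods (no |X'X| term), so AIC values are comparable with
that ecosystem.

Small-sample inference follows Kenward & Roger in the linear-covariance
form (second derivatives of V with respect to the variance parameters
vanish), with a Satterthwaite fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "FittedLMM",
    "FTestResult",
    "fit_reml",
    "reml_criterion",
    "information_criterion",
    "adjust_small_sample",
    "f_test",
    "LMMError",
    "ConvergenceWarning",
]


class LMMError(ValueError):
    pass


class ConvergenceWarning(UserWarning):
    pass


# deterministic multi-start list for the variance-ratio optimizer
_STARTS = (0.1, 1.0)
_GAMMA_MAX = 1e6
_ACTIVE_TOL = 1e-8


class _Problem:
    """Precomputed cross-products for one (X, Z_list, y) triple."""

    def __init__(self, X: np.ndarray, Z_list: Sequence[np.ndarray], y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise LMMError("X and y have incompatible shapes")
        n, k = X.shape
        if n <= k:
            raise LMMError(f"need n > k_fixed (n={n}, k={k})")
        if np.linalg.matrix_rank(X) < k:
            raise LMMError("singular fixed-effect design")
        self.X, self.y, self.n, self.k = X, y, n, k
        self.Z_list = [np.asarray(Z, dtype=float) for Z in Z_list]
        self.r = len(self.Z_list)
        self.m_sizes = [Z.shape[1] for Z in self.Z_list]
        if self.r:
            Z = np.hstack(self.Z_list)
            self.Z = Z
            self.ZtZ = Z.T @ Z
            self.ZtX = Z.T @ X
            self.Zty = Z.T @ y
            ends = np.cumsum(self.m_sizes)
            self.blocks = [slice(e - m, e) for e, m in zip(ends, self.m_sizes)]
        else:
            self.Z = np.empty((n, 0))
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def subset(self, cols: Sequence[int]) -> "_Problem":
        """A problem on a column subset of X, re-using all cross-products."""
        cols = np.asarray(cols, dtype=int)
        sub = object.__new__(_Problem)
        sub.X = self.X[:, cols]
        sub.y, sub.n, sub.k = self.y, self.n, len(cols)
        sub.Z_list, sub.r, sub.m_sizes = self.Z_list, self.r, self.m_sizes
        sub.Z = self.Z
        if self.r:
            sub.ZtZ, sub.Zty = self.ZtZ, self.Zty
            sub.ZtX = self.ZtX[:, cols]
            sub.blocks = self.blocks
        sub.XtX = self.XtX[np.ix_(cols, cols)]
        sub.Xty = self.Xty[cols]
        sub.yty = self.yty
        return sub

    def update_y(self, y: np.ndarray) -> "_Problem":
        """Re-use the design cross-products for a new response (simulations)."""
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != self.n:
            raise LMMError("response length mismatch")
        self.y = y
        if self.r:
            self.Zty = self.Z.T @ y
        self.Xty = self.X.T @ y
        self.yty = float(y @ y)
        return self

    # -- profiled criterion ------------------------------------------------
    def _solve_parts(self, gamma: np.ndarray):
        """Return (logdetW, XtWiX, XtWiy, ytWiy, active, cho_C)."""
        active = [j for j in range(self.r) if gamma[j] > _ACTIVE_TOL]
        if not active:
            return 0.0, self.XtX, self.Xty, self.yty, active, None
        idx = np.concatenate([np.arange(b.start, b.stop) for b in (self.blocks[j] for j in active)])
        Dinv = np.concatenate([
            np.full(self.m_sizes[j], 1.0 / gamma[j]) for j in active
        ])
        C = self.ZtZ[np.ix_(idx, idx)] + np.diag(Dinv)
        cho = linalg.cho_factor(C, lower=True, check_finite=False)
        logdetC = 2.0 * np.sum(np.log(np.diag(cho[0])))
        logdetW = logdetC + sum(
            self.m_sizes[j] * np.log(gamma[j]) for j in active
        )
        ZtX_a = self.ZtX[idx]
        Zty_a = self.Zty[idx]
        CiZtX = linalg.cho_solve(cho, ZtX_a, check_finite=False)
        CiZty = linalg.cho_solve(cho, Zty_a, check_finite=False)
        XtWiX = self.XtX - ZtX_a.T @ CiZtX
        XtWiy = self.Xty - ZtX_a.T @ CiZty
        ytWiy = self.yty - float(Zty_a @ CiZty)
        return logdetW, XtWiX, XtWiy, ytWiy, (active, idx), cho

    def criterion(self, gamma: np.ndarray, reml: bool = True) -> float:
        """-2 log (restricted) likelihood profiled over beta and s2_e."""
        gamma = np.maximum(np.asarray(gamma, dtype=float), 0.0)
        try:
            logdetW, XtWiX, XtWiy, ytWiy, _, _ = self._solve_parts(gamma)
            cho_b = linalg.cho_factor(XtWiX, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return np.inf
        beta = linalg.cho_solve(cho_b, XtWiy, check_finite=False)
        rWr = max(ytWiy - float(beta @ XtWiy), 1e-300)
        n, k = self.n, self.k
        if reml:
            logdet_XtWiX = 2.0 * np.sum(np.log(np.diag(cho_b[0])))
            dof = n - k
            s2 = rWr / dof
            return logdetW + logdet_XtWiX + dof * (np.log(2 * np.pi * s2) + 1.0)
        s2 = rWr / n
        return logdetW + n * (np.log(2 * np.pi * s2) + 1.0)

    def criterion_grad(self, gamma: np.ndarray, reml: bool = True):
        """Criterion and its analytic gradient with respect to the ratios.

        Uses the envelope theorem at the profiled beta: for each ratio g_j
        (with G_j = Z_j Z_j'),

            d/dg_j = tr(W^-1 G_j) - [reml] tr(Phi_w X'W^-1 G_j W^-1 X)
                     - dof * (r'W^-1 G_j W^-1 r) / (r'W^-1 r)

        with dof = n - k under REML and n under ML.
        """
        gamma = np.maximum(np.asarray(gamma, dtype=float), 0.0)
        try:
            logdetW, XtWiX, XtWiy, ytWiy, act, cho = self._solve_parts(gamma)
            cho_b = linalg.cho_factor(XtWiX, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return np.inf, np.zeros(self.r)
        beta = linalg.cho_solve(cho_b, XtWiy, check_finite=False)
        rWr = max(ytWiy - float(beta @ XtWiy), 1e-300)
        n, k = self.n, self.k
        dof = n - k if reml else n
        if reml:
            logdet_b = 2.0 * np.sum(np.log(np.diag(cho_b[0])))
            f = logdetW + logdet_b + dof * (np.log(2 * np.pi * rWr / dof) + 1.0)
        else:
            f = logdetW + dof * (np.log(2 * np.pi * rWr / dof) + 1.0)
        phi_w = linalg.cho_solve(cho_b, np.eye(k), check_finite=False) if reml else None
        active = act[0] if act else []
        if active:
            _, idx = act
            rhs = np.concatenate(
                [self.ZtX[idx], self.Zty[idx][:, None], self.ZtZ[idx]], axis=1
            )
            sol = linalg.cho_solve(cho, rhs, check_finite=False)
            CiZtX = sol[:, : self.k]
            CiZty = sol[:, self.k]
            CiZtZ = sol[:, self.k + 1:]
            CiZtWir = CiZty - CiZtX @ beta
        grad = np.zeros(self.r)
        for j in range(self.r):
            bj = self.blocks[j]
            tr_WiG = float(np.trace(self.ZtZ[bj, bj]))
            ZjtWiX = self.ZtX[bj].copy()
            ZjtWir = self.Zty[bj] - self.ZtX[bj] @ beta
            if active:
                Zat_Zj = self.ZtZ[idx, bj]
                tr_WiG -= float(np.sum(Zat_Zj * CiZtZ[:, bj]))
                ZjtWiX -= Zat_Zj.T @ CiZtX
                ZjtWir -= Zat_Zj.T @ CiZtWir
            gj = tr_WiG - dof * float(ZjtWir @ ZjtWir) / rWr
            if reml:
                gj -= float(np.sum((ZjtWiX @ phi_w) * ZjtWiX))
            grad[j] = gj
        return f, grad

    def optimize(
        self, reml: bool = True, starts: Sequence[np.ndarray] | None = None
    ) -> tuple[np.ndarray, float, bool]:
        if self.r == 0:
            return np.empty(0), self.criterion(np.empty(0), reml), True
        best_x, best_f, ok = np.zeros(self.r), self.criterion(np.zeros(self.r), reml), False
        bounds = [(0.0, _GAMMA_MAX)] * self.r
        if starts is None:
            starts = [np.full(self.r, s) for s in _STARTS]
            starts.append(np.array([2.0 ** -(j) for j in range(self.r)]))
        else:
            starts = [np.asarray(s, dtype=float) for s in starts]
        for x0 in starts:
            res = optimize.minimize(
                self.criterion_grad,
                x0,
                args=(reml,),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-11, "gtol": 1e-7, "maxiter": 500},
            )
            if not np.isfinite(res.fun):
                continue
            if res.fun < best_f - 1e-12:
                best_x, best_f, ok = res.x, res.fun, bool(res.success)
            elif res.fun < best_f + 1e-9 and res.success:
                ok = True
        # snap near-boundary ratios to exact zero when it does not hurt
        x = np.where(best_x < 1e-6, 0.0, best_x)
        f0 = self.criterion(x, reml)
        if f0 <= best_f + 1e-8:
            best_x, best_f = x, min(f0, best_f)
        return np.maximum(best_x, 0.0), best_f, ok


@dataclass
class FTestResult:
    """An F test of L @ beta = 0."""

    F: float
    ndf: int
    ddf: float
    p: float
    method: str


@dataclass
class FittedLMM:
    """REML estimates of a nested random-intercept LMM."""

    beta: np.ndarray
    vcov_beta: np.ndarray
    theta: np.ndarray          # (s2_1, ..., s2_r, s2_e)
    gamma: np.ndarray          # variance ratios s2_j / s2_e
    sigma2: float              # residual variance
    loglik_reml: float
    loglik_ml: float
    n: int
    k_fixed: int
    k_random: int
    converged: bool
    column_labels: list[str] | None = None
    _problem: _Problem = field(repr=False, default=None)
    _kr_cache: dict = field(repr=False, default_factory=dict)

    @property
    def vcov_beta_adj(self) -> np.ndarray:
        return self._kr()["phi_adj"]

    @property
    def aic(self) -> float:
        return information_criterion(self, "reml")

    @property
    def fitted_fixed(self) -> np.ndarray:
        return self._problem.X @ self.beta

    def random_effects(self) -> list[np.ndarray]:
        """BLUPs u_hat_j = g_j Z_j' V^-1 (y - X beta) per grouping level."""
        pr = self._problem
        resid = pr.y - pr.X @ self.beta
        Vi_r = self._apply_Vinv(resid)
        return [
            self.gamma[j] * self.sigma2 * (pr.Z_list[j].T @ Vi_r)
            for j in range(pr.r)
        ]

    def conditional_residuals(self) -> np.ndarray:
        pr = self._problem
        resid = pr.y - pr.X @ self.beta
        for Z, u in zip(pr.Z_list, self.random_effects()):
            resid = resid - Z @ u
        return resid

    # -- linear algebra helpers -------------------------------------------
    def _apply_Vinv(self, M: np.ndarray) -> np.ndarray:
        """V^-1 M for an n-row matrix/vector."""
        pr = self._problem
        logdetW, XtWiX, XtWiy, ytWiy, act, cho = pr._solve_parts(self.gamma)
        if not act or not act[0]:
            return M / self.sigma2
        _, idx = act
        ZtM = pr.Z[:, idx].T @ M
        return (M - pr.Z[:, idx] @ linalg.cho_solve(cho, ZtM, check_finite=False)) / self.sigma2

    def _kr(self) -> dict:
        """Kenward-Roger machinery, computed once per fit.

        Variance parameters are theta = (s2_1..s2_r, s2_e) with
        dV/ds2_j = Z_j Z_j' and dV/ds2_e = I. Everything is reduced to
        group-level (m x m) and fixed-effect (k x k) blocks; no n x n
        matrix is formed.
        """
        if self._kr_cache:
            return self._kr_cache
        pr = self._problem
        n, k, r = pr.n, pr.k, pr.r
        s2 = self.sigma2
        if s2 < 1e-25:  # (near-)perfect fit: no sampling variability to adjust
            nparam = r + 1
            self._kr_cache.update(
                phi=self.vcov_beta, phi_adj=self.vcov_beta,
                W=np.zeros((nparam, nparam)),
                P_list=[np.zeros((k, k))] * nparam,
                info=np.zeros((nparam, nparam)),
            )
            return self._kr_cache
        gamma = self.gamma
        active = [j for j in range(r) if gamma[j] > _ACTIVE_TOL]
        phi = self.vcov_beta
        # B = V^-1 X  (n x k)
        B = self._apply_Vinv(pr.X)
        N = B.T @ B                       # X' V^-2 X
        ZtB = [pr.Z_list[j].T @ B for j in range(r)]       # m_j x k
        # S[j][l] = Z_j' V^-1 Z_l ; K[j] = C^-1 (Z_act' Z_j)
        if active:
            idx = np.concatenate([np.arange(pr.blocks[j].start, pr.blocks[j].stop) for j in active])
            Dinv = np.concatenate([np.full(pr.m_sizes[j], 1.0 / gamma[j]) for j in active])
            C = pr.ZtZ[np.ix_(idx, idx)] + np.diag(Dinv)
            cho = linalg.cho_factor(C, lower=True, check_finite=False)
        else:
            idx = np.empty(0, dtype=int)
        ZtZ_cols = [pr.ZtZ[np.ix_(idx, np.arange(pr.blocks[j].start, pr.blocks[j].stop))] if active else None
                    for j in range(r)]
        K = [linalg.cho_solve(cho, ZtZ_cols[j], check_finite=False) if active else None
             for j in range(r)]

        def block(j, l):
            full = pr.ZtZ[pr.blocks[j], pr.blocks[l]]
            return full

        S = [[None] * r for _ in range(r)]
        for j in range(r):
            for l in range(r):
                if active:
                    S[j][l] = (block(j, l) - ZtZ_cols[j].T @ K[l]) / s2
                else:
                    S[j][l] = block(j, l) / s2
        ViB = self._apply_Vinv(B)                     # V^-2 X
        ZtViB = [pr.Z_list[j].T @ ViB for j in range(r)]   # Z_j' V^-2 X

        # gradient matrices P_i = X' V^-1 G_i V^-1 X; last entry is residual
        P_list = [ZtB[j].T @ ZtB[j] for j in range(r)] + [N]
        # Q_ij = X' V^-1 G_i V^-1 G_j V^-1 X
        nparam = r + 1
        Q = [[None] * nparam for _ in range(nparam)]
        for j in range(r):
            for l in range(r):
                Q[j][l] = ZtB[j].T @ (S[j][l] @ ZtB[l])
            Q[j][r] = ZtB[j].T @ ZtViB[j]
            Q[r][j] = Q[j][r].T
        Q[r][r] = B.T @ ViB

        # expected REML information I_ij = 0.5 tr(P G_i P G_j),
        # P = V^-1 - B phi B'
        info = np.zeros((nparam, nparam))
        # group-group blocks
        ZtPZ = [[None] * r for _ in range(r)]
        for j in range(r):
            for l in range(r):
                ZtPZ[j][l] = S[j][l] - ZtB[j] @ phi @ ZtB[l].T
                info[j, l] = 0.5 * float(np.sum(ZtPZ[j][l] ** 2))
        # group-residual: 0.5 ||P Z_j||_F^2
        for j in range(r):
            t1 = np.trace(block(j, j))
            if active:
                t1 += -2.0 * float(np.sum(ZtZ_cols[j] * K[j])) + float(
                    np.sum((pr.ZtZ[np.ix_(idx, idx)] @ K[j]) * K[j])
                )
            tr_V2 = t1 / s2 ** 2            # tr(Z_j' V^-2 Z_j)
            cross = float(np.sum(ZtViB[j] * (ZtB[j] @ phi)))
            quad = float(np.sum((ZtB[j] @ phi @ N) * (ZtB[j] @ phi)))
            info[j, r] = info[r, j] = 0.5 * (tr_V2 - 2.0 * cross + quad)
        # residual-residual: 0.5 tr(P^2)
        if active:
            G_aa = pr.ZtZ[np.ix_(idx, idx)]
            CiG = linalg.cho_solve(cho, G_aa, check_finite=False)
            tr_Vi2 = (n - 2.0 * np.trace(CiG) + float(np.sum(CiG * CiG.T))) / s2 ** 2
        else:
            tr_Vi2 = n / s2 ** 2
        tr_cross = float(np.trace(phi @ (B.T @ ViB)))
        tr_quad = float(np.trace(phi @ N @ phi @ N))
        info[r, r] = 0.5 * (tr_Vi2 - 2.0 * tr_cross + tr_quad)

        # W = cov(theta_hat): pseudo-inverse guards boundary/degenerate fits
        try:
            W = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            W = np.linalg.pinv(info)

        # adjusted covariance (linear covariance structure: R terms vanish)
        U = np.zeros((k, k))
        for i in range(nparam):
            for j in range(nparam):
                U += W[i, j] * (Q[i][j] - P_list[i] @ phi @ P_list[j])
        phi_adj = phi + 2.0 * phi @ U @ phi
        # guard: adjusted variances should not be negative
        if np.any(np.diag(phi_adj) < 0):
            warnings.warn(
                "Kenward-Roger adjustment produced a negative variance; "
                "falling back to the unadjusted covariance",
                ConvergenceWarning,
            )
            phi_adj = phi
        self._kr_cache.update(
            phi=phi, phi_adj=phi_adj, W=W, P_list=P_list, info=info
        )
        return self._kr_cache


def reml_criterion(
    X: np.ndarray,
    Z_list: Sequence[np.ndarray],
    y: np.ndarray,
    gamma: Sequence[float],
    reml: bool = True,
) -> float:
    """-2 profiled (restricted) log-likelihood at variance ratios ``gamma``.

    Exposed for brute-force verification of the optimizer.
    """
    return _Problem(X, Z_list, y).criterion(np.asarray(gamma, float), reml)


def fit_reml(
    X: np.ndarray,
    Z_list: Sequence[np.ndarray],
    y: np.ndarray,
    column_labels: list[str] | None = None,
    starts: Sequence[np.ndarray] | None = None,
    problem: _Problem | None = None,
    compute_ml: bool = True,
) -> FittedLMM:
    """Fit the LMM by REML. With ``Z_list`` empty this reduces to OLS.

    ``starts`` overrides the deterministic multi-start list (useful to warm
    start repeated fits on one design); ``problem`` re-uses precomputed
    cross-products from a previous fit on the same (X, Z_list).
    """
    pr = problem if problem is not None else _Problem(X, Z_list, y)
    gamma, crit, ok = pr.optimize(reml=True, starts=starts)
    if not ok:
        warnings.warn("REML optimizer did not report convergence", ConvergenceWarning)
    logdetW, XtWiX, XtWiy, ytWiy, _, _ = pr._solve_parts(gamma)
    cho_b = linalg.cho_factor(XtWiX, lower=True, check_finite=False)
    beta = linalg.cho_solve(cho_b, XtWiy, check_finite=False)
    rWr = max(ytWiy - float(beta @ XtWiy), 1e-300)
    sigma2 = rWr / (pr.n - pr.k)
    vcov = sigma2 * linalg.cho_solve(cho_b, np.eye(pr.k), check_finite=False)
    vcov = 0.5 * (vcov + vcov.T)
    theta = np.append(gamma * sigma2, sigma2)
    # ML log-likelihood via its own profile optimization (warm started)
    if compute_ml:
        _, crit_ml, _ = pr.optimize(reml=False, starts=[gamma] + ([np.full(pr.r, 1.0)] if pr.r else []))
    else:
        crit_ml = np.nan
    return FittedLMM(
        beta=beta,
        vcov_beta=vcov,
        theta=theta,
        gamma=gamma,
        sigma2=sigma2,
        loglik_reml=-0.5 * crit,
        loglik_ml=-0.5 * crit_ml,
        n=pr.n,
        k_fixed=pr.k,
        k_random=pr.r,
        converged=ok,
        column_labels=column_labels,
        _problem=pr,
    )


def information_criterion(fit: FittedLMM, likelihood: str = "reml") -> float:
    """AIC = -2 l + 2 k with k = k_fixed + k_random + 1 (residual variance)."""
    if likelihood not in ("reml", "ml"):
        raise ValueError("likelihood must be 'reml' or 'ml'")
    ll = fit.loglik_reml if likelihood == "reml" else fit.loglik_ml
    kpar = fit.k_fixed + fit.k_random + 1
    return -2.0 * ll + 2.0 * kpar


def adjust_small_sample(fit: FittedLMM) -> np.ndarray:
    """Kenward-Roger adjusted covariance of the fixed coefficients."""
    return fit.vcov_beta_adj


def satterthwaite_ddf_all(fit: FittedLMM) -> np.ndarray:
    """Satterthwaite denominator df for every coefficient at once."""
    kr = fit._kr()
    phi, W, P_list = kr["phi"], kr["W"], kr["P_list"]
    v = np.diag(phi)
    D = np.array([np.diag(phi @ P @ phi) for P in P_list])  # nparam x k
    denom = np.einsum("ic,ij,jc->c", D, W, D)
    out = np.full(fit.k_fixed, float(fit.n - fit.k_fixed))
    good = denom > 0
    out[good] = 2.0 * v[good] ** 2 / denom[good]
    return out


def _satterthwaite_ddf(fit: FittedLMM, ell: np.ndarray) -> float:
    """Satterthwaite denominator df for a single contrast ell' beta."""
    kr = fit._kr()
    phi, W, P_list = kr["phi"], kr["W"], kr["P_list"]
    v = float(ell @ phi @ ell)
    g = np.array([float(ell @ phi @ P @ phi @ ell) for P in P_list])
    denom = float(g @ W @ g)
    if denom <= 0:
        return float(fit.n - fit.k_fixed)
    return 2.0 * v * v / denom


def f_test(fit: FittedLMM, L: np.ndarray, method: str = "kenward_roger") -> FTestResult:
    """F test of H0: L beta = 0.

    ``method`` selects the denominator-df machinery: ``kenward_roger``
    (adjusted covariance and the scaled-F calibration), ``satterthwaite``,
    or ``residual`` (classical n - k df).
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    if L.shape[1] != fit.k_fixed:
        raise LMMError("contrast matrix has wrong number of columns")
    q = np.linalg.matrix_rank(L)
    if q < 1:
        raise LMMError("contrast matrix has rank 0")
    if q < L.shape[0]:
        # reduce to a full-rank row basis
        Lq, _ = np.linalg.qr(L.T)
        L = Lq[:, :q].T
    Lb = L @ fit.beta

    if method == "residual":
        M = L @ fit.vcov_beta @ L.T
        F = float(Lb @ np.linalg.solve(M, Lb)) / q
        ddf = float(fit.n - fit.k_fixed)
        return FTestResult(F, q, ddf, float(stats.f.sf(F, q, ddf)), method)

    if method == "satterthwaite":
        kr = fit._kr()
        phi = kr["phi"]
        M = L @ phi @ L.T
        d, Uv = np.linalg.eigh(M)
        ord_ = np.argsort(d)[::-1]
        d, Uv = d[ord_], Uv[:, ord_]
        Lt = Uv.T @ L
        t2 = []
        nus = []
        for i in range(q):
            ell = Lt[i]
            t2.append(float(ell @ fit.beta) ** 2 / d[i])
            nus.append(_satterthwaite_ddf(fit, ell))
        F = sum(t2) / q
        E = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0)
        ddf = 2.0 * E / (E - q) if E > q else np.inf
        p = float(stats.f.sf(F, q, ddf)) if np.isfinite(ddf) else float(stats.chi2.sf(q * F, q))
        return FTestResult(float(F), q, float(ddf), p, method)

    if method != "kenward_roger":
        raise ValueError(f"unknown method {method!r}")

    kr = fit._kr()
    phi, phi_adj, W, P_list = kr["phi"], kr["phi_adj"], kr["W"], kr["P_list"]
    M_adj = L @ phi_adj @ L.T
    F = float(Lb @ np.linalg.solve(M_adj, Lb)) / q
    # Kenward-Roger scale and ddf
    M = L @ phi @ L.T
    Theta = L.T @ np.linalg.solve(M, L)
    nparam = len(P_list)
    TPhiP = [Theta @ phi @ P_list[i] @ phi for i in range(nparam)]
    A1 = 0.0
    A2 = 0.0
    for i in range(nparam):
        tri = np.trace(TPhiP[i])
        for j in range(nparam):
            A1 += W[i, j] * tri * np.trace(TPhiP[j])
            A2 += W[i, j] * float(np.trace(TPhiP[i] @ TPhiP[j]))
    B = (A1 + 6.0 * A2) / (2.0 * q)
    g = ((q + 1.0) * A1 - (q + 4.0) * A2) / ((q + 2.0) * A2) if A2 > 1e-14 else 0.0
    c1 = g / (3.0 * q + 2.0 * (1.0 - g))
    c2 = (q - g) / (3.0 * q + 2.0 * (1.0 - g))
    c3 = (q + 2.0 - g) / (3.0 * q + 2.0 * (1.0 - g))
    Estar = 1.0 / (1.0 - A2 / q) if A2 < q else 1.0
    Vstar = (2.0 / q) * (1.0 + c1 * B) / ((1.0 - c2 * B) ** 2 * (1.0 - c3 * B))
    rho = Vstar / (2.0 * Estar ** 2)
    ddf = 4.0 + (q + 2.0) / (q * rho - 1.0) if q * rho > 1.0 else np.inf
    lam = ddf / (Estar * (ddf - 2.0)) if np.isfinite(ddf) and ddf > 2.0 else 1.0
    F_scaled = max(lam * F, 0.0)
    p = float(stats.f.sf(F_scaled, q, ddf)) if np.isfinite(ddf) else float(stats.chi2.sf(q * F, q))
    return FTestResult(float(F_scaled), q, float(ddf), p, "kenward_roger")
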