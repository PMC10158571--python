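"""Linear mixed-effects models with variance components and Satterthwaite df.

The model is

    y = X beta + sum_k Z_k b_k + e,     b_k ~ N(0, sigma_k^2 I),  e ~ N(0, sigma_e^2 I)

i.e. every random term contributes independent effects with a single variance
— random intercepts for grouping factors (participant, fROI, condition) and
uncorrelated random slopes (a slope term's Z carries the covariate value in
the group's column).  This covers crossed random intercepts plus by-participant
slopes, the "maximal" structures used for ISC contrasts, with slopes
uncorrelated from intercepts.

Estimation is restricted maximum likelihood (REML), profiled over the
residual variance and optimized over log variance ratios; all linear algebra
goes through the Woodbury identity so each evaluation costs O(q^3) in the
total random-effect dimension q, independent of the number of rows after a
one-time pass.  Fixed-effect t-tests use the Satterthwaite approximation:
the variance of the contrast variance estimate is obtained by the delta
method from the numerical Hessian of the REML deviance at the optimum, and

    df = 2 f^2 / (g' A g),   f = c' Cov(beta) c,  A = 2 H^{-1},  g = df/dphi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

_GAMMA_LOG_BOUNDS = (-18.0, 12.0)
_BOUNDARY_TOL = 1e-4  # gamma below this counts as a zero variance component


@dataclass
class RandomTerm:
    """One variance component: name and its n × q design matrix."""

    name: str
    Z: np.ndarray


def indicator_matrix(labels: Sequence) -> np.ndarray:
    """n × q 0/1 design for a grouping factor (random intercepts)."""
    _, inverse = np.unique(np.asarray(labels), return_inverse=True)
    q = inverse.max() + 1
    Z = np.zeros((len(inverse), q))
    Z[np.arange(len(inverse)), inverse] = 1.0
    return Z


def slope_matrix(labels: Sequence, x: np.ndarray) -> np.ndarray:
    """n × q design for a by-group random slope on covariate ``x``."""
    Z = indicator_matrix(labels)
    return Z * np.asarray(x, dtype=float)[:, None]


@dataclass
class MixedModelResult:
    """Fitted variance-components mixed model."""

    beta: np.ndarray
    xnames: List[str]
    cov_beta: np.ndarray
    sigma2: float  # residual variance
    gammas: Dict[str, float]  # variance ratios sigma_k^2 / sigma_e^2
    deviance: float  # -2 REML log-likelihood
    n: int
    p: int
    converged: bool
    re_structure: str
    degenerate: bool = False
    _engine: Optional["_REMLEngine"] = field(default=None, repr=False)

    @property
    def variance_components(self) -> Dict[str, float]:
        out = {k: g * self.sigma2 for k, g in self.gammas.items()}
        out["residual"] = self.sigma2
        return out

    def contrast(self, c: np.ndarray, one_tailed: bool = False) -> Dict[str, float]:
        """Estimate, SE, t, Satterthwaite df, and p for a fixed-effect contrast."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta)
        var = float(c @ self.cov_beta @ c)
        if self.degenerate or var <= 0:
            return {"estimate": est, "se": 0.0, "t": np.nan, "df": np.nan, "p": np.nan}
        se = np.sqrt(var)
        t = est / se
        df = self._satterthwaite_df(c) if self._engine is not None else float(self.n - self.p)
        p = float(stats.t.sf(t, df)) if one_tailed else float(2.0 * stats.t.sf(abs(t), df))
        return {"estimate": est, "se": se, "t": float(t), "df": float(df), "p": p}

    def _satterthwaite_df(self, c: np.ndarray) -> float:
        return self._engine.satterthwaite_df(c, self.gammas, self.sigma2)


class _REMLEngine:
    """Precomputed cross-products and Woodbury evaluations for one dataset."""

    def __init__(self, y: np.ndarray, X: np.ndarray, terms: List[RandomTerm]):
        self.n, self.p = X.shape
        self.terms = terms
        self.K = len(terms)
        if terms:
            Z = np.hstack([t.Z for t in terms])
            self.comp = np.concatenate(
                [np.full(t.Z.shape[1], k) for k, t in enumerate(terms)]
            )
        else:
            Z = np.zeros((self.n, 0))
            self.comp = np.zeros(0, dtype=int)
        self.q = Z.shape[1]
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    # -- core: everything needed at one gamma point ------------------------
    def _pieces(self, gammas: np.ndarray):
        """Return (logdet M, Q = X'V0^-1 X, X'V0^-1 y, y'V0^-1 y)."""
        if self.q == 0:
            return 0.0, self.XtX, self.Xty, self.yty
        d = gammas[self.comp]
        sq = np.sqrt(d)
        M = np.eye(self.q) + (sq[:, None] * self.ZtZ) * sq[None, :]
        cf = cho_factor(M, lower=True)
        logdet_m = 2.0 * np.log(np.diag(cf[0])).sum()
        A = sq[:, None] * self.ZtX  # q × p
        b = sq * self.Zty  # q
        MiA = cho_solve(cf, A)
        Mib = cho_solve(cf, b)
        Q = self.XtX - A.T @ MiA
        Xy = self.Xty - A.T @ Mib
        yy = self.yty - b @ Mib
        return logdet_m, Q, Xy, yy

    def gls(self, gammas: np.ndarray):
        """beta-hat, RSS0, logdet M, logdet Q at given variance ratios."""
        logdet_m, Q, Xy, yy = self._pieces(gammas)
        cfq = cho_factor(Q, lower=True)
        beta = cho_solve(cfq, Xy)
        logdet_q = 2.0 * np.log(np.diag(cfq[0])).sum()
        rss = max(yy - Xy @ beta, 1e-300)
        return beta, rss, logdet_m, logdet_q, Q

    def profiled_deviance(self, log_gammas: np.ndarray) -> float:
        """-2 REML log-likelihood profiled over sigma_e^2 (constants dropped)."""
        try:
            _, rss, logdet_m, logdet_q, _ = self.gls(np.exp(log_gammas))
        except np.linalg.LinAlgError:
            return np.inf
        nmp = self.n - self.p
        return nmp * np.log(rss / nmp) + logdet_m + logdet_q

    def full_deviance(self, sigma2s: np.ndarray, sigma2_e: float) -> float:
        """-2 REML log-likelihood as a function of raw variances (constants
        without parameter dependence dropped consistently)."""
        gammas = sigma2s / sigma2_e
        try:
            _, rss, logdet_m, logdet_q, _ = self.gls(gammas)
        except np.linalg.LinAlgError:
            return np.inf
        return (
            (self.n - self.p) * np.log(sigma2_e)
            + logdet_m
            + logdet_q
            + rss / sigma2_e
        )

    def satterthwaite_df(self, c: np.ndarray, gammas: Dict[str, float], sigma2: float) -> float:
        """Delta-method Satterthwaite df for contrast ``c``.

        Variance components estimated at (or numerically near) the zero
        boundary are held fixed; the df then reflects uncertainty in the
        remaining components and the residual variance.
        """
        gam = np.array([gammas[t.name] for t in self.terms])
        active = np.flatnonzero(gam > _BOUNDARY_TOL)
        phi_hat = np.concatenate([gam[active] * sigma2, [sigma2]])

        def f_of_phi(phi: np.ndarray) -> float:
            g = gam.copy()
            g[active] = phi[:-1] / phi[-1]
            _, Q, _, _ = self._pieces(g)
            cfq = cho_factor(Q, lower=True)
            return float(phi[-1] * (c @ cho_solve(cfq, c)))

        def dev_of_phi(phi: np.ndarray) -> float:
            g = gam.copy()
            g[active] = phi[:-1] / phi[-1]
            return self.full_deviance(g * phi[-1], phi[-1])

        try:
            grad = _num_grad(f_of_phi, phi_hat)
            hess = _num_hess(dev_of_phi, phi_hat)
            cov_phi = 2.0 * np.linalg.pinv(hess)
            denom = float(grad @ cov_phi @ grad)
            f_val = f_of_phi(phi_hat)
            if denom <= 0 or not np.isfinite(denom) or f_val <= 0:
                return float(self.n - self.p)
            df = 2.0 * f_val**2 / denom
        except (np.linalg.LinAlgError, ValueError):
            return float(self.n - self.p)
        if not np.isfinite(df) or df < 1.0:
            return 1.0
        # never report more information than the residual-df upper bound
        return float(min(df, self.n - self.p))


def _num_grad(fun, x: np.ndarray, rel: float = 1e-5) -> np.ndarray:
    g = np.zeros_like(x)
    for j in range(x.size):
        h = rel * max(abs(x[j]), 1e-8)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        g[j] = (fun(xp) - fun(xm)) / (2 * h)
    return g


def _num_hess(fun, x: np.ndarray, rel: float = 1e-4) -> np.ndarray:
    k = x.size
    H = np.zeros((k, k))
    hs = np.array([rel * max(abs(x[j]), 1e-8) for j in range(k)])
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += hs[i]
                xm[i] -= hs[i]
                H[i, i] = (fun(xp) - 2 * f0 + fun(xm)) / hs[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[i] += hs[i]; xpp[j] += hs[j]
                xpm[i] += hs[i]; xpm[j] -= hs[j]
                xmp[i] -= hs[i]; xmp[j] += hs[j]
                xmm[i] -= hs[i]; xmm[j] -= hs[j]
                H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (
                    4 * hs[i] * hs[j]
                )
    return H


def fit_mixed_model(
    y: np.ndarray,
    X: np.ndarray,
    terms: Sequence[RandomTerm] = (),
    xnames: Optional[List[str]] = None,
) -> MixedModelResult:
    """Fit the variance-components mixed model by profiled REML.

    Degenerate responses (zero variance after removing fixed effects) are
    flagged rather than raised: the result carries OLS fixed effects with
    ``converged=False`` and NaN test statistics.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.size != n:
        raise ValueError("y and X row counts differ")
    if n <= p:
        raise ValueError("more fixed-effect columns than rows")
    if xnames is None:
        xnames = [f"x{j}" for j in range(p)]
    terms = [t for t in terms if t.Z.shape[1] > 0]
    names = [t.name for t in terms]
    re_structure = " + ".join(names) if names else "none"

    # degenerate response: no residual variation around the fixed effects
    beta_ols, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    scale = max(float(np.var(y)), 1.0)
    if float(resid @ resid) / n < 1e-12 * scale:
        logger.warning("degenerate response (no residual variance); flagging fit")
        return MixedModelResult(
            beta=beta_ols, xnames=xnames, cov_beta=np.zeros((p, p)), sigma2=0.0,
            gammas={t.name: 0.0 for t in terms}, deviance=np.nan, n=n, p=p,
            converged=False, re_structure=re_structure, degenerate=True,
        )

    engine = _REMLEngine(y, X, list(terms))
    K = engine.K
    if K == 0:
        beta, rss, _, _, Q = engine.gls(np.zeros(0))
        sigma2 = rss / (n - p)
        cov_beta = sigma2 * np.linalg.inv(Q)
        return MixedModelResult(
            beta=beta, xnames=xnames, cov_beta=cov_beta, sigma2=sigma2, gammas={},
            deviance=engine.profiled_deviance(np.zeros(0)), n=n, p=p,
            converged=True, re_structure=re_structure, _engine=engine,
        )

    best = None
    for start in (np.zeros(K), np.full(K, np.log(0.05))):
        res = optimize.minimize(
            engine.profiled_deviance,
            start,
            method="L-BFGS-B",
            bounds=[_GAMMA_LOG_BOUNDS] * K,
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    gam = np.exp(best.x)
    gam[gam < _BOUNDARY_TOL] = 0.0
    beta, rss, _, _, Q = engine.gls(gam)
    sigma2 = rss / (n - p)
    cov_beta = sigma2 * np.linalg.inv(Q)
    return MixedModelResult(
        beta=beta,
        xnames=xnames,
        cov_beta=cov_beta,
        sigma2=float(sigma2),
        gammas={t.name: float(g) for t, g in zip(terms, gam)},
        deviance=float(best.fun),
        n=n,
        p=p,
        converged=bool(best.success and np.isfinite(best.fun)),
        re_structure=re_structure,
        _engine=engine,
    )
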