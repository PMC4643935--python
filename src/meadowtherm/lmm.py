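"""Linear mixed models with crossed random intercepts.

Fits y = X beta + sum_k Z_k u_k + e by REML, where each Z_k is the indicator
matrix of a grouping factor (e.g. calendar month, probe id) and
u_k ~ N(0, tau_k^2 I).  The implementation profiles beta and the residual
variance out of the REML criterion and optimizes the variance ratios
gamma_k = tau_k^2 / sigma^2 on the log scale, using the Woodbury identity so
each evaluation costs O(q^3) in the total number of random-effect levels q,
not O(n^3).

Inference on fixed-effect contrasts uses the Satterthwaite approximation:
df = 2 f^2 / (g' A g), with f = Var(c' beta_hat), g its gradient in the
variance components, and A the inverse observed REML information (both by
finite differences).  This reproduces the fractional degrees of freedom
style of lmerTest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["LMMResult", "ContrastResult", "fit_lmm"]

_LOG_GAMMA_MIN, _LOG_GAMMA_MAX = -16.0, 8.0
_PIN_THRESHOLD = 1e-5  # variance ratios below this are treated as zero


@dataclass(frozen=True)
class ContrastResult:
    estimate: float
    se: float
    t: float
    df: float
    p_value: float


@dataclass
class LMMResult:
    beta: np.ndarray
    names: list[str]
    cov_beta: np.ndarray
    sigma2: float
    variance_components: dict[str, float]  # tau_k^2 (0 when pinned)
    n: int
    p: int
    converged: bool
    singular: list[str] = field(default_factory=list)
    fitted: np.ndarray | None = None
    _machinery: "_Machinery | None" = None

    @property
    def residual_sd(self) -> float:
        return float(np.sqrt(self.sigma2))

    def re_sd(self, name: str) -> float:
        return float(np.sqrt(self.variance_components[name]))

    def residuals(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, float) - self.fitted

    def contrast(self, c, ddf: str = "satterthwaite") -> ContrastResult:
        c = np.asarray(c, float)
        est = float(c @ self.beta)
        var = float(c @ self.cov_beta @ c)
        se = float(np.sqrt(max(var, 0.0)))
        if ddf == "satterthwaite" and self._machinery is not None:
            df = self._machinery.satterthwaite_df(c, self.sigma2, self.variance_components)
        else:
            df = float(self.n - self.p)
        if se == 0.0:
            return ContrastResult(est, 0.0, np.inf if est else 0.0, df, 0.0 if est else 1.0)
        t = est / se
        p = 2.0 * stats.t.sf(abs(t), df)
        return ContrastResult(est, se, float(t), float(df), float(p))


class _Machinery:
    """Sufficient statistics and REML criterion for one model."""

    def __init__(self, y, X, Zs, factor_names):
        self.y = y
        self.X = X
        self.Zs = Zs
        self.names = factor_names
        self.n, self.p = X.shape
        self.qs = [Z.shape[1] for Z in Zs]
        Z = np.hstack(Zs) if Zs else np.empty((self.n, 0))
        self.Z = Z
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _core(self, gammas):
        """Profiled pieces for V0 = I + Z diag(gamma) Z'."""
        n, p = self.n, self.p
        if self.Z.shape[1] and np.any(np.asarray(gammas) > 0):
            dinv = np.concatenate(
                [np.full(q, 1.0 / max(g, 1e-300)) for q, g in zip(self.qs, gammas)]
            )
            M = self.ZtZ + np.diag(dinv)
            sign, logdet_M = np.linalg.slogdet(M)
            logdet_V0 = logdet_M + float(
                np.sum([q * np.log(max(g, 1e-300)) for q, g in zip(self.qs, gammas)])
            )
            Minv_ZtX = np.linalg.solve(M, self.ZtX)
            Minv_Zty = np.linalg.solve(M, self.Zty)
            XtV0X = self.XtX - self.ZtX.T @ Minv_ZtX
            XtV0y = self.Xty - self.ZtX.T @ Minv_Zty
            ytV0y = self.yty - self.Zty @ Minv_Zty
        else:
            logdet_V0 = 0.0
            XtV0X, XtV0y, ytV0y = self.XtX, self.Xty, self.yty
        beta = np.linalg.solve(XtV0X, XtV0y)
        rss = max(ytV0y - float(beta @ XtV0y), 1e-12)
        return logdet_V0, XtV0X, XtV0y, beta, rss

    def neg2_profiled(self, log_gammas):
        gammas = np.exp(log_gammas)
        logdet_V0, XtV0X, _, _, rss = self._core(gammas)
        n, p = self.n, self.p
        sigma2 = rss / (n - p)
        _, logdet_XVX = np.linalg.slogdet(XtV0X)
        return (n - p) * np.log(sigma2) + logdet_V0 + logdet_XVX + (n - p)

    def neg2_raw(self, v, active):
        """-2 REML log-likelihood in raw variance components.

        ``v = [sigma2, tau2 for each active factor]``; inactive (pinned)
        factors stay at zero.
        """
        sigma2 = max(v[0], 1e-12)
        gammas = np.zeros(len(self.qs))
        for j, k in enumerate(active):
            gammas[k] = max(v[1 + j], 0.0) / sigma2
        logdet_V0, XtV0X, _, _, rss = self._core(gammas)
        n, p = self.n, self.p
        _, logdet_XVX = np.linalg.slogdet(XtV0X)
        return (n - p) * np.log(sigma2) + logdet_V0 + logdet_XVX + rss / sigma2

    def covbeta_raw(self, v, active, c):
        sigma2 = max(v[0], 1e-12)
        gammas = np.zeros(len(self.qs))
        for j, k in enumerate(active):
            gammas[k] = max(v[1 + j], 0.0) / sigma2
        _, XtV0X, _, _, _ = self._core(gammas)
        cov = sigma2 * np.linalg.inv(XtV0X)
        return float(c @ cov @ c)

    def satterthwaite_df(self, c, sigma2, variance_components):
        active = [k for k, name in enumerate(self.names) if variance_components[name] > 0]
        v = np.array([sigma2] + [variance_components[self.names[k]] for k in active])
        f0 = self.covbeta_raw(v, active, c)
        m = len(v)
        steps = np.maximum(1e-4 * np.abs(v), 1e-10)

        grad = np.empty(m)
        for i in range(m):
            vp, vm = v.copy(), v.copy()
            vp[i] += steps[i]
            vm[i] = max(vm[i] - steps[i], 1e-12)
            grad[i] = (self.covbeta_raw(vp, active, c) - self.covbeta_raw(vm, active, c)) / (
                vp[i] - vm[i]
            )

        def nll(vv):  # -log REML likelihood
            return 0.5 * self.neg2_raw(vv, active)

        H = np.empty((m, m))
        for i in range(m):
            for j in range(i, m):
                hi, hj = steps[i], steps[j]
                if i == j:
                    f_p = nll(_bump(v, i, hi))
                    f_m = nll(_bump(v, i, -hi))
                    H[i, i] = (f_p - 2 * nll(v) + f_m) / hi**2
                else:
                    fpp = nll(_bump(_bump(v, i, hi), j, hj))
                    fpm = nll(_bump(_bump(v, i, hi), j, -hj))
                    fmp = nll(_bump(_bump(v, i, -hi), j, hj))
                    fmm = nll(_bump(_bump(v, i, -hi), j, -hj))
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hi * hj)
        try:
            A = np.linalg.inv(H)
            denom = float(grad @ A @ grad)
        except np.linalg.LinAlgError:
            denom = -1.0
        if denom <= 0 or not np.isfinite(denom):
            return float(self.n - self.p)
        df = 2.0 * f0**2 / denom
        return float(np.clip(df, 1.0, self.n - self.p))


def _bump(v, i, h):
    out = v.copy()
    out[i] = max(out[i] + h, 1e-12)
    return out


def _indicator(codes: np.ndarray) -> np.ndarray:
    codes = np.asarray(codes)
    _, inv = np.unique(codes, return_inverse=True)
    q = inv.max() + 1
    Z = np.zeros((len(codes), q))
    Z[np.arange(len(codes)), inv] = 1.0
    return Z


def fit_lmm(
    y,
    X,
    factors: dict[str, np.ndarray] | None = None,
    names: list[str] | None = None,
) -> LMMResult:
    """REML fit of a linear model with crossed random intercept factors.

    Parameters
    ----------
    y, X:
        Response vector and fixed-effects design matrix (with intercept).
    factors:
        Mapping factor name -> level codes (length n); each contributes a
        random intercept per level.  Empty/None reduces to OLS with
        residual degrees of freedom.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effects design matrix is rank deficient")
    factors = factors or {}
    fnames = list(factors)
    Zs = [_indicator(factors[name]) for name in fnames]
    mach = _Machinery(y, X, Zs, fnames)

    singular: list[str] = []
    if not fnames:
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / max(n - p, 1)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        return LMMResult(
            beta=beta,
            names=names or [f"x{i}" for i in range(p)],
            cov_beta=cov,
            sigma2=sigma2,
            variance_components={},
            n=n,
            p=p,
            converged=True,
            fitted=X @ beta,
            _machinery=mach,
        )

    k = len(fnames)
    # coarse grid start, then Nelder-Mead on log variance ratios
    grid = [-6.0, -2.0, 0.0, 2.0]
    best, best_val = None, np.inf
    for start in np.array(np.meshgrid(*([grid] * k))).T.reshape(-1, k):
        val = mach.neg2_profiled(start)
        if val < best_val:
            best, best_val = start, val
    res = optimize.minimize(
        mach.neg2_profiled,
        best,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
    )
    log_g = np.clip(res.x, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX)
    gammas = np.exp(log_g)
    pinned = gammas < _PIN_THRESHOLD
    gammas[pinned] = 0.0
    singular = [fnames[i] for i in range(k) if pinned[i]]

    logdet_V0, XtV0X, XtV0y, beta, rss = mach._core(gammas)
    sigma2 = rss / (n - p)
    cov_beta = sigma2 * np.linalg.inv(XtV0X)
    vc = {fnames[i]: float(gammas[i] * sigma2) for i in range(k)}

    # BLUP-based fitted values (fixed part + predicted random effects)
    if np.any(gammas > 0):
        dinv = np.concatenate(
            [np.full(q, 1.0 / g if g > 0 else 1e300) for q, g in zip(mach.qs, gammas)]
        )
        M = mach.ZtZ + np.diag(dinv)
        u = np.linalg.solve(M, mach.Zty - mach.ZtX @ beta)
        fitted = X @ beta + mach.Z @ u
    else:
        fitted = X @ beta

    return LMMResult(
        beta=beta,
        names=names or [f"x{i}" for i in range(p)],
        cov_beta=cov_beta,
        sigma2=float(sigma2),
        variance_components=vc,
        n=n,
        p=p,
        converged=bool(res.success),
        singular=singular,
        fitted=fitted,
        _machinery=mach,
    )
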