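"""Binomial-logit mixed model with Laplace-approximated maximum likelihood.

Fits models of the form

    y_i ~ Binomial(n_i, p_i),   logit(p_i) = x_i' beta + u_{g(i)} + e_i

with independent normal random intercepts: a grouping factor (e.g. site)
and, optionally, an observation-level random effect (OLRE, one level per
row) that absorbs overdispersion.  The marginal likelihood is integrated
over the random effects with a Laplace approximation around their joint
mode, the standard approach for binomial mixed models; variance parameters
are profiled in an outer derivative-free optimization while (beta, u, e)
are found by an inner Newton iteration.

The inner linear algebra exploits the model structure: the OLRE block of
the penalized Hessian is diagonal, so each Newton step costs O(n (p+q)^2)
rather than O((n+q+p)^3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["GlmmResult", "fit_binomial_glmm"]

_ETA_CLIP = 30.0
_LOG_SD_BOUNDS = (-6.0, 3.0)


@dataclass
class GlmmResult:
    """Fixed-effect table and variance components of a fitted model."""

    beta: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    vcov: np.ndarray
    term_names: list[str]
    sd_group: float
    sd_olre: float
    loglik: float
    converged: bool
    n_obs: int
    u_group: np.ndarray
    u_olre: np.ndarray

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "Estimate": self.beta,
                "Std. Error": self.se,
                "z value": self.zvalues,
                "p value": self.pvalues,
            },
            index=self.term_names,
        )


class _Workspace:
    def __init__(self, y, n, X, group_idx, n_groups, olre):
        self.y = np.asarray(y, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.g = np.asarray(group_idx, dtype=int)
        self.q = int(n_groups)
        self.olre = bool(olre)
        self.nobs, self.p = self.X.shape
        # group indicator matrix (n x q), dense: q is small; q = 0 removes
        # the grouping random effect entirely (plain GLM limit)
        Z = np.zeros((self.nobs, self.q))
        if self.q:
            Z[np.arange(self.nobs), self.g] = 1.0
        self.Z = Z
        self.M = np.hstack([self.X, Z])  # (n, p+q)
        self.phi = np.zeros(self.p + self.q)  # warm start (beta, u)
        self.e = np.zeros(self.nobs)

    # ---- penalized log-likelihood pieces -------------------------------
    def _eta(self, phi, e):
        return np.clip(self.M @ phi + e, -_ETA_CLIP, _ETA_CLIP)

    def _loglik(self, eta):
        return float(self.y @ eta - self.n @ np.logaddexp(0.0, eta))

    def _penalized(self, phi, e, inv_vs, inv_vo):
        u = phi[self.p :]
        pen = 0.5 * inv_vs * (u @ u)
        if self.olre:
            pen += 0.5 * inv_vo * (e @ e)
        return self._loglik(self._eta(phi, e)) - pen

    def inner_mode(self, sd_group, sd_olre, max_iter=80, tol=1e-10):
        """Newton maximization of the penalized log-likelihood over
        (beta, u, e) with step halving; warm-started across calls."""
        inv_vs = 1.0 / sd_group**2
        inv_vo = (1.0 / sd_olre**2) if self.olre else np.inf
        phi, e = self.phi.copy(), (self.e.copy() if self.olre else np.zeros(self.nobs))
        f_cur = self._penalized(phi, e, inv_vs, inv_vo)
        converged = False
        for _ in range(max_iter):
            eta = self._eta(phi, e)
            mu = self.n * _expit(eta)
            w = np.maximum(self.n * _expit(eta) * _expit(-eta), 1e-12)
            res = self.y - mu
            u = phi[self.p :]
            g_phi = self.M.T @ res
            g_phi[self.p :] -= inv_vs * u
            if self.olre:
                g_e = res - inv_vo * e
                d = w + inv_vo
                WM = self.M * w[:, None]
                S = self.M.T @ WM
                S[self.p :, self.p :] += inv_vs * np.eye(self.q)
                S -= WM.T @ (WM / d[:, None])
                rhs = g_phi - WM.T @ (g_e / d)
                try:
                    d_phi = np.linalg.solve(S, rhs)
                except np.linalg.LinAlgError:
                    d_phi = np.linalg.lstsq(S, rhs, rcond=None)[0]
                d_e = (g_e - WM @ d_phi) / d
            else:
                WM = self.M * w[:, None]
                S = self.M.T @ WM
                S[self.p :, self.p :] += inv_vs * np.eye(self.q)
                try:
                    d_phi = np.linalg.solve(S, g_phi)
                except np.linalg.LinAlgError:
                    d_phi = np.linalg.lstsq(S, g_phi, rcond=None)[0]
                d_e = np.zeros(self.nobs)

            step = 1.0
            for _half in range(30):
                phi_new = phi + step * d_phi
                e_new = e + step * d_e
                f_new = self._penalized(phi_new, e_new, inv_vs, inv_vo)
                if f_new >= f_cur - 1e-12:
                    break
                step *= 0.5
            gain = f_new - f_cur
            phi, e, f_cur = phi_new, e_new, f_new
            if abs(gain) < tol * (abs(f_cur) + 1.0):
                converged = True
                break
        self.phi, self.e = phi, e
        return phi, e, f_cur, converged

    def laplace_nll(self, log_sd_group, log_sd_olre):
        """Negative Laplace-approximated log marginal likelihood."""
        sd_s = float(np.exp(np.clip(log_sd_group, *_LOG_SD_BOUNDS)))
        sd_o = float(np.exp(np.clip(log_sd_olre, *_LOG_SD_BOUNDS))) if self.olre else 0.0
        phi, e, f_pen, _ = self.inner_mode(sd_s, sd_o)
        eta = self._eta(phi, e)
        w = np.maximum(self.n * _expit(eta) * _expit(-eta), 1e-12)
        inv_vs = 1.0 / sd_s**2
        logdet = self._logdet_random(w, inv_vs, sd_o)
        ll = f_pen - self.q * np.log(sd_s) - 0.5 * logdet
        if self.olre:
            ll -= self.nobs * np.log(sd_o)
        return -ll

    def _logdet_random(self, w, inv_vs, sd_o):
        """log det of the random-effect block of the penalized Hessian."""
        Z = self.Z
        if self.olre:
            inv_vo = 1.0 / sd_o**2
            d = w + inv_vo
            WZ = Z * w[:, None]
            S = Z.T @ WZ + inv_vs * np.eye(self.q) - WZ.T @ (WZ / d[:, None])
            return float(np.sum(np.log(d)) + np.linalg.slogdet(S)[1])
        S = Z.T @ (Z * w[:, None]) + inv_vs * np.eye(self.q)
        return float(np.linalg.slogdet(S)[1])

    def beta_vcov(self, sd_group, sd_olre):
        """beta block of the inverse penalized Hessian at the joint mode
        (the conditional fixed-effect covariance, as in lme4)."""
        phi, e, _, _ = self.inner_mode(sd_group, sd_olre)
        eta = self._eta(phi, e)
        w = np.maximum(self.n * _expit(eta) * _expit(-eta), 1e-12)
        inv_vs = 1.0 / sd_group**2
        if self.olre:
            inv_vo = 1.0 / sd_olre**2
            d = w + inv_vo
            WM = self.M * w[:, None]
            S = self.M.T @ WM
            S[self.p :, self.p :] += inv_vs * np.eye(self.q)
            S -= WM.T @ (WM / d[:, None])
        else:
            WM = self.M * w[:, None]
            S = self.M.T @ WM
            S[self.p :, self.p :] += inv_vs * np.eye(self.q)
        S_inv = np.linalg.inv(S)
        return S_inv[: self.p, : self.p]


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def fit_binomial_glmm(
    y,
    n,
    X,
    group_idx,
    n_groups: int | None = None,
    term_names: list[str] | None = None,
    olre: bool = True,
    fixed_sd_group: float | None = None,
    fixed_sd_olre: float | None = None,
    maxiter: int = 400,
) -> GlmmResult:
    """Fit the binomial-logit mixed model.

    Parameters
    ----------
    y, n : successes and trials per observation.
    X : fixed-effect design matrix (n_obs x p).
    group_idx : integer codes of the grouping factor (e.g. site).
    olre : include an observation-level random intercept (overdispersion).
    fixed_sd_group / fixed_sd_olre : fix a variance component instead of
        estimating it; 0 removes the component (the model then degenerates
        toward ordinary logistic regression when both are 0).
    """
    y = np.asarray(y, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    X = np.asarray(X, dtype=float)
    group_idx = np.asarray(group_idx, dtype=int)
    if n_groups is None:
        n_groups = int(group_idx.max()) + 1
    if np.any(y < 0) or np.any(y > n_arr):
        raise ValueError("need 0 <= y <= n")
    if term_names is None:
        term_names = [f"x{j}" for j in range(X.shape[1])]

    drop_group = fixed_sd_group == 0.0
    drop_olre = (fixed_sd_olre == 0.0) or not olre
    ws = _Workspace(
        y,
        n_arr,
        X,
        group_idx if not drop_group else np.zeros(len(y), dtype=int),
        n_groups if not drop_group else 0,
        olre=not drop_olre,
    )

    min_sd = float(np.exp(_LOG_SD_BOUNDS[0]))
    if drop_group:
        # q = 0: the grouping effect is gone; the SD value is inert
        fixed_sd_group = 1.0

    free: list[str] = []
    if fixed_sd_group is None:
        free.append("group")
    if not drop_olre and fixed_sd_olre is None:
        free.append("olre")

    log_sd = {"group": np.log(0.5), "olre": np.log(0.5)}
    if fixed_sd_group is not None:
        log_sd["group"] = np.log(max(fixed_sd_group, min_sd))
    if fixed_sd_olre is not None and not drop_olre:
        log_sd["olre"] = np.log(max(fixed_sd_olre, min_sd))

    converged = True
    if free:

        def objective(theta):
            vals = dict(log_sd)
            for name, t in zip(free, theta):
                vals[name] = float(np.clip(t, *_LOG_SD_BOUNDS))
            return ws.laplace_nll(vals["group"], vals["olre"])

        x0 = np.array([log_sd[name] for name in free])
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": maxiter},
        )
        converged = bool(res.success)
        for name, t in zip(free, res.x):
            log_sd[name] = float(np.clip(t, *_LOG_SD_BOUNDS))

    sd_group = float(np.exp(log_sd["group"]))
    sd_olre = float(np.exp(log_sd["olre"])) if not drop_olre else 0.0
    nll = ws.laplace_nll(np.log(sd_group), np.log(max(sd_olre, min_sd)))
    phi, e, _, inner_ok = ws.inner_mode(sd_group, max(sd_olre, min_sd))
    if not inner_ok:
        converged = False
    vcov = ws.beta_vcov(sd_group, max(sd_olre, min_sd))
    beta = phi[: ws.p]
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return GlmmResult(
        beta=beta,
        se=se,
        zvalues=z,
        pvalues=pvals,
        vcov=vcov,
        term_names=list(term_names),
        sd_group=sd_group if not drop_group else 0.0,
        sd_olre=sd_olre,
        loglik=-float(nll),
        converged=converged,
        n_obs=ws.nobs,
        u_group=phi[ws.p :].copy(),
        u_olre=e.copy(),
    )
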