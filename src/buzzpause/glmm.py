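"""Zero-truncated Poisson mixed model with nested random intercepts.

The response (post-buzz pause, integer ms >= 1) is modelled as

    k_i | u ~ ZTPoisson(lambda_i),   log lambda_i = x_i' beta + u_date(i) + v_bat(i)

with independent Gaussian random intercepts for recording date and for bat
nested within date (each bat is observed on a single date).  The marginal
likelihood integrates the random effects out per date block; the integral
is approximated either by a joint Laplace approximation over the block's
(1 + B) intercepts (default) or by nested adaptive Gauss-Hermite
quadrature, which does a 1-D AGHQ integral per bat inside a 1-D AGHQ
integral over the date effect.

Estimation is direct maximum likelihood over (beta, sigma_date, sigma_bat)
with a bounded quasi-Newton optimizer; variance components may legally end
on the sigma ~ 0 boundary, which is reported via a flag rather than hidden.
The implementation is self-contained; no mixed-model library stands behind
it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .ztp import ztp_mean

__all__ = ["ZeroTruncatedPoissonGLMM", "fit_ztp_glmm", "GlmmFit"]

_ETA_CLIP = 50.0
_SIGMA_LB = 1e-6
_BOUNDARY_TOL = 1e-4


def _ztp_eta_derivs(eta, y):
    """Per-observation nll, d nll/d eta and d2 nll/d eta2 of the ZTP."""
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    lam = np.exp(eta)
    em1 = -np.expm1(-lam)  # 1 - e^{-lam}
    small = lam < np.log(2.0)
    log_em1 = np.where(
        small,
        np.log(-np.expm1(-np.where(small, lam, 1.0))),
        np.log1p(-np.exp(-np.where(small, 1.0, lam))),
    )
    nll = lam - y * eta + special.gammaln(y + 1.0) + log_em1
    lh0 = lam * np.exp(-lam) / em1  # lam e^{-lam} / (1-e^{-lam})
    grad = lam + lh0 - y
    hess = lam + lh0 - lh0 * lam / em1
    return nll, grad, hess


@dataclass
class _Block:
    """One outer-group (date) block: observation rows and inner coding."""

    idx: np.ndarray  # rows of the full data in this block
    inner_codes: np.ndarray | None  # bat index within block, or None
    n_inner: int  # number of bats in the block (0 if no inner term)


@dataclass
class GlmmFit:
    """Summary container mirroring the fitted estimator (plain data)."""

    coef: dict
    sigma: dict
    loglik: float
    n_obs: int
    n_params: int
    aicc: float
    converged: bool
    boundary: bool
    method: str
    model: str = ""


class ZeroTruncatedPoissonGLMM(BaseEstimator):
    """Sklearn-style estimator for the zero-truncated Poisson GLMM.

    Parameters
    ----------
    fixed : tuple of str
        Covariate columns.  Object/category columns enter treatment-coded
        with the first sorted level as reference; numeric columns enter
        linearly.  An intercept is always included.
    random : tuple of str or None
        ``("date", "bat_id")`` for bat nested within date (outer first),
        a single column for one grouping level, or None for a fixed-effects
        model.
    method : {"laplace", "aghq"}
        Marginal-likelihood approximation.  ``aghq`` uses ``n_nodes``
        Gauss-Hermite nodes per scalar integral; 1 node reproduces Laplace.
    n_nodes : int
        AGHQ nodes per dimension.
    tol : float
        Gradient tolerance of the outer optimizer.

    Attributes (after fit)
    ----------------------
    coef_, coef_names_ : fixed-effect estimates on the log-rate scale.
    sigma_outer_, sigma_inner_ : random-intercept SDs (None if absent).
    loglik_, aicc_, n_obs_, n_params_ : fit summaries; ``n_params_`` counts
        fixed effects plus variance components.
    vcov_ : covariance of ``coef_`` (observed information, variance
        components held at their estimates).
    converged_, boundary_ : optimizer status and sigma-on-boundary flag.
    """

    def __init__(self, fixed=("outcome",), random=("date", "bat_id"), method="laplace",
                 n_nodes=7, tol=1e-8, max_iter=500, response="pause_ms"):
        self.fixed = fixed
        self.random = random
        self.method = method
        self.n_nodes = n_nodes
        self.tol = tol
        self.max_iter = max_iter
        self.response = response

    # -- design ------------------------------------------------------------

    def _build_design(self, X: pd.DataFrame):
        cols = [np.ones(len(X))]
        names = ["(Intercept)"]
        self.term_slices_ = {"(Intercept)": slice(0, 1)}
        self.term_levels_ = {}
        pos = 1
        for term in self.fixed:
            col = X[term]
            if col.dtype.kind in "OUS" or isinstance(col.dtype, pd.CategoricalDtype):
                levels = sorted(pd.unique(col.astype(str)))
                if len(levels) < 2:
                    raise ValueError(f"factor {term!r} has a single level")
                self.term_levels_[term] = levels
                for lev in levels[1:]:
                    cols.append((col.astype(str) == lev).to_numpy(float))
                    names.append(f"{term}[{lev}]")
                self.term_slices_[term] = slice(pos, pos + len(levels) - 1)
                pos += len(levels) - 1
            else:
                cols.append(col.to_numpy(float))
                names.append(term)
                self.term_slices_[term] = slice(pos, pos + 1)
                pos += 1
        return np.column_stack(cols), names

    def _build_blocks(self, X: pd.DataFrame):
        rnd = tuple(self.random) if self.random else ()
        if not rnd:
            return [], ()
        outer = rnd[0]
        blocks = []
        for _, sub in X.groupby(outer, sort=True):
            idx = sub.index.to_numpy()
            if len(rnd) == 2:
                codes, uniques = pd.factorize(sub[rnd[1]], sort=True)
                blocks.append(_Block(idx=idx, inner_codes=codes, n_inner=len(uniques)))
            else:
                blocks.append(_Block(idx=idx, inner_codes=None, n_inner=0))
        return blocks, rnd

    # -- likelihood --------------------------------------------------------

    def _nll_fixed(self, beta, Xm, y):
        nll, grad, _ = _ztp_eta_derivs(Xm @ beta, y)
        return nll.sum(), Xm.T @ grad

    def _block_laplace(self, block, eta0, y, sig_out, sig_in, warm):
        """Joint Laplace over the block's (1 + B) intercepts via Newton."""
        has_inner = block.inner_codes is not None
        m = 1 + (block.n_inner if has_inner else 0)
        u = warm.get(id(block))
        if u is None or len(u) != m:
            u = np.zeros(m)
        prec = np.empty(m)
        prec[0] = 1.0 / sig_out**2
        if has_inner:
            prec[1:] = 1.0 / sig_in**2
        yb = y[block.idx]
        eta_b = eta0[block.idx]
        codes = block.inner_codes

        def penalized(uvec):
            eta = eta_b + uvec[0]
            if has_inner:
                eta = eta + uvec[1:][codes]
            nll, g, h = _ztp_eta_derivs(eta, yb)
            return nll.sum() + 0.5 * np.sum(prec * uvec**2), g, h

        f, g_eta, h_eta = penalized(u)
        for _ in range(50):
            grad = np.empty(m)
            grad[0] = g_eta.sum() + prec[0] * u[0]
            H = np.zeros((m, m))
            H[0, 0] = h_eta.sum() + prec[0]
            if has_inner:
                gsum = np.bincount(codes, weights=g_eta, minlength=block.n_inner)
                hsum = np.bincount(codes, weights=h_eta, minlength=block.n_inner)
                grad[1:] = gsum + prec[1:] * u[1:]
                H[1:, 1:] = np.diag(hsum + prec[1:])
                H[0, 1:] = hsum
                H[1:, 0] = hsum
            if np.max(np.abs(grad)) < 1e-10 * (1.0 + abs(f)):
                break
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = grad / np.diag(H)
            t = 1.0
            for _ in range(25):
                u_try = u - t * step
                f_new, g_new, h_new = penalized(u_try)
                if f_new <= f + 1e-9 * (1.0 + abs(f)):
                    break
                t *= 0.5
            u = u_try
            f, g_eta, h_eta = f_new, g_new, h_new
        warm[id(block)] = u.copy()
        # final Hessian at the mode
        H = np.zeros((m, m))
        H[0, 0] = h_eta.sum() + prec[0]
        if has_inner:
            hsum = np.bincount(codes, weights=h_eta, minlength=block.n_inner)
            H[1:, 1:] = np.diag(hsum + prec[1:])
            H[0, 1:] = hsum
            H[1:, 0] = hsum
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return np.inf
        n_in = block.n_inner if has_inner else 0
        return f + 0.5 * logdet + np.log(sig_out) + n_in * np.log(sig_in if has_inner else 1.0)

    def _inner_aghq(self, eta_base, yb, sigma, nodes, weights):
        """1-D adaptive GH: log of integral of ZTP likelihood x N(0, sigma^2)."""
        # mode/curvature of the scalar penalized problem by Newton
        v, prec = 0.0, 1.0 / sigma**2
        for _ in range(50):
            nll, g, h = _ztp_eta_derivs(eta_base + v, yb)
            grad = g.sum() + prec * v
            hess = h.sum() + prec
            step = grad / hess
            if abs(step) < 1e-12:
                break
            v -= step
        _, _, h = _ztp_eta_derivs(eta_base + v, yb)
        hess = h.sum() + prec
        scale = np.sqrt(2.0 / hess)
        pts = v + scale * nodes
        logf = np.array(
            [
                -_ztp_eta_derivs(eta_base + p, yb)[0].sum()
                - 0.5 * p * p * prec
                - np.log(sigma)
                - 0.5 * np.log(2 * np.pi)
                for p in pts
            ]
        )
        return logsumexp(logf + np.log(weights) + nodes**2) + np.log(scale)

    def _block_aghq(self, block, eta0, y, sig_out, sig_in, nodes, weights):
        """Nested AGHQ: outer 1-D integral over the date effect."""
        has_inner = block.inner_codes is not None
        yb = y[block.idx]
        eta_b = eta0[block.idx]
        codes = block.inner_codes

        def log_inner(u0):
            if not has_inner:
                return -_ztp_eta_derivs(eta_b + u0, yb)[0].sum()
            tot = 0.0
            for b in range(block.n_inner):
                sel = codes == b
                tot += self._inner_aghq(eta_b[sel] + u0, yb[sel], sig_in, nodes, weights)
            return tot

        prec = 1.0 / sig_out**2
        # outer mode by derivative-free bracketing on the smooth 1-D problem
        obj = lambda u0: -(log_inner(u0) - 0.5 * u0 * u0 * prec)
        res = optimize.minimize_scalar(obj, bounds=(-5, 5), method="bounded",
                                       options={"xatol": 1e-8})
        u0 = res.x
        h = 1e-4
        hess = (obj(u0 + h) - 2 * obj(u0) + obj(u0 - h)) / h**2
        if not np.isfinite(hess) or hess <= 0:
            hess = prec
        scale = np.sqrt(2.0 / hess)
        pts = u0 + scale * nodes
        logf = np.array(
            [
                log_inner(p) - 0.5 * p * p * prec - np.log(sig_out) - 0.5 * np.log(2 * np.pi)
                for p in pts
            ]
        )
        return -(logsumexp(logf + np.log(weights) + nodes**2) + np.log(scale))

    def _nll(self, theta, Xm, y, blocks, warm):
        p = Xm.shape[1]
        beta = theta[:p]
        eta0 = Xm @ beta
        if not blocks:
            nll, _, _ = _ztp_eta_derivs(eta0, y)
            return nll.sum()
        sig_out = theta[p]
        sig_in = theta[p + 1] if len(theta) > p + 1 else None
        if self.method == "aghq":
            nodes, weights = hermgauss(self.n_nodes)
            return sum(
                self._block_aghq(b, eta0, y, sig_out, sig_in, nodes, weights) for b in blocks
            )
        return sum(self._block_laplace(b, eta0, y, sig_out, sig_in, warm) for b in blocks)

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None):
        """Fit by maximum (approximate) marginal likelihood.

        ``X`` is a DataFrame holding the fixed-effect and grouping columns;
        ``y`` the integer response (taken from ``X[self.response]`` when
        omitted).
        """
        X = pd.DataFrame(X).reset_index(drop=True)
        if y is None:
            y = X[self.response]
        y = np.asarray(y, dtype=float)
        if np.any(y < 1) or np.any(y != np.round(y)):
            raise ValueError("response must be integers >= 1 (zero-truncated support)")
        if self.method not in ("laplace", "aghq"):
            raise ValueError("method must be 'laplace' or 'aghq'")
        Xm, names = self._build_design(X)
        if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
            raise ValueError("fixed-effect design is rank deficient (not identifiable)")
        blocks, rnd = self._build_blocks(X)
        p = Xm.shape[1]

        # starting values: fixed-effects-only fit from a flat start
        beta0 = np.zeros(p)
        beta0[0] = np.log(max(y.mean(), 1.0 + 1e-6))
        res0 = optimize.minimize(
            self._nll_fixed, beta0, args=(Xm, y), jac=True, method="BFGS",
            options={"gtol": 1e-10, "maxiter": 500},
        )
        theta0 = res0.x
        bounds = [(None, None)] * p
        n_var = 0
        if blocks:
            n_var = 1 + (1 if len(rnd) == 2 else 0)
            theta0 = np.concatenate([theta0, np.full(n_var, 0.1)])
            bounds += [(_SIGMA_LB, 50.0)] * n_var

        warm = {}
        if blocks:
            res = optimize.minimize(
                lambda th: self._nll(th, Xm, y, blocks, warm),
                theta0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": self.max_iter, "ftol": 1e-12, "gtol": self.tol},
            )
            theta_hat = res.x
            converged = bool(res.success)
            nll_hat = float(res.fun)
        else:
            theta_hat = theta0
            converged = bool(res0.success)
            nll_hat = float(res0.fun[0]) if np.ndim(res0.fun) else float(res0.fun)

        self.coef_ = theta_hat[:p]
        self.coef_names_ = names
        self.sigma_outer_ = float(theta_hat[p]) if n_var >= 1 else None
        self.sigma_inner_ = float(theta_hat[p + 1]) if n_var == 2 else None
        self.boundary_ = any(
            s is not None and s < _BOUNDARY_TOL for s in (self.sigma_outer_, self.sigma_inner_)
        )
        self.loglik_ = -nll_hat
        self.n_obs_ = len(y)
        self.n_params_ = p + n_var
        k, n = self.n_params_, self.n_obs_
        self.aicc_ = (
            -2.0 * self.loglik_ + 2.0 * k + (2.0 * k * (k + 1.0) / (n - k - 1.0))
            if n - k - 1 > 0
            else np.inf
        )
        self.converged_ = converged
        self.method_ = self.method
        self._Xm, self._y, self._blocks, self._warm = Xm, y, blocks, warm
        self.vcov_ = self._beta_vcov(theta_hat, Xm, y, blocks, warm)
        if not converged:
            self.diagnostics_ = {"optimizer_message": getattr(res0, "message", "")}
        return self

    def _beta_vcov(self, theta, Xm, y, blocks, warm):
        """Observed-information covariance of beta, sigmas held at their MLEs."""
        p = Xm.shape[1]

        def f(beta):
            th = theta.copy()
            th[:p] = beta
            return self._nll(th, Xm, y, blocks, warm)

        beta = theta[:p].copy()
        h = 1e-5 * (1.0 + np.abs(beta))
        H = np.empty((p, p))
        f0 = f(beta)
        for i in range(p):
            for j in range(i, p):
                ei = np.zeros(p)
                ej = np.zeros(p)
                ei[i] = h[i]
                ej[j] = h[j]
                if i == j:
                    H[i, i] = (f(beta + ei) - 2 * f0 + f(beta - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f(beta + ei + ej) - f(beta + ei - ej) - f(beta - ei + ej) + f(beta - ei - ej)
                    ) / (4 * h[i] * h[j])
        try:
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.full((p, p), np.nan)

    # -- prediction and summaries ------------------------------------------

    def linear_predictor(self, X):
        """x'beta for new rows (random effects at zero)."""
        X = pd.DataFrame(X)
        cols = [np.ones(len(X))]
        for term in self.fixed:
            if term in self.term_levels_:
                for lev in self.term_levels_[term][1:]:
                    cols.append((X[term].astype(str) == lev).to_numpy(float))
            else:
                cols.append(X[term].to_numpy(float))
        return np.column_stack(cols) @ self.coef_

    def predict(self, X):
        """Truncation-corrected expected response E[k] = lam/(1-e^{-lam})."""
        lam = np.exp(self.linear_predictor(X))
        return ztp_mean(lam)

    def summary(self, model=""):
        """Plain-data :class:`GlmmFit` snapshot of the fitted model."""
        sigma = {}
        if self.sigma_outer_ is not None:
            sigma[self.random[0]] = self.sigma_outer_
        if self.sigma_inner_ is not None:
            sigma[f"{self.random[1]}:{self.random[0]}"] = self.sigma_inner_
        return GlmmFit(
            coef=dict(zip(self.coef_names_, self.coef_)),
            sigma=sigma,
            loglik=self.loglik_,
            n_obs=self.n_obs_,
            n_params=self.n_params_,
            aicc=self.aicc_,
            converged=self.converged_,
            boundary=self.boundary_,
            method=self.method_,
            model=model or "+".join(self.fixed) if self.fixed else "null",
        )


def fit_ztp_glmm(data, fixed=("outcome",), random=("date", "bat_id"), method="laplace",
                 n_nodes=7, response="pause_ms"):
    """Functional wrapper: fit and return the estimator."""
    est = ZeroTruncatedPoissonGLMM(
        fixed=tuple(fixed), random=tuple(random) if random else None,
        method=method, n_nodes=n_nodes, response=response,
    )
    return est.fit(data)
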