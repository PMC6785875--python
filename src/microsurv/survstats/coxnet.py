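"""Elastic-net penalized Cox regression by cyclic coordinate descent.

Minimizes

    -(1/n) log PL(beta) + lambda * sum_j w_j [ alpha |beta_j| + (1-alpha)/2 beta_j^2 ]

with Breslow handling of ties in the partial likelihood (PL), penalty factors
w_j = 1 for microbiome features and 0 for the clinical covariates (which are
therefore never shrunk), and alpha mixing the lasso and ridge penalties
(alpha = 0.5 by default, encouraging joint selection of correlated features).

The solver follows the glmnet strategy: an outer iteratively-reweighted
least-squares loop builds a quadratic approximation to the partial likelihood
around the current linear predictor, an inner cyclic coordinate-descent loop
solves the penalized weighted least-squares problem, and solutions are
warm-started down a log-spaced lambda ladder. Penalized columns are
standardized internally; coefficients are returned on the input scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit


# ---------------------------------------------------------------------------
# numba kernels (samples sorted by descending time; grp_last[i] is the last
# index of sample i's tie group, so that risk sets are array prefixes)

@njit(cache=False)
def _irls_weights(eta, delta, grp_last, g, w, z):
    """Gradient/diagonal-Hessian IRLS weights of -(1/n) Breslow log PL.

    Fills g (score per sample / n), w (curvature per sample / n) and the
    working response z in place.
    """
    n = eta.shape[0]
    m = eta.max()
    e = np.exp(eta - m)
    # cumulative risk sums up to each tie group's end
    cum = 0.0
    S = np.empty(n)
    i = 0
    while i < n:
        j = grp_last[i]
        for k in range(i, j + 1):
            cum += e[k]
        for k in range(i, j + 1):
            S[k] = cum
        i = j + 1
    # sample i's hazard term sums d/S over event groups with time <= t_i,
    # so accumulate from the smallest time (array end) backwards
    cumD = 0.0
    cumD2 = 0.0
    j = n - 1
    while j >= 0:
        i = j
        while i > 0 and grp_last[i - 1] == j:
            i -= 1
        d = 0
        for k in range(i, j + 1):
            d += delta[k]
        if d > 0:
            cumD += d / S[i]
            cumD2 += d / (S[i] * S[i])
        for k in range(i, j + 1):
            g[k] = (delta[k] - e[k] * cumD) / n
            wk = (e[k] * cumD - e[k] * e[k] * cumD2) / n
            if wk < 1e-12:
                wk = 1e-12
            w[k] = wk
            z[k] = eta[k] + g[k] / wk
        j = i - 1


@njit(cache=False)
def _solve_path(XT, delta, grp_last, lambdas, alpha, pen, betas,
                tol, max_irls, max_cd):
    """Warm-started coordinate-descent path.

    ``XT`` is the standardized design transposed (p x n, C-contiguous) so
    each coordinate update scans a contiguous row. Writes the solution at
    each lambda into ``betas`` (n_lambda x p).
    """
    p, n = XT.shape
    beta = np.zeros(p)
    eta = np.zeros(n)
    g = np.empty(n)
    w = np.empty(n)
    z = np.empty(n)
    xv = np.empty(p)
    for li in range(lambdas.shape[0]):
        lam = lambdas[li]
        for _ in range(max_irls):
            _irls_weights(eta, delta, grp_last, g, w, z)
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * XT[j, i] * XT[j, i]
                xv[j] = s
            r = np.empty(n)
            for i in range(n):
                r[i] = z[i] - eta[i]
            outer_change = 0.0
            # glmnet-style active-set iteration: full sweeps establish the
            # active set; inner sweeps over active coordinates do the work
            active = np.zeros(p, dtype=np.bool_)
            cd_iter = 0
            while cd_iter < max_cd:
                dlx = 0.0
                for j in range(p):
                    bj = beta[j]
                    gj = 0.0
                    for i in range(n):
                        gj += w[i] * XT[j, i] * r[i]
                    u = gj + bj * xv[j]
                    if pen[j] > 0.0:
                        thr = lam * alpha * pen[j]
                        if u > thr:
                            bnew = (u - thr) / (xv[j] + lam * (1.0 - alpha) * pen[j])
                        elif u < -thr:
                            bnew = (u + thr) / (xv[j] + lam * (1.0 - alpha) * pen[j])
                        else:
                            bnew = 0.0
                    else:
                        bnew = u / xv[j] if xv[j] > 0.0 else 0.0
                    dj = bnew - bj
                    if dj != 0.0:
                        beta[j] = bnew
                        for i in range(n):
                            r[i] -= dj * XT[j, i]
                        c = xv[j] * dj * dj
                        if c > dlx:
                            dlx = c
                        if c > outer_change:
                            outer_change = c
                    active[j] = bnew != 0.0 or pen[j] == 0.0
                cd_iter += 1
                if dlx < tol:
                    break
                # iterate the active set to convergence before the next sweep
                while cd_iter < max_cd:
                    dlx_a = 0.0
                    for j in range(p):
                        if not active[j]:
                            continue
                        bj = beta[j]
                        gj = 0.0
                        for i in range(n):
                            gj += w[i] * XT[j, i] * r[i]
                        u = gj + bj * xv[j]
                        if pen[j] > 0.0:
                            thr = lam * alpha * pen[j]
                            if u > thr:
                                bnew = (u - thr) / (xv[j] + lam * (1.0 - alpha) * pen[j])
                            elif u < -thr:
                                bnew = (u + thr) / (xv[j] + lam * (1.0 - alpha) * pen[j])
                            else:
                                bnew = 0.0
                        else:
                            bnew = u / xv[j] if xv[j] > 0.0 else 0.0
                        dj = bnew - bj
                        if dj != 0.0:
                            beta[j] = bnew
                            for i in range(n):
                                r[i] -= dj * XT[j, i]
                            c = xv[j] * dj * dj
                            if c > dlx_a:
                                dlx_a = c
                            if c > outer_change:
                                outer_change = c
                    cd_iter += 1
                    if dlx_a < tol:
                        break
            clamped = False
            for i in range(n):
                ei = z[i] - r[i]
                # clamp the linear predictor so risk sums stay positive even
                # when a small-lambda fit heads towards monotone likelihood
                if ei > 30.0:
                    ei = 30.0
                    clamped = True
                elif ei < -30.0:
                    ei = -30.0
                    clamped = True
                eta[i] = ei
            # a saturated predictor means the fit is diverging (monotone
            # likelihood); polishing it further is meaningless
            if outer_change < tol or clamped:
                break
        for j in range(p):
            betas[li, j] = beta[j]


@njit(cache=False)
def _breslow_loglik(eta, delta, grp_last):
    """Breslow-ties Cox partial log-likelihood (unscaled)."""
    n = eta.shape[0]
    m = eta.max()
    e = np.exp(eta - m)
    cum = 0.0
    S = np.empty(n)
    i = 0
    while i < n:
        j = grp_last[i]
        for k in range(i, j + 1):
            cum += e[k]
        for k in range(i, j + 1):
            S[k] = cum
        i = j + 1
    ll = 0.0
    i = 0
    while i < n:
        j = grp_last[i]
        d = 0
        esum = 0.0
        for k in range(i, j + 1):
            if delta[k] == 1:
                d += 1
                esum += eta[k] - m
        if d > 0:
            ll += esum - d * np.log(S[i])
        i = j + 1
    return ll


@njit(cache=False)
def _breslow_loglik_batch(etas, delta, grp_last):
    """Breslow log PL for each column of ``etas`` (n x L)."""
    L = etas.shape[1]
    out = np.empty(L)
    for li in range(L):
        out[li] = _breslow_loglik(np.ascontiguousarray(etas[:, li]), delta, grp_last)
    return out


# ---------------------------------------------------------------------------
# python-level API

def _sorted_problem(time, event):
    """Sort by descending time; return order and tie-group last indices."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=np.int64)
    order = np.argsort(-time, kind="stable")
    ts = time[order]
    n = ts.size
    grp_last = np.empty(n, dtype=np.int64)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        grp_last[i: j + 1] = j
        i = j + 1
    return order, ts, event[order], grp_last


def breslow_loglik(eta, time, event) -> float:
    """Cox partial log-likelihood with Breslow ties at linear predictor eta."""
    order, _, es, grp_last = _sorted_problem(time, event)
    return float(_breslow_loglik(np.asarray(eta, float)[order], es, grp_last))


class CoxnetPath:
    """Elastic-net Cox solution path with unpenalized clinical covariates.

    Parameters
    ----------
    X_pen
        Penalized feature matrix (clr-scale abundances), samples x features.
    X_unpen
        Unpenalized covariate matrix (may be None).
    time, event
        Right-censored outcome.
    alpha
        Elastic-net mixing parameter in (0, 1]; 0.5 by default.
    """

    def __init__(self, X_pen, X_unpen, time, event, alpha: float = 0.5):
        self.feature_names = (list(X_pen.columns) if isinstance(X_pen, pd.DataFrame)
                              else [f"f{j}" for j in range(np.asarray(X_pen).shape[1])])
        X_pen = np.asarray(X_pen, dtype=float)
        if X_unpen is None:
            X_unpen = np.zeros((X_pen.shape[0], 0))
        self.covariate_names = (list(X_unpen.columns) if isinstance(X_unpen, pd.DataFrame)
                                else [f"z{j}" for j in range(np.asarray(X_unpen).shape[1])])
        X_unpen = np.asarray(X_unpen, dtype=float)
        if not (0.0 < alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        self.alpha = float(alpha)
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=np.int64)
        if self.event.sum() < 1:
            raise ValueError("at least one event is required")

        self.p_pen = X_pen.shape[1]
        self.p_unpen = X_unpen.shape[1]
        X = np.hstack([X_pen, X_unpen])
        # standardize all columns internally (1/n variance, glmnet convention);
        # constant columns get unit scale and a zero coefficient
        self._mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self._sd = sd
        self._Xstd = (X - self._mean) / sd
        self.pen = np.concatenate([np.ones(self.p_pen), np.zeros(self.p_unpen)])

        order, _, es, grp_last = _sorted_problem(self.time, self.event)
        self._order = order
        self._Xs = np.ascontiguousarray(self._Xstd[order])
        self._XsT = np.ascontiguousarray(self._Xs.T)
        self._es = es
        self._grp_last = grp_last

    # -- lambda ladder ------------------------------------------------------

    def lambda_max(self) -> float:
        """Smallest lambda at which every penalized coefficient is zero."""
        n = self.time.size
        # fit unpenalized covariates alone (huge lambda kills penalized block)
        eta = np.zeros(n)
        if self.p_unpen:
            betas = np.zeros((1, self._Xs.shape[1]))
            _solve_path(self._XsT, self._es, self._grp_last,
                        np.array([1e30]), self.alpha, self.pen, betas,
                        1e-10, 50, 1000)
            eta = self._Xs @ betas[0]
        g = np.empty(n)
        w = np.empty(n)
        z = np.empty(n)
        _irls_weights(eta, self._es, self._grp_last, g, w, z)
        score = np.abs(self._Xs[:, : self.p_pen].T @ g)
        return float(score.max() / max(self.alpha, 1e-3))

    def lambda_ladder(self, n_lambda: int = 50, min_ratio: float | None = None) -> np.ndarray:
        lmax = self.lambda_max()
        if min_ratio is None:
            n, p = self.time.size, self.p_pen
            min_ratio = 0.01 if n < p else 1e-4
        return np.geomspace(lmax, lmax * min_ratio, n_lambda)

    # -- fitting ------------------------------------------------------------

    def fit(self, lambdas=None, n_lambda: int = 50, tol: float = 1e-9,
            max_irls: int = 25, max_cd: int = 1000) -> "CoxnetPathResults":
        if lambdas is None:
            lambdas = self.lambda_ladder(n_lambda=n_lambda)
        lambdas = np.asarray(lambdas, dtype=float)
        if lambdas.ndim != 1 or len(lambdas) == 0:
            raise ValueError("lambda ladder must be a nonempty 1-d sequence")
        if np.any(np.diff(lambdas) >= 0):
            raise ValueError("lambda ladder must be strictly decreasing")
        betas_std = np.zeros((len(lambdas), self._Xs.shape[1]))
        _solve_path(self._XsT, self._es, self._grp_last, lambdas,
                    self.alpha, self.pen, betas_std, tol, max_irls, max_cd)
        betas = betas_std / self._sd[None, :]
        # columns that were constant in the input carry no information
        betas[:, np.asarray(self._Xstd.std(axis=0) == 0)] = 0.0
        return CoxnetPathResults(self, lambdas, betas, betas_std)

    # -- diagnostics --------------------------------------------------------

    def kkt_residuals(self, lambdas, betas_std) -> np.ndarray:
        """Max violation of the subgradient optimality conditions per lambda.

        For penalized j: |grad_j + lam (1-alpha) b_j| <= lam alpha when b_j = 0
        and grad_j + lam (1-alpha) b_j + lam alpha sign(b_j) = 0 otherwise;
        for unpenalized j the plain gradient must vanish.
        """
        out = np.zeros(len(lambdas))
        n = self.time.size
        for li, lam in enumerate(np.asarray(lambdas, float)):
            b = betas_std[li]
            eta = self._Xs @ b
            g = np.empty(n)
            w = np.empty(n)
            z = np.empty(n)
            _irls_weights(eta, self._es, self._grp_last, g, w, z)
            grad = -(self._Xs.T @ g)  # gradient of -(1/n) log PL
            viol = 0.0
            for j in range(len(b)):
                if self.pen[j] > 0:
                    gj = grad[j] + lam * (1 - self.alpha) * b[j]
                    if b[j] == 0.0:
                        viol = max(viol, max(0.0, abs(gj) - lam * self.alpha))
                    else:
                        viol = max(viol, abs(gj + lam * self.alpha * np.sign(b[j])))
                else:
                    viol = max(viol, abs(grad[j]))
            out[li] = viol
        return out


class CoxnetPathResults:
    """Coefficient path over the lambda ladder."""

    def __init__(self, model: CoxnetPath, lambdas: np.ndarray,
                 betas: np.ndarray, betas_std: np.ndarray):
        self.model = model
        self.lambdas = lambdas
        self._betas = betas          # input scale
        self._betas_std = betas_std  # standardized scale
        names = model.feature_names + model.covariate_names
        self.coefficients = pd.DataFrame(betas, index=lambdas, columns=names)

    @property
    def feature_coefficients(self) -> pd.DataFrame:
        return self.coefficients[self.model.feature_names]

    @property
    def covariate_coefficients(self) -> pd.DataFrame:
        return self.coefficients[self.model.covariate_names]

    def n_selected(self) -> np.ndarray:
        return (self.feature_coefficients.to_numpy() != 0).sum(axis=1)

    def kkt_residuals(self) -> np.ndarray:
        return self.model.kkt_residuals(self.lambdas, self._betas_std)

    def linear_predictor(self, li: int) -> np.ndarray:
        """Linear predictor (input order) at the li-th lambda, centered."""
        Xc = self.model._Xstd
        return Xc @ self._betas_std[li]


def coxnet_path(X_pen, X_unpen, time, event, alpha: float = 0.5,
                lambdas=None, n_lambda: int = 50) -> CoxnetPathResults:
    """Fit the elastic-net Cox path (functional convenience wrapper)."""
    return CoxnetPath(X_pen, X_unpen, time, event, alpha=alpha).fit(
        lambdas=lambdas, n_lambda=n_lambda)
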