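"""Cox proportional hazards model.

Maximizes the partial likelihood by Newton-Raphson with step-halving, Efron
handling of tied event times by default (Breslow optional). Standard errors
come from the inverse observed information. Monotone likelihood (perfect
separation of risk) is detected and flagged instead of returning a divergent
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ..containers import SurvivalData

_MONOTONE_BETA_BOUND = 20.0


def _as_design(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    return X, [f"x{j}" for j in range(X.shape[1])]


def _loglik_grad_hess(beta, X, time, event, ties):
    """Partial log-likelihood, gradient and Hessian at ``beta``.

    Samples must be sorted by descending time so the risk set at each event
    time is a prefix of the array (tie groups included whole).
    """
    n, p = X.shape
    eta = X @ beta
    eta_stab = eta - eta.max()
    w = np.exp(eta_stab)
    wx = X * w[:, None]

    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))

    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        # absorb the whole tie group into the running risk-set sums
        for k in range(i, j):
            s0 += w[k]
            s1 += wx[k]
            s2 += np.outer(X[k], wx[k])
        dead = [k for k in range(i, j) if event[k] == 1]
        d = len(dead)
        if d > 0:
            xd = X[dead]
            loglik += eta_stab[dead].sum()
            if ties == "breslow":
                fracs = np.zeros(d)
            else:  # efron
                fracs = np.arange(d) / d
            s0d = w[dead].sum()
            s1d = wx[dead].sum(axis=0)
            s2d = xd.T @ (xd * w[dead][:, None])
            grad += xd.sum(axis=0)
            for frac in fracs:
                denom = s0 - frac * s0d
                num1 = s1 - frac * s1d
                num2 = s2 - frac * s2d
                m = num1 / denom
                loglik -= np.log(denom)
                grad -= m
                hess -= num2 / denom - np.outer(m, m)
        i = j
    # undo the eta stabilisation: each log(denom) picked up -eta_max, each
    # event contributed eta_stab; the net shift cancels exactly, so loglik is
    # already the true partial log-likelihood.
    return loglik, grad, hess


@dataclass
class CoxPHResults:
    """Fitted Cox model: coefficients, uncertainty and diagnostics."""

    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: str
    converged: bool
    monotone: bool
    dropped: list[str] = field(default_factory=list)
    model: "CoxPH | None" = None

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params).rename("HR")

    @property
    def zvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        z = self.zvalues
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=z.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        zcrit = stats.norm.ppf(1 - alpha / 2)
        with np.errstate(over="ignore"):  # monotone fits legitimately give inf
            lo = np.exp(self.params - zcrit * self.bse)
            hi = np.exp(self.params + zcrit * self.bse)
        return pd.DataFrame({"hr_lower": lo, "hr_upper": hi})

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        out = pd.DataFrame({
            "coef": self.params,
            "HR": self.hazard_ratios,
            "se": self.bse,
            "hr_lower": ci["hr_lower"],
            "hr_upper": ci["hr_upper"],
            "z": self.zvalues,
            "p": self.pvalues,
        })
        return out


class CoxPH:
    """Cox proportional hazards model for right-censored data.

    Parameters
    ----------
    X
        Design matrix (DataFrame or array), one row per subject.
    time, event
        Follow-up times (>0) and event indicators (1 = event, 0 = censored).
    ties
        "efron" (default) or "breslow".
    """

    def __init__(self, X, time, event, ties: str = "efron"):
        self.X, self.names = _as_design(X)
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        if ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        self.ties = ties
        if self.X.shape[0] != self.time.size or self.time.size != self.event.size:
            raise ValueError("X, time and event must have matching lengths")
        if (self.time <= 0).any():
            raise ValueError("all times must be positive")
        if self.event.sum() < 1:
            raise ValueError("at least one event is required")

    @classmethod
    def from_survival(cls, survival: SurvivalData, extra_X=None, ties: str = "efron") -> "CoxPH":
        """Build from clinical metadata, optionally prepending feature columns."""
        Z = survival.design()
        if extra_X is not None:
            if not isinstance(extra_X, pd.DataFrame):
                extra_X = pd.DataFrame(np.atleast_2d(np.asarray(extra_X, float)),
                                       index=Z.index)
            X = pd.concat([extra_X, Z], axis=1)
        else:
            X = Z
        return cls(X, survival.time, survival.event, ties=ties)

    def fit(self, tol: float = 1e-9, max_iter: int = 100,
            ridge: float = 0.0) -> CoxPHResults:
        """Maximize the partial likelihood.

        ``ridge`` adds an L2 penalty (ridge/2)*||beta||^2 to the negative
        log-likelihood, the standard stabilization when a covariate level
        separates the risk sets (monotone likelihood) in a small cohort.
        """
        X, names = self.X, list(self.names)
        # constant columns carry no partial-likelihood information: flag, drop
        keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        Xf = X[:, keep]
        kept_names = [names[j] for j in keep]
        order = np.argsort(-self.time, kind="stable")
        Xs, ts, es = Xf[order], self.time[order], self.event[order]
        p = Xf.shape[1]

        def penalized(beta):
            ll, grad, hess = _loglik_grad_hess(beta, Xs, ts, es, self.ties)
            if ridge > 0:
                ll -= 0.5 * ridge * float(beta @ beta)
                grad = grad - ridge * beta
                hess = hess - ridge * np.eye(p)
            return ll, grad, hess

        beta = np.zeros(p)
        ll, grad, hess = penalized(beta)
        ll_null = ll
        converged = False
        monotone = False
        for _ in range(max_iter):
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
            # step halving keeps the likelihood ascent monotone
            factor = 1.0
            for _ in range(30):
                cand = beta + factor * step
                ll_new, grad_new, hess_new = penalized(cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                factor /= 2.0
            delta = np.abs(cand - beta).max() if p else 0.0
            beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
            if np.abs(beta).max() > _MONOTONE_BETA_BOUND:
                monotone = True
                break
            if delta < tol or (p and np.abs(grad).max() < tol):
                converged = True
                break

        if p:
            try:
                cov = np.linalg.inv(-hess)
                bse = np.sqrt(np.clip(np.diag(cov), 0, None))
            except np.linalg.LinAlgError:
                cov = np.full((p, p), np.nan)
                bse = np.full(p, np.nan)
        else:
            cov = np.zeros((0, 0))
            bse = np.zeros(0)

        params = pd.Series(np.nan, index=names, name="coef")
        params[kept_names] = beta
        bse_s = pd.Series(np.nan, index=names, name="se")
        bse_s[kept_names] = bse
        cov_df = pd.DataFrame(np.nan, index=names, columns=names)
        cov_df.loc[kept_names, kept_names] = cov
        return CoxPHResults(
            params=params, bse=bse_s, cov_params=cov_df,
            loglik=float(ll), loglik_null=float(ll_null),
            n=int(self.time.size), n_events=int(self.event.sum()),
            ties=self.ties, converged=converged and not monotone,
            monotone=monotone, dropped=dropped, model=self,
        )

    def baseline_cumulative_hazard(self, results: CoxPHResults) -> pd.Series:
        """Breslow estimator of the baseline cumulative hazard at each time."""
        beta = results.params.fillna(0.0).to_numpy()
        eta = self.X @ beta
        w = np.exp(eta - eta.mean())
        order = np.argsort(self.time, kind="stable")
        t_sorted = self.time[order]
        uniq = np.unique(t_sorted[self.event[order] == 1])
        h0 = []
        cum = 0.0
        for t in uniq:
            at_risk = w[self.time >= t].sum()
            d = int(((self.time == t) & (self.event == 1)).sum())
            cum += d / at_risk
            h0.append((t, cum))
        times = np.array([t for t, _ in h0])
        H = np.array([c for _, c in h0])
        # rescale back: w used exp(eta - mean), so H0 absorbs exp(mean(eta))
        H = H * np.exp(-eta.mean())
        return pd.Series(H, index=times, name="H0")

    def martingale_residuals(self, results: CoxPHResults) -> np.ndarray:
        """delta_i - H0(T_i) exp(eta_i) under the fitted model."""
        H0 = self.baseline_cumulative_hazard(results)
        beta = results.params.fillna(0.0).to_numpy()
        eta = self.X @ beta
        times = H0.index.to_numpy()
        vals = H0.to_numpy()
        idx = np.searchsorted(times, self.time, side="right") - 1
        H_at = np.where(idx >= 0, vals[np.clip(idx, 0, None)], 0.0)
        return self.event - H_at * np.exp(eta)


def cox_fit(X, time=None, event=None, survival: SurvivalData | None = None,
            ties: str = "efron") -> CoxPHResults:
    """Convenience wrapper: fit a Cox model and return its results."""
    if survival is not None:
        model = CoxPH.from_survival(survival, extra_X=X, ties=ties)
    else:
        model = CoxPH(X, time, event, ties=ties)
    return model.fit()
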