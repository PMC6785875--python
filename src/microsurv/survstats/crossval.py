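"""Cross-validated lambda choice for the elastic-net Cox path.

Per-fold prediction error uses the Verweij & van Houwelingen partial-deviance
construction (the cv.glmnet "deviance" measure for Cox models): for fold k,
the fold's contribution is D_all(beta_k) - D_train(beta_k), the deviance of
the full data minus that of the training data at the coefficients fitted
without fold k. Folds are event-stratified so events are spread as evenly as
possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._rng import as_rng
from .coxnet import CoxnetPath, CoxnetPathResults, _breslow_loglik_batch, _sorted_problem


def event_stratified_folds(event, n_folds: int, rng) -> np.ndarray:
    """Assign samples to folds, dealing events and censored separately."""
    event = np.asarray(event, dtype=int)
    n = event.size
    if n_folds < 2 or n_folds > n:
        raise ValueError("need 2 <= folds <= n")
    rng = as_rng(rng)
    assignment = np.empty(n, dtype=np.int64)
    for group in (np.flatnonzero(event == 1), np.flatnonzero(event == 0)):
        perm = rng.permutation(group)
        assignment[perm] = np.arange(perm.size) % n_folds
    return assignment


@dataclass
class CVCoxnetResults:
    """Chosen lambda with the full-data refit at that lambda."""

    lambdas: np.ndarray
    cvm: np.ndarray
    cvse: np.ndarray
    lambda_min: float
    lambda_1se: float
    lambda_rule: str
    coefficients: pd.Series       # full-data coefficients at the chosen lambda
    feature_names: list
    covariate_names: list

    @property
    def lambda_chosen(self) -> float:
        return self.lambda_min if self.lambda_rule == "min" else self.lambda_1se

    @property
    def selected(self) -> list:
        coefs = self.coefficients[self.feature_names]
        return list(coefs.index[coefs != 0])

    @property
    def selection_indicator(self) -> pd.Series:
        coefs = self.coefficients[self.feature_names]
        return (coefs != 0).astype(int)


def cv_coxnet(
    X_pen,
    X_unpen,
    time,
    event,
    alpha: float = 0.5,
    folds: int = 10,
    rng=None,
    lambdas=None,
    n_lambda: int = 50,
    lambda_rule: str = "min",
    tol: float = 1e-7,
    max_refold: int = 10,
    full_path: CoxnetPathResults | None = None,
) -> CVCoxnetResults:
    """K-fold cross-validated elastic-net Cox fit.

    Returns the CV deviance curve, the deviance-minimizing ``lambda_min`` and
    the one-standard-error ``lambda_1se``, and the full-data coefficients
    refit at the lambda selected by ``lambda_rule`` ("min" or "1se").
    """
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")
    rng = as_rng(rng)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if full_path is not None and lambdas is None:
        lambdas = full_path.lambdas
    model = full_path.model if full_path is not None else CoxnetPath(
        X_pen, X_unpen, time, event, alpha=alpha)
    if lambdas is None:
        lambdas = model.lambda_ladder(n_lambda=n_lambda)
    lambdas = np.asarray(lambdas, dtype=float)

    X_pen_arr = np.asarray(X_pen, dtype=float)
    X_unpen_arr = (np.zeros((X_pen_arr.shape[0], 0)) if X_unpen is None
                   else np.asarray(X_unpen, dtype=float))
    X_all = np.hstack([X_pen_arr, X_unpen_arr])
    n = X_all.shape[0]

    # refold until every training set contains an event
    for _ in range(max_refold):
        assignment = event_stratified_folds(event, folds, rng)
        ok = all(event[assignment != k].sum() >= 1 for k in range(folds))
        if ok:
            break
    else:
        raise ValueError("could not construct folds with events in every training set")

    order_all, _, ev_all, grp_all = _sorted_problem(time, event)
    fold_dev = np.zeros((folds, len(lambdas)))
    for k in range(folds):
        train = assignment != k
        sub = CoxnetPath(X_pen_arr[train], X_unpen_arr[train] if X_unpen_arr.shape[1] else None,
                         time[train], event[train], alpha=alpha)
        path = sub.fit(lambdas=lambdas, tol=tol)
        order_tr, _, ev_tr, grp_tr = _sorted_problem(time[train], event[train])
        betas = path.coefficients.to_numpy()  # (L, p) on input scale
        etas = X_all @ betas.T                # (n, L)
        ll_all = _breslow_loglik_batch(np.ascontiguousarray(etas[order_all]),
                                       ev_all, grp_all)
        ll_train = _breslow_loglik_batch(np.ascontiguousarray(etas[train][order_tr]),
                                         ev_tr, grp_tr)
        fold_dev[k] = -2.0 * (ll_all - ll_train)

    cvm = fold_dev.mean(axis=0)
    cvse = fold_dev.std(axis=0, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(cvm))
    lambda_min = float(lambdas[i_min])
    within = np.flatnonzero(cvm <= cvm[i_min] + cvse[i_min])
    lambda_1se = float(lambdas[within.min()])  # ladder is decreasing: first = largest

    chosen = lambda_min if lambda_rule == "min" else lambda_1se
    if full_path is None:
        full_path = model.fit(lambdas=lambdas, tol=tol)
    li = int(np.argmin(np.abs(lambdas - chosen)))
    coefs = full_path.coefficients.iloc[li]
    return CVCoxnetResults(
        lambdas=lambdas, cvm=cvm, cvse=cvse,
        lambda_min=lambda_min, lambda_1se=lambda_1se, lambda_rule=lambda_rule,
        coefficients=coefs,
        feature_names=model.feature_names, covariate_names=model.covariate_names,
    )
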