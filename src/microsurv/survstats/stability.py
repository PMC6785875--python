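"""Stability selection over repeated cross-validated elastic-net Cox fits.

The procedure repeats K-fold cross-validated elastic-net Cox regression R
times (500 x 10-fold in the reference configuration), each repetition with an
independent fold assignment, and counts how often each feature's coefficient
is nonzero at that repetition's chosen lambda. Alongside, each feature gets a
companion covariate-adjusted unpenalized Cox fit whose p-values are
Benjamini-Hochberg adjusted within the table. A feature is called when its
selection count reaches the count threshold (>= 25% of repetitions by
default) and its FDR q-value is below the q threshold (0.20 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .._rng import as_rng
from ..containers import SurvivalData
from .coxnet import CoxnetPath
from .coxph import CoxPH
from .crossval import cv_coxnet


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def per_feature_cox(X_pen: pd.DataFrame, X_unpen, time, event,
                    ties: str = "efron") -> pd.DataFrame:
    """Covariate-adjusted unpenalized Cox fit for each feature separately.

    Returns per-feature coefficient, HR, CI, Wald p, BH q (adjusted within
    this table) and convergence flags.
    """
    rows = []
    Xu = None if X_unpen is None else np.asarray(X_unpen, dtype=float)
    for name in X_pen.columns:
        x = X_pen[name].to_numpy(dtype=float)[:, None]
        design = x if Xu is None else np.hstack([x, Xu])
        try:
            res = CoxPH(design, time, event, ties=ties).fit()
            coef = float(res.params.iloc[0])
            se = float(res.bse.iloc[0])
            p = float(res.pvalues.iloc[0])
            ci = res.conf_int().iloc[0]
            rows.append({"feature": name, "coef": coef, "HR": np.exp(coef),
                         "hr_lower": ci["hr_lower"], "hr_upper": ci["hr_upper"],
                         "se": se, "p": p,
                         "converged": res.converged, "monotone": res.monotone})
        except ValueError:
            rows.append({"feature": name, "coef": np.nan, "HR": np.nan,
                         "hr_lower": np.nan, "hr_upper": np.nan, "se": np.nan,
                         "p": np.nan, "converged": False, "monotone": False})
    out = pd.DataFrame(rows).set_index("feature")
    valid = out["p"].notna()
    out["q"] = np.nan
    if valid.any():
        out.loc[valid, "q"] = bh_fdr(out.loc[valid, "p"].to_numpy())
    return out


@dataclass
class StabilityResults:
    """Selection counts, signs and companion per-feature Cox statistics."""

    table: pd.DataFrame       # indexed by feature
    repeats: int
    folds: int
    alpha: float
    lambda_rule: str

    def summary(self) -> pd.DataFrame:
        return self.table.copy()

    def selected(self, count_threshold: int, q_threshold: float) -> list:
        t = self.table
        mask = (t["selection_count"] >= count_threshold) & (t["q"] < q_threshold)
        return list(t.index[mask.fillna(False)])


class StabilitySelector:
    """Repeated cross-validated elastic-net Cox selection.

    Parameters
    ----------
    X_pen
        Penalized (clr-scale) feature DataFrame, samples x features.
    survival
        :class:`SurvivalData` supplying the outcome and the six unpenalized
        clinical covariates; alternatively pass ``time``/``event`` arrays and
        an explicit ``X_unpen``.
    repeats, folds
        Number of repetitions and CV folds (500 x 10 in the reference
        configuration).
    lambda_rule
        "min" (deviance-minimizing, default) or "1se".
    """

    def __init__(self, X_pen: pd.DataFrame, survival: SurvivalData | None = None,
                 X_unpen=None, time=None, event=None, alpha: float = 0.5,
                 folds: int = 10, repeats: int = 500, n_lambda: int = 50,
                 lambda_rule: str = "min", cv_tol: float = 1e-7):
        if not isinstance(X_pen, pd.DataFrame):
            X_pen = pd.DataFrame(np.asarray(X_pen, dtype=float))
        self.X_pen = X_pen
        if survival is not None:
            self.X_unpen = survival.design()
            self.time = survival.time
            self.event = survival.event
        else:
            self.X_unpen = X_unpen
            self.time = np.asarray(time, dtype=float)
            self.event = np.asarray(event, dtype=int)
        if repeats < 1:
            raise ValueError("repeats must be >= 1")
        self.alpha = alpha
        self.folds = folds
        self.repeats = repeats
        self.n_lambda = n_lambda
        self.lambda_rule = lambda_rule
        self.cv_tol = cv_tol

    def fit(self, rng=None) -> StabilityResults:
        rng = as_rng(rng)
        features = list(self.X_pen.columns)
        counts = pd.Series(0, index=features, dtype=int)
        sign_sum = pd.Series(0.0, index=features)

        # the full-data path is repetition-invariant: fit once, reuse
        model = CoxnetPath(self.X_pen, self.X_unpen, self.time, self.event,
                           alpha=self.alpha)
        lambdas = model.lambda_ladder(n_lambda=self.n_lambda)
        full_path = model.fit(lambdas=lambdas, tol=self.cv_tol)

        # one independent substream per repetition so results do not depend
        # on feature order or on each other's draw counts
        seeds = rng.bit_generator.seed_seq.spawn(self.repeats)
        for r in range(self.repeats):
            rep_rng = np.random.default_rng(seeds[r])
            cv = cv_coxnet(self.X_pen, self.X_unpen, self.time, self.event,
                           alpha=self.alpha, folds=self.folds, rng=rep_rng,
                           lambdas=lambdas, lambda_rule=self.lambda_rule,
                           tol=self.cv_tol, full_path=full_path)
            coefs = cv.coefficients[features]
            counts += (coefs != 0).astype(int)
            sign_sum += np.sign(coefs)

        companion = per_feature_cox(self.X_pen, self.X_unpen, self.time, self.event)
        table = pd.DataFrame({
            "selection_count": counts,
            "selection_frequency": counts / self.repeats,
            "sign_consensus": np.sign(sign_sum),
        })
        table = table.join(companion)
        return StabilityResults(table=table, repeats=self.repeats,
                                folds=self.folds, alpha=self.alpha,
                                lambda_rule=self.lambda_rule)


def stability_selection(X_pen, X_unpen, time, event, repeats: int = 500,
                        folds: int = 10, alpha: float = 0.5, rng=None,
                        **kwargs) -> StabilityResults:
    """Functional wrapper around :class:`StabilitySelector`."""
    sel = StabilitySelector(X_pen, X_unpen=X_unpen, time=time, event=event,
                            alpha=alpha, folds=folds, repeats=repeats, **kwargs)
    return sel.fit(rng=rng)


def select_features(stability_by_datatype: dict[str, StabilityResults],
                    count_threshold: int, q_threshold: float) -> pd.DataFrame:
    """Dual-criterion feature call, unioned across data types.

    A feature is selected when, within at least one data type, its selection
    count meets ``count_threshold`` (>= comparison) and its q-value is below
    ``q_threshold``. The returned table records which data type(s) triggered
    the call.
    """
    for name, res in stability_by_datatype.items():
        if count_threshold > res.repeats:
            raise ValueError(
                f"count threshold {count_threshold} exceeds repeats {res.repeats} "
                f"for data type {name!r}")
    provenance: dict[str, list[str]] = {}
    for dtype, res in stability_by_datatype.items():
        for feat in res.selected(count_threshold, q_threshold):
            provenance.setdefault(feat, []).append(dtype)
    rows = []
    for feat, dtypes in sorted(provenance.items()):
        rows.append({"feature": feat, "provenance": ",".join(sorted(dtypes))})
    return pd.DataFrame(rows, columns=["feature", "provenance"])
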