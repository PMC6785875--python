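"""Metagenome-metatranscriptome integration.

Functional features (pathways/reactions/gene families) that pass stability
selection and the FDR screen are additionally gated on having positively
correlated metatranscriptomic expression (Spearman p < 0.05 on the
metatranscriptome sample subset). Relative expression (RNA/DNA ratio,
independent of gene copy number), per-species pathway contribution summaries
and per-(species, pathway) covariate-adjusted Cox fits complete the
functional picture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureTable, StratifiedFunctionTable, SurvivalData
from .survstats.coxph import CoxPH
from .survstats.stability import StabilityResults


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str
    defined: bool = True


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p via the t approximation; for n <= 9 the exact permutation
    distribution of rho is enumerated instead. Constant input leaves rho
    undefined (flagged, not raised).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(np.nan, np.nan, n, "undefined", defined=False)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        # exact permutation null of the rank correlation
        from itertools import permutations

        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
        obs = abs((rx_c * ry_c).sum() / denom)
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = abs((rx_c[list(perm)] * ry_c).sum() / denom)
            count += r >= obs - 1e-12
            total += 1
        return SpearmanResult(rho, count / total, n, "exact-permutation")
    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho, float(min(p, 1.0)), n, "t-approximation")


def mgx_mtx_correlations(mgx_total: pd.DataFrame, mtx_total: pd.DataFrame,
                         features=None) -> pd.DataFrame:
    """Per-feature Spearman correlation of DNA vs RNA relative abundance,
    computed on the shared (metatranscriptome) samples."""
    shared_samples = mtx_total.index.intersection(mgx_total.index)
    feats = list(features) if features is not None else list(mgx_total.columns)
    rows = []
    for f in feats:
        if f not in mgx_total.columns or f not in mtx_total.columns:
            rows.append({"feature": f, "rho": np.nan, "p": np.nan,
                         "n": len(shared_samples), "defined": False})
            continue
        res = spearman(mgx_total.loc[shared_samples, f],
                       mtx_total.loc[shared_samples, f])
        rows.append({"feature": f, "rho": res.rho, "p": res.p_value,
                     "n": res.n, "defined": res.defined})
    return pd.DataFrame(rows).set_index("feature")


def mgx_mtx_gate(stability: StabilityResults, correlations: pd.DataFrame,
                 count_threshold: int, q_threshold: float,
                 p_threshold: float = 0.05,
                 require_positive: bool = True) -> pd.DataFrame:
    """Triple-criterion gate for functional features.

    A feature passes when (a) its stability-selection count reaches
    ``count_threshold``, (b) its FDR q-value is below ``q_threshold``, and
    (c) its metatranscriptomic expression is correlated (Spearman
    p < ``p_threshold``; positive rho required by default). Returns the full
    audit table with per-criterion flags and the ``gated`` indicator.
    """
    t = stability.table
    audit = pd.DataFrame(index=t.index)
    audit["selection_count"] = t["selection_count"]
    audit["q"] = t["q"]
    audit["pass_count"] = t["selection_count"] >= count_threshold
    audit["pass_q"] = (t["q"] < q_threshold).fillna(False)
    corr = correlations.reindex(t.index)
    audit["rho"] = corr["rho"]
    audit["corr_p"] = corr["p"]
    pass_corr = (corr["p"] < p_threshold).fillna(False)
    if require_positive:
        pass_corr &= (corr["rho"] > 0).fillna(False)
    audit["pass_corr"] = pass_corr
    audit["gated"] = audit["pass_count"] & audit["pass_q"] & audit["pass_corr"]
    return audit


def relative_expression(mtx: StratifiedFunctionTable, mgx: StratifiedFunctionTable,
                        smoothing: float | None = None,
                        log2: bool = False) -> FeatureTable:
    """Per-feature RNA/DNA ratio on the shared samples.

    Zeros in the DNA denominator are Laplace-smoothed: ratio =
    (RNA + s) / (DNA + s) with ``s`` defaulting to half the smallest nonzero
    DNA abundance per feature. Features absent from the DNA table are
    excluded (flagged via the feature metadata).
    """
    samples = mtx.total.index.intersection(mgx.total.index)
    shared = [f for f in mtx.total.columns if f in mgx.total.columns]
    skipped = [f for f in mtx.total.columns if f not in mgx.total.columns]
    rna = mtx.total.loc[samples, shared]
    dna = mgx.total.loc[samples, shared]
    out = {}
    for f in shared:
        d = dna[f].to_numpy(dtype=float)
        r = rna[f].to_numpy(dtype=float)
        if smoothing is None:
            nz = d[d > 0]
            s = float(nz.min() / 2.0) if nz.size else 1e-12
        else:
            s = float(smoothing)
        ratio = (r + s) / (d + s)
        out[f] = np.log2(ratio) if log2 else ratio
    values = pd.DataFrame(out, index=samples)
    table = FeatureTable(values.clip(lower=0.0), level="pathway")
    table.skipped_features = skipped  # RNA features with no DNA counterpart
    return table


def species_contribution(stratified: StratifiedFunctionTable,
                         top_n: int = 5) -> pd.DataFrame:
    """Mean per-species percent contribution to each pathway.

    Species shares are normalized to 100% per pathway within each sample
    (samples where the pathway is absent are excluded from that pathway's
    mean), then averaged across samples; the ``rank`` column orders species
    within each pathway and ``top`` flags the top ``top_n`` contributors.
    """
    rows = []
    for pw in stratified.pathways:
        strat = stratified.stratified.get(pw)
        if strat is None or strat.to_numpy().sum() == 0:
            continue
        totals = strat.sum(axis=1)
        present = totals > 0
        if not present.any():
            continue
        shares = strat.loc[present].div(totals[present], axis=0) * 100.0
        mean_share = shares.mean(axis=0).sort_values(ascending=False)
        for rank, (sp, share) in enumerate(mean_share.items(), start=1):
            rows.append({"pathway": pw, "species": sp, "mean_percent": float(share),
                         "rank": rank, "top": rank <= top_n,
                         "n_samples": int(present.sum())})
    return pd.DataFrame(rows, columns=["pathway", "species", "mean_percent",
                                       "rank", "top", "n_samples"])


def per_species_pathway_cox(stratified: StratifiedFunctionTable,
                            survival: SurvivalData,
                            pseudocount: float | None = None) -> pd.DataFrame:
    """Covariate-adjusted Cox fit per (species, pathway) stratum.

    Each nonzero stratum's abundance vector is clr-transformed jointly with
    the other strata (one composition per sample over all strata) and tested
    in its own adjusted model. Non-converging combinations are flagged, not
    dropped.
    """
    from .compositional import clr_transform

    strat = stratified.stratified.loc[survival.patient_ids]
    nonzero = [c for c in strat.columns if strat[c].to_numpy().sum() > 0]
    strat = strat[nonzero]
    flat = strat.copy()
    flat.columns = [f"{pw}|{sp}" for pw, sp in strat.columns]
    ft = FeatureTable(flat, level="pathway")
    clr = clr_transform(ft, pseudocount=pseudocount)
    rows = []
    for (pw, sp), col in zip(strat.columns, clr.values.columns):
        x = clr.values[col].to_numpy()[:, None]
        model = CoxPH.from_survival(survival, extra_X=pd.DataFrame(
            x, index=survival.patient_ids, columns=[col]))
        res = model.fit()
        rows.append({
            "pathway": pw, "species": sp,
            "coef": res.params.iloc[0], "HR": float(np.exp(res.params.iloc[0])),
            "hr_lower": res.conf_int().iloc[0, 0], "hr_upper": res.conf_int().iloc[0, 1],
            "p": res.pvalues.iloc[0],
            "converged": res.converged, "monotone": res.monotone,
        })
    return pd.DataFrame(rows, columns=["pathway", "species", "coef", "HR",
                                       "hr_lower", "hr_upper", "p",
                                       "converged", "monotone"])
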