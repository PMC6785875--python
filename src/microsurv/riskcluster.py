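"""Beta-diversity risk clustering and survival comparison.

Patients are clustered on a beta-diversity distance matrix with Ward's
hierarchical agglomerative method (Ward.D2 on distances by default), the two
clusters per platform are tagged low/high risk by Kaplan-Meier median PFS,
and the 16S/shotgun cluster pair defines three combined groups: low risk
(concordantly low), high risk (concordantly high) and intermediate
(discordant). Group survival is compared with Kaplan-Meier curves and the
log-rank test.

Note: tagging each platform's clusters by observed median PFS before
log-rank testing makes the combined-group test partially circular; this
mirrors the original design and is flagged here deliberately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from .containers import SurvivalData

RISK_LOW, RISK_INTERMEDIATE, RISK_HIGH = "low", "intermediate", "high"


def ward_cluster(dm: DistanceMatrix | np.ndarray, k: int,
                 variant: str = "ward.D2", ids=None) -> pd.Series:
    """Cut a Ward dendrogram of the distance matrix into ``k`` clusters.

    ``variant="ward.D2"`` applies the Lance-Williams Ward update to squared
    dissimilarities (scipy's ``ward`` on the distances); ``"ward.D"`` applies
    it to the dissimilarities as given, computed here by running Ward.D2 on
    the elementwise square root. Labels are arbitrary {1..k}.
    """
    if isinstance(dm, DistanceMatrix):
        ids = list(dm.ids)
        arr = dm.data
    else:
        arr = np.asarray(dm, dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if ids is None:
            ids = list(range(arr.shape[0]))
    n = arr.shape[0]
    if not (2 <= k <= n):
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    if variant == "ward.D2":
        condensed = squareform(arr, checks=False)
    elif variant == "ward.D":
        condensed = squareform(np.sqrt(arr), checks=False)
    else:
        raise ValueError("variant must be 'ward.D' or 'ward.D2'")
    Z = linkage(condensed, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=ids, name="cluster")


def km_median(time: np.ndarray, event: np.ndarray) -> float:
    """Kaplan-Meier median survival time (inf if the curve stays above 0.5)."""
    kmf = KaplanMeierFitter().fit(time, event)
    return float(kmf.median_survival_time_)


def assign_risk_groups(labels_16s: pd.Series, labels_shotgun: pd.Series,
                       survival: SurvivalData) -> pd.DataFrame:
    """Concordance risk grouping across the two platforms.

    Within each platform the cluster with the longer Kaplan-Meier median PFS
    is tagged low risk (ties broken by the lower event fraction). Patients
    concordantly low in both platforms form the low-risk group, concordantly
    high the high-risk group, and discordant patients the intermediate group.
    """
    ids = list(survival.patient_ids)
    for name, lab in (("16S", labels_16s), ("shotgun", labels_shotgun)):
        diff = set(ids).symmetric_difference(lab.index)
        if diff:
            raise ValueError(f"{name} labels do not cover the survival patients: {sorted(diff)}")
        if lab.nunique() != 2:
            raise ValueError(f"{name} labeling must have exactly 2 clusters for risk grouping")

    def low_cluster(lab: pd.Series) -> int:
        stats = {}
        for c in sorted(lab.unique()):
            members = lab.index[lab == c]
            sub = survival.frame.loc[members]
            med = km_median(sub["time"].to_numpy(), sub["event"].to_numpy())
            stats[c] = (med, -sub["event"].mean())
        # longer median PFS wins; tie-break: lower event fraction
        return max(stats, key=lambda c: stats[c])

    low16 = low_cluster(labels_16s.loc[ids])
    lowsg = low_cluster(labels_shotgun.loc[ids])
    out = pd.DataFrame(index=ids)
    out["cluster_16s"] = labels_16s.loc[ids]
    out["cluster_shotgun"] = labels_shotgun.loc[ids]
    out["risk_16s"] = np.where(out["cluster_16s"] == low16, "low", "high")
    out["risk_shotgun"] = np.where(out["cluster_shotgun"] == lowsg, "low", "high")
    combined = np.where(
        (out["risk_16s"] == "low") & (out["risk_shotgun"] == "low"), RISK_LOW,
        np.where((out["risk_16s"] == "high") & (out["risk_shotgun"] == "high"),
                 RISK_HIGH, RISK_INTERMEDIATE))
    out["combined_group"] = combined
    return out


def kaplan_meier(survival: SurvivalData, groups: pd.Series) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group.

    Returns, per group, a DataFrame of event times with the survival
    probability after each (right-continuous steps at event times only).
    """
    if len(groups) == 0:
        raise ValueError("empty grouping")
    out = {}
    for g in pd.unique(groups):
        members = groups.index[groups == g]
        if len(members) == 0:
            raise ValueError(f"group {g!r} is empty")
        sub = survival.frame.loc[members]
        kmf = KaplanMeierFitter().fit(sub["time"], sub["event"])
        sf = kmf.survival_function_
        out[str(g)] = pd.DataFrame({
            "time": sf.index.to_numpy(),
            "survival": sf.iloc[:, 0].to_numpy(),
        })
    return out


def logrank_test(survival: SurvivalData, groups: pd.Series) -> tuple[float, int, float]:
    """Log-rank test across groups; returns (chi-square, df, p)."""
    groups = groups.loc[survival.patient_ids]
    n_groups = groups.nunique()
    if n_groups < 2:
        raise ValueError("log-rank test requires at least two nonempty groups")
    if survival.n_events == 0:
        raise ValueError("log-rank test requires at least one event")
    res = multivariate_logrank_test(survival.time, groups.to_numpy(), survival.event)
    return float(res.test_statistic), int(n_groups - 1), float(res.p_value)
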