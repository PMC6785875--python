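"""Core in-memory containers shared across the pipeline.

Feature tables are pandas DataFrames oriented samples x features throughout;
phylogenies are :class:`skbio.TreeNode` and distance matrices
:class:`skbio.DistanceMatrix`, so the standard ecosystem tooling applies
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Design-matrix columns for the clinical adjustment set, in reporting order.
#: Metastatic-site count is an ordinal three-level factor ("0", "1-2", ">=3")
#: encoded as two indicator contrasts against the "0 sites" reference.
COVARIATE_COLUMNS = [
    "age",
    "sex",
    "bmi",
    "stage",
    "met_sites_1_2",
    "met_sites_3plus",
    "antibiotics",
]

#: Raw clinical metadata columns expected at ingestion.
METADATA_COLUMNS = ["time", "event", "age", "sex", "bmi", "stage", "met_sites", "antibiotics"]

MET_SITES_LEVELS = ["0", "1-2", ">=3"]

FEATURE_LEVELS = (
    "s-OTU",
    "genus",
    "species",
    "subspecies",
    "pathway",
    "reaction",
    "gene-family",
)


@dataclass
class FeatureTable:
    """Samples x features abundance matrix with feature identity metadata.

    Parameters
    ----------
    values
        Nonnegative abundances; rows are samples, columns are features.
    level
        Feature resolution, one of :data:`FEATURE_LEVELS`.
    feature_meta
        Optional per-feature metadata (e.g. a ``taxonomy`` column holding
        Greengenes-style rank-prefixed strings), indexed by feature id.
    """

    values: pd.DataFrame
    level: str
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.level not in FEATURE_LEVELS:
            raise ValueError(f"unknown feature level {self.level!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("feature table values must be numeric")
        if np.isnan(arr).any():
            raise ValueError("feature table contains missing values")
        if (arr < 0).any():
            raise ValueError("feature table contains negative values")
        if self.feature_meta is not None:
            missing = self.values.columns.difference(self.feature_meta.index)
            if len(missing):
                raise ValueError(f"feature_meta missing entries for: {list(missing)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def is_counts(self) -> bool:
        """True when every cell is a nonnegative integer (count data)."""
        arr = self.values.to_numpy()
        return bool(np.all(np.equal(np.mod(arr, 1), 0)))

    @property
    def is_relabund(self) -> bool:
        """True when every row closes to 1 (relative-abundance data)."""
        sums = self.values.to_numpy().sum(axis=1)
        return bool(np.allclose(sums, 1.0, atol=1e-9))

    def subset_features(self, keep) -> "FeatureTable":
        keep = [f for f in self.feature_ids if f in set(keep)]
        meta = None if self.feature_meta is None else self.feature_meta.loc[keep]
        return FeatureTable(self.values[keep].copy(), self.level, meta)

    def subset_samples(self, keep) -> "FeatureTable":
        keep = [s for s in self.sample_ids if s in set(keep)]
        return FeatureTable(self.values.loc[keep].copy(), self.level, self.feature_meta)


@dataclass
class ClrTable:
    """Centered log-ratio transformed table; rows sum to zero by construction."""

    values: pd.DataFrame
    pseudocount: float
    level: str = "species"

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        sums = self.values.to_numpy().sum(axis=1)
        if not np.allclose(sums, 0.0, atol=1e-8):
            raise ValueError("clr rows must sum to zero")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)


class SurvivalData:
    """Right-censored follow-up with the six clinical adjustment covariates.

    The underlying frame is indexed by patient id and holds ``time`` (months,
    positive), ``event`` (1 = progression or death, 0 = censored), and the
    covariates ``age``, ``sex``, ``bmi``, ``stage`` (0 = III, 1 = IV),
    ``met_sites`` (categorical "0"/"1-2"/">=3") and ``antibiotics``
    (any use in the prior six months).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        frame = frame.copy()
        frame["met_sites"] = frame["met_sites"].astype(str)
        bad_time = frame.index[~(frame["time"] > 0)].tolist()
        if bad_time:
            raise ValueError(f"nonpositive follow-up time for patients: {bad_time}")
        if not frame["event"].isin([0, 1]).all():
            bad = frame.index[~frame["event"].isin([0, 1])].tolist()
            raise ValueError(f"event indicator must be 0/1; offending patients: {bad}")
        bad_ms = frame.index[~frame["met_sites"].isin(MET_SITES_LEVELS)].tolist()
        if bad_ms:
            raise ValueError(f"met_sites must be one of {MET_SITES_LEVELS}; offending: {bad_ms}")
        num_cols = ["time", "event", "age", "sex", "bmi", "stage", "antibiotics"]
        if frame[num_cols].isna().any().any():
            bad = frame.index[frame[num_cols].isna().any(axis=1)].tolist()
            raise ValueError(f"missing covariate values for patients: {bad}")
        self.frame = frame

    @property
    def patient_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def time(self) -> np.ndarray:
        return self.frame["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.frame["event"].to_numpy(dtype=int)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def design(self) -> pd.DataFrame:
        """Covariate design matrix with the ordinal metastatic-site contrasts."""
        f = self.frame
        out = pd.DataFrame(index=f.index)
        out["age"] = f["age"].astype(float)
        out["sex"] = f["sex"].astype(float)
        out["bmi"] = f["bmi"].astype(float)
        out["stage"] = f["stage"].astype(float)
        out["met_sites_1_2"] = (f["met_sites"] == "1-2").astype(float)
        out["met_sites_3plus"] = (f["met_sites"] == ">=3").astype(float)
        out["antibiotics"] = f["antibiotics"].astype(float)
        return out[COVARIATE_COLUMNS]

    def subset(self, patient_ids) -> "SurvivalData":
        return SurvivalData(self.frame.loc[list(patient_ids)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"SurvivalData(n={self.n}, events={self.n_events})"


@dataclass
class StratifiedFunctionTable:
    """Pathway abundance with its per-species decomposition.

    ``total`` is samples x pathways; ``stratified`` is samples x
    (pathway, species) with a two-level column MultiIndex. For every sample
    and pathway the species strata may sum to at most the total (an
    unclassified remainder is allowed).
    """

    total: pd.DataFrame
    stratified: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.stratified.columns, pd.MultiIndex):
            raise ValueError("stratified columns must be a (pathway, species) MultiIndex")
        if (self.stratified.to_numpy() < 0).any():
            raise ValueError("stratified abundances must be nonnegative")
        strat_sum = self.stratified.T.groupby(level=0).sum().T
        for pw in strat_sum.columns:
            if pw not in self.total.columns:
                raise ValueError(f"stratified pathway {pw!r} absent from total table")
            excess = strat_sum[pw] - self.total[pw]
            if (excess > 1e-8).any():
                raise ValueError(f"species strata exceed total abundance for pathway {pw!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.total.index)

    @property
    def pathways(self) -> list[str]:
        return list(self.total.columns)

    def species_for(self, pathway: str) -> list[str]:
        return list(self.stratified[pathway].columns)

    @property
    def mapping(self) -> dict[str, list[str]]:
        return {pw: self.species_for(pw) for pw in self.stratified.columns.levels[0]}
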