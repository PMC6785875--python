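"""Compositional preprocessing: closure, clr transform, taxonomic
agglomeration, and the prevalence / mean-abundance / variance feature filters.

Sequencing abundances are compositional (each sample closes to a constant
sum), so downstream regression operates on centered log-ratio (clr)
coordinates: clr(x)_j = ln((x_j + p) / g(x + p)) with g the within-sample
geometric mean and p a pseudocount handling zeros. By default the pseudocount
is half the smallest nonzero value of the relative-abundance table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ClrTable, FeatureTable

RANK_PREFIXES = ["k__", "p__", "c__", "o__", "f__", "g__", "s__"]
LEVEL_TO_RANK = {"kingdom": 0, "phylum": 1, "class": 2, "order": 3, "family": 4,
                 "genus": 5, "species": 6}


def to_relative_abundance(table: FeatureTable) -> FeatureTable:
    """Close each sample's abundances to sum 1.

    Raises
    ------
    ValueError
        If any sample has zero total abundance (naming the sample).
    """
    vals = table.values
    totals = vals.sum(axis=1)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"samples with zero total abundance: {zero}")
    rel = vals.div(totals, axis=0)
    return FeatureTable(rel, table.level, table.feature_meta)


def default_pseudocount(table: FeatureTable) -> float:
    """Half the smallest nonzero relative abundance in the table."""
    rel = to_relative_abundance(table).values.to_numpy()
    nz = rel[rel > 0]
    if nz.size == 0:
        raise ValueError("table has no nonzero entries")
    return float(nz.min() / 2.0)


def clr_transform(table: FeatureTable, pseudocount: float | None = None) -> ClrTable:
    """Centered log-ratio transform on the relative-abundance scale.

    Abundances are closed to proportions, the pseudocount is added, and each
    row is log-transformed and centered on its geometric mean, giving
    unconstrained zero-sum coordinates per sample.
    """
    rel = to_relative_abundance(table)
    if pseudocount is None:
        pseudocount = default_pseudocount(table)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logged = np.log(rel.values.to_numpy() + pseudocount)
    centered = logged - logged.mean(axis=1, keepdims=True)
    values = pd.DataFrame(centered, index=rel.values.index, columns=rel.values.columns)
    return ClrTable(values=values, pseudocount=float(pseudocount), level=table.level)


def _taxon_name_at_level(taxonomy: str, level: str, feature_id: str) -> str:
    """Semicolon-joined name down to `level`; empty string if unclassified there."""
    rank_idx = LEVEL_TO_RANK[level]
    parts = [p.strip() for p in taxonomy.split(";")]
    if len(parts) < rank_idx + 1:
        parts = parts + [""] * (rank_idx + 1 - len(parts))
    cleaned = []
    for i, part in enumerate(parts[: rank_idx + 1]):
        prefix = RANK_PREFIXES[i]
        if part and not part.startswith(prefix):
            raise ValueError(
                f"malformed taxonomy for feature {feature_id!r}: expected rank prefix "
                f"{prefix!r} at position {i}, got {part!r}"
            )
        cleaned.append(part)
    # unclassified at the target rank -> empty name, feature is dropped
    if not cleaned[rank_idx] or cleaned[rank_idx] == RANK_PREFIXES[rank_idx]:
        return ""
    return ";".join(cleaned)


def agglomerate_taxa(table: FeatureTable, target_level: str) -> FeatureTable:
    """Sum features sharing the same taxonomy down to ``target_level``.

    Features lacking a classification at the target rank are removed, per the
    convention that agglomerated taxa missing genus- or species-level names
    are excluded from taxon-level analysis. Abundance is conserved over the
    retained features.
    """
    if target_level not in LEVEL_TO_RANK:
        raise ValueError(f"cannot agglomerate to level {target_level!r}")
    if table.feature_meta is None or "taxonomy" not in table.feature_meta.columns:
        raise ValueError("agglomeration requires feature_meta with a 'taxonomy' column")
    names = {}
    for fid in table.feature_ids:
        tax = table.feature_meta.loc[fid, "taxonomy"]
        names[fid] = _taxon_name_at_level(str(tax), target_level, fid)
    keep = [f for f in table.feature_ids if names[f]]
    grouped = table.values[keep].T.groupby(by=[names[f] for f in keep]).sum().T
    grouped = grouped.sort_index(axis=1)
    meta = pd.DataFrame({"taxonomy": grouped.columns}, index=grouped.columns)
    return FeatureTable(grouped, target_level, meta)


def filter_features(
    table: FeatureTable,
    prevalence_min: float = 0.25,
    mean_relabund_min: float = 1e-4,
    variance_quantile: float | None = None,
    pseudocount: float | None = None,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Apply the prevalence / mean-abundance / variance screens.

    A feature is kept when it is present (nonzero) in at least
    ``prevalence_min`` of samples and its mean relative abundance exceeds
    ``mean_relabund_min``. When ``variance_quantile`` is given, features
    passing the first two screens must additionally have clr-scale variance
    above that quantile of the variances among those same features; the
    variance screen is computed on the clr scale because raw-proportion
    variance is dominated by the abundant features.

    Returns the filtered table and a per-feature report
    (prevalence, mean, variance, kept flag, drop reason).
    """
    rel = to_relative_abundance(table)
    vals = rel.values
    prevalence = (vals > 0).mean(axis=0)
    mean_ab = vals.mean(axis=0)

    report = pd.DataFrame({
        "feature": rel.feature_ids,
        "prevalence": prevalence.to_numpy(),
        "mean_relabund": mean_ab.to_numpy(),
        "clr_variance": np.nan,
        "kept": False,
        "reason": "",
    }).set_index("feature")

    pass12 = (prevalence >= prevalence_min) & (mean_ab > mean_relabund_min)
    report.loc[prevalence < prevalence_min, "reason"] = "prevalence"
    low_mean = (prevalence >= prevalence_min) & (mean_ab <= mean_relabund_min)
    report.loc[low_mean[low_mean].index, "reason"] = "mean_relabund"

    kept = list(vals.columns[pass12])
    if variance_quantile is not None and kept:
        clr = clr_transform(rel, pseudocount=pseudocount)
        variances = clr.values[kept].var(axis=0, ddof=1)
        report.loc[kept, "clr_variance"] = variances
        cutoff = np.quantile(variances.to_numpy(), variance_quantile)
        low_var = [f for f in kept if variances[f] < cutoff]
        report.loc[low_var, "reason"] = "variance"
        kept = [f for f in kept if variances[f] >= cutoff]

    report.loc[kept, "kept"] = True
    report.loc[kept, "reason"] = ""
    out = table.subset_features(kept)
    return out, report.reset_index()
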