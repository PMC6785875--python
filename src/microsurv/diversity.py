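"""Alpha and beta diversity.

Alpha diversity (richness and Shannon index, log base 2) is computed on 16S
count tables by averaging over repeated rarefactions to a common depth;
shotgun subspecies tables are summarized without rarefaction since they are
relative abundances. Beta diversity offers the Jensen-Shannon divergence
(natural log, bounded by ln 2) and the weighted UniFrac distance
(non-normalized by default), with principal coordinate analysis for
ordination.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.stats.ordination import pcoa as _skbio_pcoa

from ._rng import as_rng
from .containers import FeatureTable


# ---------------------------------------------------------------------------
# alpha diversity

def rarefy(counts_row: np.ndarray, depth: int, rng) -> np.ndarray:
    """Subsample a single sample's counts to ``depth`` reads without
    replacement (multivariate hypergeometric draw)."""
    counts = np.asarray(counts_row)
    if not np.all(np.equal(np.mod(counts, 1), 0)) or (counts < 0).any():
        raise ValueError("rarefaction requires nonnegative integer counts")
    counts = counts.astype(np.int64)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds sample total {total}")
    rng = as_rng(rng)
    return rng.multivariate_hypergeometric(counts, depth)


def shannon_index(abundances: np.ndarray, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_j log_base p_j over nonzero components."""
    a = np.asarray(abundances, dtype=float)
    total = a.sum()
    if total <= 0:
        return 0.0
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(base))


def richness(abundances: np.ndarray) -> int:
    """Number of features observed (nonzero)."""
    return int(np.count_nonzero(np.asarray(abundances)))


def alpha_rarefied(
    table: FeatureTable,
    depth: int | str = "min-sample",
    iters: int = 100,
    rng=None,
) -> pd.DataFrame:
    """Mean richness and Shannon index over ``iters`` rarefactions per sample.

    ``depth="min-sample"`` rarefies to the lowest sequencing depth among
    samples. Returns a DataFrame indexed by sample with columns ``richness``
    and ``shannon``.
    """
    if not table.is_counts:
        raise ValueError("rarefied alpha diversity requires a count table")
    rng = as_rng(rng)
    counts = table.values.to_numpy().astype(np.int64)
    if depth == "min-sample":
        depth = int(counts.sum(axis=1).min())
    depth = int(depth)
    rich = np.zeros(table.n_samples)
    shan = np.zeros(table.n_samples)
    for _ in range(iters):
        for i in range(table.n_samples):
            sub = rarefy(counts[i], depth, rng)
            rich[i] += richness(sub)
            shan[i] += shannon_index(sub)
    out = pd.DataFrame(
        {"richness": rich / iters, "shannon": shan / iters},
        index=table.values.index,
    )
    return out


def alpha_unrarefied(table: FeatureTable) -> pd.DataFrame:
    """Richness and Shannon index computed directly (no rarefaction)."""
    vals = table.values.to_numpy()
    out = pd.DataFrame(
        {
            "richness": [richness(v) for v in vals],
            "shannon": [shannon_index(v) for v in vals],
        },
        index=table.values.index,
    )
    return out


# ---------------------------------------------------------------------------
# beta diversity

def jsd_matrix(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Jensen-Shannon divergence between sample compositions.

    JSD(P,Q) = KL(P||M)/2 + KL(Q||M)/2 with M = (P+Q)/2, natural logarithm,
    so values lie in [0, ln 2].
    """
    rel = table.values.to_numpy(dtype=float)
    if (rel < 0).any():
        raise ValueError("compositions must be nonnegative")
    sums = rel.sum(axis=1)
    if (sums <= 0).any():
        bad = list(table.values.index[sums <= 0])
        raise ValueError(f"samples with zero total abundance: {bad}")
    rel = rel / sums[:, None]
    # scipy's jensenshannon returns sqrt(JSD) in natural log; square it
    dist = pdist(rel, metric="jensenshannon") ** 2
    return DistanceMatrix(squareform(dist), ids=table.sample_ids)


def weighted_unifrac(
    table: FeatureTable, tree: TreeNode, normalized: bool = False
) -> DistanceMatrix:
    """Weighted UniFrac distance between samples.

    Sums, over tree branches, branch length times the absolute difference in
    the proportion of each sample's abundance descending through the branch.
    Non-normalized by default.
    """
    leaf_names = {t.name for t in tree.tips()}
    missing = [f for f in table.feature_ids if f not in leaf_names]
    if missing:
        raise ValueError(f"features absent from the tree: {missing}")
    counts = table.values.to_numpy(dtype=float)
    return skbio.diversity.beta_diversity(
        "weighted_unifrac",
        counts,
        ids=table.sample_ids,
        taxa=table.feature_ids,
        tree=tree,
        normalized=normalized,
        validate=True,
    )


def pcoa(dm: DistanceMatrix, n_axes: int | None = None):
    """Principal coordinate analysis of a distance matrix.

    Gower-centers -D^2/2 and eigendecomposes it. Returns ``(coordinates,
    eigenvalues)``; negative eigenvalues are reported as-is so the caller can
    assess non-Euclidean distortion (coordinates are only returned for
    positive eigenvalues).
    """
    if not isinstance(dm, DistanceMatrix):
        arr = np.asarray(dm, dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        dm = DistanceMatrix(arr)
    import warnings

    with warnings.catch_warnings():
        # full eigendecomposition is intended: negative eigenvalues must be
        # reported, not silently truncated
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh", inplace=False)
    eigvals = res.eigvals.to_numpy()
    coords = res.samples
    coords.index = list(dm.ids)
    if n_axes is not None:
        coords = coords.iloc[:, :n_axes]
    return coords, eigvals
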