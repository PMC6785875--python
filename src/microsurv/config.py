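"""Analysis configuration.

Houses the analysis constants: rarefaction to the minimum sample depth
averaged over 100 iterations; prevalence >= 25% of samples; mean relative
abundance > 0.01% for taxa and gene families, > 0.03% for pathways and
reactions; clr-variance above the 25th percentile for functional features;
elastic-net mixing alpha = 0.5; 500 x 10-fold cross-validated repetitions
with a selection-count threshold of 125 (25%); FDR q < 0.20; expression
correlation p < 0.05.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field


@dataclass
class AnalysisConfig:
    # input paths (unused when objects are passed directly)
    table_16s: str | None = None
    taxonomy_16s: str | None = None
    table_shotgun: str | None = None
    taxonomy_shotgun: str | None = None
    tree: str | None = None
    metadata: str | None = None
    mgx_total: str | None = None
    mgx_stratified: str | None = None
    mtx_total: str | None = None
    mtx_stratified: str | None = None

    # compositional handling
    pseudocount: float | None = None          # None = half min nonzero
    prevalence_min: float = 0.25
    mean_relabund_min_taxa: float = 1e-4      # 0.01% as a proportion
    mean_relabund_min_pathways: float = 3e-4  # 0.03% as a proportion
    variance_quantile: float = 0.25

    # penalized survival regression
    alpha_mixing: float = 0.5
    cv_folds: int = 10
    cv_repeats: int = 500
    selection_count_threshold: int = 125
    q_threshold: float = 0.20
    correlation_p_threshold: float = 0.05
    lambda_rule: str = "min"
    n_lambda: int = 30

    # diversity
    rarefaction_iters: int = 100
    rarefaction_depth: int | str = "min-sample"
    ward_variant: str = "ward.D2"
    n_clusters: int = 2

    # community test
    n_permutations: int = 999

    seed: int = 0
    taxa_levels_16s: tuple[str, ...] = ("genus", "species")
    taxa_levels_shotgun: tuple[str, ...] = ("genus", "species")

    def __post_init__(self) -> None:
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be >= 1")
        if self.selection_count_threshold > self.cv_repeats:
            raise ValueError("selection_count_threshold cannot exceed cv_repeats")
        for name in ("prevalence_min", "variance_quantile", "q_threshold",
                     "correlation_p_threshold"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0 < self.alpha_mixing <= 1):
            raise ValueError("alpha_mixing must lie in (0, 1]")
        if self.cv_folds < 3:
            raise ValueError("cv_folds must be >= 3")
        if self.pseudocount is not None and self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.rarefaction_iters < 1:
            raise ValueError("rarefaction_iters must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["taxa_levels_16s"] = list(self.taxa_levels_16s)
        d["taxa_levels_shotgun"] = list(self.taxa_levels_shotgun)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        from .io import read_json

        d = read_json(path)
        for key in ("taxa_levels_16s", "taxa_levels_shotgun"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self, path) -> None:
        from .io import write_json

        write_json(self.to_dict(), path)
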